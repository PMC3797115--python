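# apaswitch

Analysis of alternative polyadenylation (APA) isoform switching between two
cellular conditions, and of its downstream consequences for miRNA-mediated
protein regulation.

## The problem

Alternative polyadenylation generates transcript isoforms of the same gene
that differ only in 3′UTR length. Because the 3′UTR harbours miRNA binding
sites, a shift in isoform usage — say, during stem-cell differentiation,
comparing induced (IN) against control (CT) cells — changes which miRNAs can
act on a gene even when total expression is unchanged. This package takes
isoform-level abundance tables (cuffdiff-style `fpkm_tracking` TSVs), a 3′UTR
annotation (Ensembl GTF or a transcript→length table), a binary
transcript × miRNA target matrix, and a per-gene protein log-fold-change time
course, and asks:

1. Do genes shift toward longer or shorter 3′UTRs after induction, and is the
   shift significant per gene and globally?
2. Which miRNAs gain or lose access to each gene through the usage shift?
3. Does adding those miRNA scores to a linear model of protein fold-change on
   mRNA fold-change explain the protein changes that mRNA alone cannot?

## The statistics

**Usage-weighted length difference.** With `p_c(t)` the usage proportion of
transcript `t` (its FPKM over the gene's summed FPKM) in condition `c`, the
per-gene shift is `Δ = Σ_t len(t)·(p_IN(t) − p_CT(t))` — positive means longer
3′UTRs under induction.

**CMH linear-trend test.** Per gene, the 2 × k table of condition × transcript
counts is scored with column scores = 3′UTR lengths and row scores CT < IN;
`r` is the count-weighted Pearson correlation of the scores and
`M² = (n−1)·r²` is chi-square with 1 df under independence. Benjamini–
Hochberg controls the FDR across genes, and a one-sample Wilcoxon of the
per-gene `r` against zero summarises the global shift.

**Usage score.** For gene g and miRNA i,
`score(g,i) = Σ_t (p_IN(t) − p_CT(t))·1[site of i in t]` ∈ [−1, 1]: +1 is a
complete switch onto site-carrying isoforms, 0 means the miRNA targets all or
none of the gene's isoforms.

**Protein models.** `logFC_prot = β₀ + b·logFC_mRNA − Σ_i γ_i·score_i + ε`.
The slope `b` is the range-compression coefficient (if protein quantity
scales as `c·mRNA^b`, the logFC slope is exactly `b`); each `γ_i > 0` is a
repression effect, the log-scale image of per-target-site exponential mRNA
decay. Models with 1–5 miRNA covariates are ranked by BIC (error variance
counted as a parameter); a permutation bootstrap shuffles each miRNA's scores
across genes and reports the fraction of permutations the true model's R²
beats.

Also included: a pairwise miRNA co-occurrence scan on the target matrix
(binary and usage-weighted, with pairwise-zero filtering), a gene-set
ranking report over the genome-wide Δ ranking, and a synthetic-data
generator that plants all of the above structure with known ground truth.

## Worked example

Simulate a small dataset and run the trend, model, and bootstrap stages:

```sh
printf 'n_genes: 500\nn_mirnas: 60\nn_protein_genes: 80\n' > demo_cfg.yaml
apaswitch simulate --config demo_cfg.yaml --seed 11 -o demo
apaswitch trend --isoforms demo/isoforms.tsv -o demo/trend.tsv
apaswitch model --prot demo/protein.tsv --isoforms demo/isoforms.tsv \
    --targets demo/targets.tsv --day 5 -o demo/models.tsv
apaswitch bootstrap --prot demo/protein.tsv --isoforms demo/isoforms.tsv \
    --targets demo/targets.tsv --n-perm 200 --seed 11 -o demo/boot.tsv
```

prints

```
simulated 500 genes, 60 miRNAs -> demo
genes tested: 385  mean delta: 65.82 b (trimmed 26.04 b)
positive 204  negative 179  none 2  q<0.05: 174
best model: logfc_mrna+miR-0001  R2=0.936 BIC=-124.85
60 miRNAs; Kruskal-Wallis p (high vs low win) = 6.56e-05
```

Reading this: 385 multi-isoform genes entered the trend test; the mean
usage-weighted 3′UTR shift is +65.8 bases (+26.0 after removing >1 kb
outliers), with more lengthening (204) than shortening (179) genes — the
planted bias toward longer 3′UTRs under induction. The best protein model by
BIC contains exactly the planted repressive miRNA (miR-0001) and explains
93.6% of protein log-fold-change variance, against 2–20% for the base
mRNA-only model; the bootstrap separates it cleanly from chance covariates.
`trend.tsv` holds the per-gene table (gene, Δ bases, trend r, M², p, q,
class); `apaswitch run-all -o out/` executes every stage and writes a
`manifest.json` with sha256 hashes of each output.

## Layout

- `src/apaswitch/io_formats.py` — fpkm_tracking / GTF / target-matrix /
  protein-table readers, usage proportions, gene logFC, symbol matching
- `src/apaswitch/apa_trend.py` — Δ length, CMH trend test, FDR, global tests
- `src/apaswitch/mirna_scoring.py` — usage score matrix, site-gain census
- `src/apaswitch/protein_models.py` — OLS fits, BIC search, bootstrap
- `src/apaswitch/cooccurrence.py` — pairwise miRNA correlation
- `src/apaswitch/geneset_rank.py` — gene-set ranking report
- `src/apaswitch/synthetic_data.py` — generator + worked toy fixture
- `src/apaswitch/cli.py` — `apaswitch` subcommands and `run-all`
- `docs/methods.md` — models, assumptions, parameter choices, limitations
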