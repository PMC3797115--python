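# Methods

## Data model

The unit of analysis is the isoform usage table: one row per transcript with
its gene, 3′UTR length (bases), and FPKM per condition (CT = control,
IN = induced). Usage proportions are FPKM over the gene's summed FPKM per
condition; genes whose summed FPKM is zero in a condition have undefined
proportions and are flagged and excluded from per-gene tests rather than
zero-filled. Transcripts are retained only when their cuffdiff
quantification status is `OK` in every requested condition — the strictest
reading of status filtering, chosen because low-coverage FPKM estimates are
exactly the rows whose proportions are least trustworthy. The number of
excluded transcripts is reported on the table.

GTF coordinates are treated as 1-based inclusive (Ensembl convention); a
3′UTR interval contributes `end − start + 1` bases and a transcript's length
is the sum over its `three_prime_utr` features. The GTF reader is a direct
line parser so that malformed input can be reported with its line number;
tests cross-check it against gffutils and a per-base counting oracle.

Gene-level mRNA log fold-change is `log2((ΣFPKM_IN + c)/(ΣFPKM_CT + c))`
with pseudocount `c = 0.1` (configurable, strictly positive). This is
deliberately simple plumbing: the upstream differential-expression machinery
that would normally produce moderated logFCs is out of scope, and the
pseudocounted ratio is transparent and monotone in the data.

Cross-species protein/mRNA joins (murine SILAC panel against human
transcripts) use case-insensitive symbol equality only. Unmatched rows are
reported, never silently dropped; duplicated symbols are all joined with a
warning. Orthology inference is a non-goal.

## Trend testing

The per-gene 2 × k count table is built from FPKM rounded to the nearest
integer (floored at zero), optionally scaled by `--count-scale`. The
statistic's magnitude grows linearly with the table total, so the count
scale is part of the reported analysis conditions, not a hidden constant;
at scale 1 an FPKM unit plays the role of one pseudo-count. Degenerate
tables (a condition with no counts, all counts in one transcript, total
< 2) are skipped with a logged reason. Genes need ≥ 2 transcripts with
annotated 3′UTRs to enter.

Trend classes are the sign of r (`none` only at exactly 0). Multiple
testing uses Benjamini–Hochberg; the global shift test is a one-sample
Wilcoxon signed-rank of per-gene trend r against zero (two-sided default),
returning p = 1 on all-zero input. The total-vs-polysomal comparison is a
fraction × trend-class chi-square without continuity correction (so the
null p stays uniform) plus a Pearson correlation of per-gene r over the
shared genes. The >1 kb outlier cut for the trimmed mean shift only affects
the global mean, never per-gene results.

## Usage scores and the site-gain census

The score is the inner product of the per-transcript usage shift with the
binary presence vector. One-or-more sites collapse to presence = 1 by
default; a cooperative variant (`read_mirna_targets(..., cooperative=True)`,
`apaswitch score --cooperative`) retains site counts, in which case the
score weighs shifts by multiplicity and the [−1, 1] bound no longer
applies. Conservation — a miRNA targeting all or none of a
gene's isoforms scores exactly 0 — is enforced structurally (constant
presence columns are zeroed per gene) rather than left to floating-point
cancellation, because downstream code treats exact zeros as "no usage
information".

The census counts genes with at least one transcript pair whose 3′UTR
lengths differ by at most d bases (but not zero) and whose target sets
differ in at least one miRNA. The ≤ d reading is intentional: the question
is whether length differences *that small* can already change miRNA
content.

## Protein models

All fits are OLS. BIC is computed from the Gaussian log-likelihood at the
MLE error variance with penalty `(p + 1)·ln(n)`, counting the intercept,
the slopes, and the error variance — one fixed convention so rankings are
bit-reproducible (it equals the statsmodels OLS BIC plus `ln n`). Exact
fits floor the RSS at 1e-300 to keep the likelihood finite.

The combination search fits univariate models for every miRNA with score
variance, BH-adjusts their coefficient p-values, and then explores
2–5-miRNA subsets only within the univariate-significant set (capped at the
15 smallest q-values), exhaustively or greedily forward by BIC. An
unrestricted exhaustive search over all subsets of hundreds of miRNAs is
combinatorially infeasible and would mostly enumerate noise; restriction to
marginally significant candidates is the documented surrogate. The search
uses a closed-form OLS path (normal equations, t-based p-values) verified
against statsmodels to 1e-12 in the test suite.

The bootstrap permutes one miRNA's scores across genes (preserving the
multiset), refits, and reports the fraction of `n_perm` permutations the
unshuffled model's R² strictly exceeds. The default `n_perm = 1000` and the
0.95 win threshold are configuration keys, not constants. Internally the
permuted R² is computed by residualising the permuted column against the
base design once per miRNA (QR projection) and using the partial
correlation identity `R²_full = 1 − (1 − R²_base)(1 − ρ²)`; this makes a
400-miRNA × 1000-permutation scan a few seconds' work. High-win versus
low-win explained variances are compared by Kruskal–Wallis.

Two structural identities anchor the modelling choices. First, if absolute
protein quantity is `c·mRNA^b` in both conditions (translational efficiency
decaying with abundance), the logFC-on-logFC slope is exactly `b` — so
range compression (b < 1) is expected and b is directly interpretable; the
suite verifies noiseless recovery to 1e-6. Second, a per-target-site
exponential decay of the message is, on the log scale, exactly the linear
`−γ·score` term, so the generator produces proteins from that form and
recovery of γ is a meaningful end-to-end check rather than a tautology.

## Co-occurrence

Per pair, rows where neither miRNA has a site are removed (pairwise-zero
filtering, keyed on binary presence for both the binary and the weighted
matrix, never consulting a third column); Pearson r over the survivors with
t-distribution p, BH-adjusted per matrix type. The weighted matrix scales a
present site by the transcript's usage proportion in a chosen condition
(IN default; CT and the IN−CT shift are selectable), so with unit weights
it reduces to the binary matrix identically.

Two consequences of the filter are worth stating plainly. Columns that
agree on every surviving row are constant (all (1,1)) there, so Pearson r is
formally undefined; perfect co-occurrence is reported as r = 1, p = 0 by
convention. And the filter is Berkson selection: conditioning on "at least
one of the pair present" makes even independent columns genuinely
anti-correlated (r concentrates near −1/2 at presence 0.5), so filtered
correlations must be read against that background, not against zero. The
test suite quantifies both effects.

## Gene-set ranking

Genes are sorted ascending by Δ length (ties broken by gene id; rank 1 =
strongest shortening). The report carries the set members' ranks, the
cumulative rank curve (ends at (1,1); the diagonal means the set is
exchangeable with the background), the negative/zero/positive split of the
set (|Δ| < 1e-9 counts as zero), and a two-sided Mann–Whitney of set vs
non-set Δ — a quantitative stand-in, labelled as such, for what is
otherwise a visual density comparison.

## Synthetic data

The generator emulates a two-condition bulk isoform-level experiment joined
to a protein panel. Per gene: 1–5 transcripts; 3′UTR lengths log-normal
(ln-mean 6.5, ln-sd 0.8 → median ≈ 665 bases, a realistic mammalian 3′UTR
scale); CT usage Dirichlet(1.5); a fraction `frac_trend` (default 0.5) of
multi-isoform genes gets its IN usage tilted along the within-gene length
rank by `exp(±shift·z)` with shift 2.0, positive direction with probability
`frac_positive_trend` (default 0.6 — a modest, consistent lengthening
bias); every transcript additionally receives log-normal usage wobble
(sd 0.1) so non-trend genes still show small usage noise. Gene totals are
log-normal (ln-mean 4, ln-sd 1) with a Normal(0,1) log2 expression fold
change. miRNA sites are Bernoulli with probability `2e-4 · length` (capped
at 1), so longer 3′UTRs stochastically carry more sites. Protein logFC per
day is `β₀ + b·logFC_mRNA − Σγ_i·score_i + Normal(0, 0.1)` with b = 0.2 and
one planted repressive miRNA at γ = 2 by default; 150 protein genes are
drawn from the multi-isoform genes. Default scale is 2,000 genes and 400
miRNAs — the order of magnitude of a filtered bulk experiment and a SILAC
panel — and a full simulation plus analysis runs in seconds. One integer
seed drives a single named generator; identical seeds give byte-identical
output files.

What the generator does *not* emulate: biological replicates and
overdispersion across donors, positional site structure within the 3′UTR,
miRNA expression levels (presence only, matching the analysis), mapping
and assembly artefacts, and cross-species noise in the protein join.
Passing recovery tests therefore demonstrates the estimators' correctness
under the assumed structure, not robustness to those real-data features.

The worked toy (5 genes, 3 miRNAs) is hand-auditable: a full usage switch
giving score +1 and M² = 19 on a 20-count table, a nested-site-set gene
with Δ = +90 bases, a no-change gene, a shortening gene (Δ = −240), and a
single-transcript gene that cannot enter the test. Its protein table is
generated from the model form with a fixed tiny wiggle so the planted
single-miRNA model is the BIC optimum. Every stage's output on the toy is
shipped and compared byte-for-byte in the test suite (writers pin float
formatting to `%.10g`).

## Numerical and design notes

- Trend r is clipped to [−1, 1] against rounding before squaring.
- Model-fit preconditions (≥ 10 complete rows by default) are exposed as
  `min_rows` so deliberately tiny fixtures like the toy can run with the
  bound lowered explicitly.
- `compare_fractions` drops trend classes empty in both fractions before
  the chi-square.
- The test suite seeds every simulation and derandomises hypothesis;
  the acceptance script derives all sub-seeds from the single `--seed`.
- Problem sizes in the recovery checks (20 seeds at 2,000 genes; bootstrap
  calibration at 50 miRNAs × 200 permutations × 10 seeds) were chosen to
  give stable pass/fail behaviour at a few seconds to half a minute each.

## Known limitations

- The CMH count scale treats one FPKM unit as one pseudo-count; absolute
  p-values therefore depend on sequencing-depth conventions upstream, and
  only the relative ranking of genes is scale-robust.
- Single-stratum design: conditions are pooled, with no donor/replicate
  strata.
- The exhaustive model search is exhaustive only within the
  univariate-significant candidate set; a miRNA predictive solely in
  combination will be missed unless greedy search picks it up.
- Filtered co-occurrence correlations carry the Berkson baseline described
  above; comparisons between matrices (binary vs weighted) are meaningful,
  raw significance against zero is not.
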