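"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates, from isoform abundances downward, the kind of data
the pipeline consumes: multi-isoform genes whose 3'UTR lengths are
log-normal; per-condition isoform usage drawn from a Dirichlet, with a
planted subset of "trend" genes whose induced-condition usage is tilted
toward longer (positive trend) or shorter (negative trend) 3'UTRs;
miRNA target sites whose per-transcript probability grows with 3'UTR
length (longer UTRs carry stochastically more sites); and a protein
log-fold-change time course generated as

    logFC_prot = b0 + b * logFC_mRNA - sum_i gamma_i * score_i + N(0, sd)

i.e. range compression (slope b < 1) plus linear-in-score miRNA
repression — the log-scale image of a per-target-site exponential decay of
the message, which makes the downstream models' assumption literally true
and parameter recovery a meaningful check.

Everything is driven by one integer seed through a single named generator;
the same seed reproduces the same tables bit for bit.  Ground truth
(per-gene trend direction and true weighted length difference, the
compression slope, the planted miRNA effects) is returned alongside the
tables for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_formats import IsoformUsageTable, PROTEIN_DAYS
from .mirna_scoring import usage_score_matrix


@dataclass
class SyntheticConfig:
    """Generator parameters.

    Default scale — 2,000 genes, 400 miRNAs, 150 protein genes — matches
    the order of magnitude of a bulk isoform-level differentiation
    experiment joined to a SILAC protein panel, while staying sub-minute.
    Lengths are in bases; FPKM totals and 3'UTR lengths are log-normal.
    """

    n_genes: int = 2000
    min_transcripts: int = 1
    max_transcripts: int = 5
    utr3_log_mean: float = 6.5      # ln-scale; median ~665 bases
    utr3_log_sd: float = 0.8
    frac_trend: float = 0.5         # multi-isoform genes given a usage shift
    frac_positive_trend: float = 0.6  # share of trend genes tilted longer
    dirichlet_alpha: float = 1.5
    shift_strength: float = 2.0     # log-tilt per unit length rank
    usage_noise_sd: float = 0.1     # residual usage wobble for all genes
    expr_log_mean: float = 4.0      # ln total FPKM; median ~55
    expr_log_sd: float = 1.0
    mrna_lfc_sd: float = 1.0        # per-gene expression log2FC spread
    site_prob_per_base: float = 2e-4
    n_mirnas: int = 400
    n_protein_genes: int = 150
    protein_set: str = "secreted"
    beta0: float = 0.0
    beta_mrna: float = 0.2          # range-compression slope b
    gamma: dict = field(default_factory=lambda: {"miR-0001": 2.0})
    noise_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_trend", "frac_positive_trend"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.site_prob_per_base:
            raise ValueError("site_prob_per_base must be >= 0")
        if self.noise_sd < 0 or self.usage_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.min_transcripts < 1 or self.max_transcripts < self.min_transcripts:
            raise ValueError("invalid transcripts-per-gene range")
        if self.n_protein_genes > self.n_genes:
            raise ValueError("n_protein_genes exceeds n_genes")
        bad = [m for m in self.gamma if not m.startswith("miR-")]
        if bad:
            raise ValueError(f"gamma keys must be miRNA ids, got {bad}")


@dataclass
class SyntheticTruth:
    """Ground truth emitted with every simulation."""

    genes: pd.DataFrame            # gene_id, n_transcripts, trend_direction, true_delta_len
    beta0: float
    beta_mrna: float
    gamma: dict
    protein_genes: list
    logfc_mrna: pd.Series = field(repr=False, default=None)
    scores_planted: pd.DataFrame = field(repr=False, default=None)


@dataclass
class SyntheticBundle:
    table: IsoformUsageTable
    targets: pd.DataFrame
    protein: pd.DataFrame
    truth: SyntheticTruth
    config: SyntheticConfig


def simulate(config: SyntheticConfig) -> SyntheticBundle:
    """Draw one complete synthetic dataset from the config's distributions."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_genes
    ks = rng.integers(config.min_transcripts, config.max_transcripts + 1, size=n)
    total_t = int(ks.sum())
    gene_idx = np.repeat(np.arange(n), ks)
    gene_ids = np.array([f"GENE{i:05d}" for i in range(n)])
    transcript_ids = np.array([f"TX{i:06d}" for i in range(total_t)])

    lengths = np.maximum(
        np.rint(rng.lognormal(config.utr3_log_mean, config.utr3_log_sd, size=total_t)),
        20).astype(int)

    # CT usage: Dirichlet via normalized gammas within each gene
    g = rng.gamma(config.dirichlet_alpha, size=total_t)
    gene_sum = np.bincount(gene_idx, weights=g, minlength=n)
    p_ct = g / gene_sum[gene_idx]

    # trend assignment on multi-isoform genes
    multi = ks >= 2
    is_trend = multi & (rng.random(n) < config.frac_trend)
    direction = np.where(rng.random(n) < config.frac_positive_trend, 1.0, -1.0)
    direction = np.where(is_trend, direction, 0.0)

    # length rank within gene scaled to [-1, 1]
    order = np.lexsort((lengths, gene_idx))
    rank_in_gene = np.empty(total_t, dtype=float)
    pos = 0
    for i, k in enumerate(ks):
        rank_in_gene[order[pos:pos + k]] = np.arange(k)
        pos += k
    with np.errstate(invalid="ignore"):
        z = np.where(ks[gene_idx] > 1,
                     2.0 * rank_in_gene / np.maximum(ks[gene_idx] - 1, 1) - 1.0, 0.0)

    tilt = direction[gene_idx] * config.shift_strength * z
    tilt = tilt + rng.normal(0.0, config.usage_noise_sd, size=total_t)
    w_in = p_ct * np.exp(tilt)
    in_sum = np.bincount(gene_idx, weights=w_in, minlength=n)
    p_in = w_in / in_sum[gene_idx]

    total_ct = rng.lognormal(config.expr_log_mean, config.expr_log_sd, size=n)
    lfc = rng.normal(0.0, config.mrna_lfc_sd, size=n)
    total_in = total_ct * np.exp2(lfc)
    fpkm_ct = p_ct * total_ct[gene_idx]
    fpkm_in = p_in * total_in[gene_idx]

    data = pd.DataFrame({
        "transcript_id": transcript_ids,
        "gene_id": gene_ids[gene_idx],
        "utr3_length": lengths,
        "fpkm_CT": fpkm_ct,
        "fpkm_IN": fpkm_in,
    })
    table = IsoformUsageTable.from_fpkm(data, ["CT", "IN"])

    # miRNA sites: presence probability grows with 3'UTR length
    mirna_ids = [f"miR-{i + 1:04d}" for i in range(config.n_mirnas)]
    p_site = np.minimum(config.site_prob_per_base * lengths, 1.0)
    sites = rng.random((total_t, config.n_mirnas)) < p_site[:, None]
    targets = pd.DataFrame(sites.astype(np.int8), index=pd.Index(transcript_ids,
                           name="transcript_id"), columns=mirna_ids)
    targets.columns.name = "mirna_id"

    # ground truth per gene
    delta = np.bincount(gene_idx, weights=lengths * (p_in - p_ct), minlength=n)
    truth_genes = pd.DataFrame({
        "gene_id": gene_ids,
        "n_transcripts": ks,
        "trend_direction": direction.astype(int),
        "true_delta_len": delta,
    })

    # protein panel: multi-isoform genes, so miRNA scores can vary
    from .io_formats import gene_logfc
    eligible = gene_ids[multi]
    n_prot = min(config.n_protein_genes, eligible.size)
    protein_genes = list(rng.choice(eligible, size=n_prot, replace=False))
    logfc_mrna = gene_logfc(table, "IN", "CT")

    planted = [m for m in config.gamma if m in targets.columns]
    scores_planted = usage_score_matrix(table, targets[planted]) if planted \
        else pd.DataFrame(index=gene_ids)

    prot_rows = {"gene_symbol": protein_genes, "set_label": config.protein_set}
    struct = np.full(n_prot, config.beta0) \
        + config.beta_mrna * logfc_mrna.reindex(protein_genes).to_numpy()
    for m in planted:
        struct = struct - config.gamma[m] * \
            scores_planted[m].reindex(protein_genes).fillna(0.0).to_numpy()
    for d in PROTEIN_DAYS:
        prot_rows[f"logfc_day{d}"] = struct + rng.normal(0.0, config.noise_sd, n_prot)
    protein = pd.DataFrame(prot_rows)[
        ["gene_symbol"] + [f"logfc_day{d}" for d in PROTEIN_DAYS] + ["set_label"]]

    truth = SyntheticTruth(genes=truth_genes, beta0=config.beta0,
                           beta_mrna=config.beta_mrna, gamma=dict(config.gamma),
                           protein_genes=protein_genes, logfc_mrna=logfc_mrna,
                           scores_planted=scores_planted)
    return SyntheticBundle(table=table, targets=targets, protein=protein,
                           truth=truth, config=config)


def config_from_dict(d: dict) -> SyntheticConfig:
    """Build a config from a flat key-value mapping (YAML-friendly)."""
    known = {f for f in SyntheticConfig.__dataclass_fields__}
    bad = set(d) - known
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    return SyntheticConfig(**d)


def config_to_dict(config: SyntheticConfig) -> dict:
    return asdict(config)


# ---------------------------------------------------------------------------
# Worked toy fixture
# ---------------------------------------------------------------------------

def worked_toy() -> SyntheticBundle:
    """A 5-gene, 3-miRNA, hand-auditable fixture.

    Gene layout (lengths in bases):

    * G1 — full switch: T1a (100, no sites) used exclusively in CT, T1b
      (300, miR-A) exclusively in IN; usage score for miR-A is exactly +1
      and the 20-count trend table gives r = 1, M^2 = 19.
    * G2 — nested site sets on increasing lengths (the classic picture of a
      gene whose longer 3'UTRs accumulate sites): T2a (100, none),
      T2b (200, miR-A), T2c (400, miR-A + miR-B); usage shifts from
      (0.5, 0.3, 0.2) to (0.2, 0.3, 0.5), a weighted length gain of +90.
    * G3 — no usage change (two isoforms, equal proportions both
      conditions); all scores 0.
    * G4 — negative trend: long isoform (500, miR-C) loses usage
      0.8 -> 0.2.
    * G5 — single transcript (200); no alternative usage possible.

    The protein table is generated noiselessly apart from a fixed, tiny
    per-gene wiggle from logFC_prot = 0.2 * logFC_mRNA - 1.5 * score(miR-A),
    so the planted single-miRNA model is the best model by BIC.
    """
    rows = [
        # transcript, gene, utr3, fpkm_CT, fpkm_IN
        ("T1a", "G1", 100, 10.0, 0.0),
        ("T1b", "G1", 300, 0.0, 10.0),
        ("T2a", "G2", 100, 5.0, 2.0),
        ("T2b", "G2", 200, 3.0, 3.0),
        ("T2c", "G2", 400, 2.0, 5.0),
        ("T3a", "G3", 150, 4.0, 8.0),
        ("T3b", "G3", 250, 4.0, 8.0),
        ("T4a", "G4", 500, 8.0, 1.0),
        ("T4b", "G4", 100, 2.0, 4.0),
        ("T5a", "G5", 200, 5.0, 15.0),
    ]
    data = pd.DataFrame(rows, columns=["transcript_id", "gene_id", "utr3_length",
                                       "fpkm_CT", "fpkm_IN"])
    table = IsoformUsageTable.from_fpkm(data, ["CT", "IN"])

    targets = pd.DataFrame(0, index=pd.Index(data["transcript_id"], name="transcript_id"),
                           columns=["miR-A", "miR-B", "miR-C"], dtype=np.int8)
    targets.loc["T1b", "miR-A"] = 1
    targets.loc["T2b", "miR-A"] = 1
    targets.loc["T2c", ["miR-A", "miR-B"]] = 1
    targets.loc["T4a", "miR-C"] = 1
    targets.columns.name = "mirna_id"

    from .io_formats import gene_logfc
    logfc_mrna = gene_logfc(table, "IN", "CT")
    score_a = usage_score_matrix(table, targets)["miR-A"]
    genes = ["G1", "G2", "G3", "G4", "G5"]
    wiggle = pd.Series([0.01, -0.015, 0.02, -0.01, 0.005], index=genes)
    prot = {"gene_symbol": genes, "set_label": "secreted"}
    for d in PROTEIN_DAYS:
        prot[f"logfc_day{d}"] = (0.2 * logfc_mrna.reindex(genes)
                                 - 1.5 * score_a.reindex(genes).fillna(0.0)
                                 + wiggle + 0.001 * d).to_numpy()
    protein = pd.DataFrame(prot)[
        ["gene_symbol"] + [f"logfc_day{d}" for d in PROTEIN_DAYS] + ["set_label"]]

    ks = data.groupby("gene_id")["transcript_id"].count()
    truth_genes = pd.DataFrame({
        "gene_id": genes,
        "n_transcripts": ks.reindex(genes).to_numpy(),
        "trend_direction": [1, 1, 0, -1, 0],
        "true_delta_len": [200.0, 90.0, 0.0, -240.0, 0.0],
    })
    truth = SyntheticTruth(genes=truth_genes, beta0=0.0, beta_mrna=0.2,
                           gamma={"miR-A": 1.5}, protein_genes=genes,
                           logfc_mrna=logfc_mrna)
    cfg = SyntheticConfig(n_genes=5, n_mirnas=3, n_protein_genes=5, seed=0,
                          gamma={"miR-A": 1.5})
    return SyntheticBundle(table=table, targets=targets, protein=protein,
                           truth=truth, config=cfg)
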