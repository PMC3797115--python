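"""Per-gene 3'UTR length trend testing between conditions.

For each gene the weighted 3'UTR length difference is

    delta = sum_t len(t) * (p_IN(t) - p_CT(t))

i.e. the usage-weighted mean 3'UTR length under induction minus the weighted
mean under control; positive values mean longer 3'UTRs after induction.

Significance per gene comes from the Cochran-Mantel-Haenszel linear-trend
test on the 2 x k contingency table of (condition x transcript) counts with
column scores equal to 3'UTR lengths and row scores CT=0 < IN=1:

    r    = count-weighted Pearson correlation of row and column scores
    M^2  = (n - 1) * r^2        ~ chi^2 with 1 df under independence

where n is the table total.  The trend is classed positive / negative /
none by the sign of r.  Counts are FPKM values rounded to the nearest
integer (floored at zero), optionally multiplied by a count scale to
emulate read depth; the statistic's magnitude grows with n, so the count
scale is an explicit, reported parameter.

Module-level summaries reproduce the global comparisons: mean length shift
with and without >1 kb outliers, a one-sample Wilcoxon of the per-gene
trend against zero, BH false-discovery-rate adjustment, and the
total-vs-polysomal fraction comparison (trend-class chi-square plus
trend correlation over the shared genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import IsoformUsageTable

logger = logging.getLogger(__name__)

TREND_COLUMNS = ["gene_id", "n_transcripts", "delta_len", "trend_r",
                 "cmh_stat", "p_value", "q_value", "trend_class"]


@dataclass
class TrendResult:
    """CMH linear-trend outcome for one gene."""

    gene_id: str
    n_transcripts: int
    delta_len: float
    trend_r: float
    cmh_stat: float
    p_value: float
    q_value: float = float("nan")
    trend_class: str = "none"


def weighted_delta_length(lengths, p_ct, p_in) -> float:
    """Usage-weighted 3'UTR length difference (IN minus CT) in bases.

    Single-transcript genes cannot show alternative usage and return 0.
    Because the usage differences sum to zero per gene, the result is
    invariant to adding a constant to all of a gene's lengths.
    """
    lengths = np.asarray(lengths, dtype=float)
    p_ct = np.asarray(p_ct, dtype=float)
    p_in = np.asarray(p_in, dtype=float)
    if lengths.size == 1:
        logger.debug("single-transcript gene: delta length fixed at 0")
        return 0.0
    return float(np.sum(lengths * (p_in - p_ct)))


def mean_delta(deltas, outlier_kb: float = 1.0) -> tuple[float, float]:
    """Mean length shift over all genes and with >``outlier_kb`` kb outliers removed.

    Outliers are genes whose absolute weighted difference exceeds the cut
    (default 1 kb); they are excluded only for the trimmed mean, to avoid a
    handful of extreme 3'UTRs biasing the global summary.
    """
    if outlier_kb <= 0:
        raise ValueError("outlier_kb must be > 0")
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        raise ValueError("mean_delta: empty input")
    cut = outlier_kb * 1000.0
    trimmed = deltas[np.abs(deltas) <= cut]
    mean_trimmed = float(trimmed.mean()) if trimmed.size else float("nan")
    return float(deltas.mean()), mean_trimmed


class DegenerateTableError(ValueError):
    """A contingency table on which the trend statistic is undefined."""


def cmh_trend_test(counts, col_scores, row_scores=(0.0, 1.0)) -> tuple[float, float, float]:
    """CMH linear-trend test on a 2 x k count table.

    Parameters
    ----------
    counts
        2 x k non-negative table; row 0 = CT, row 1 = IN.
    col_scores
        k column scores (3'UTR lengths).
    row_scores
        Row scores; CT < IN so positive r means longer 3'UTRs under IN.

    Returns
    -------
    (trend_r, cmh_stat, p_value) with ``cmh_stat = (n - 1) * trend_r**2``
    and p from the upper tail of chi-square with 1 df.

    Raises
    ------
    DegenerateTableError
        Zero condition margin, table total < 2, or zero variance in either
        score margin (e.g. all counts in one transcript).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 2 or counts.shape[1] < 2:
        raise ValueError("counts must be a 2 x k table with k >= 2")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    x = np.asarray(col_scores, dtype=float)
    u = np.asarray(row_scores, dtype=float)
    n = counts.sum()
    if n < 2:
        raise DegenerateTableError("table total < 2")
    row_tot = counts.sum(axis=1)
    if (row_tot == 0).any():
        raise DegenerateTableError("a condition has no counts")
    col_tot = counts.sum(axis=0)
    mx = (col_tot * x).sum() / n
    mu = (row_tot * u).sum() / n
    var_x = (col_tot * (x - mx) ** 2).sum() / n
    var_u = (row_tot * (u - mu) ** 2).sum() / n
    if var_x == 0 or var_u == 0:
        raise DegenerateTableError("zero variance in a score margin")
    cov = (counts * np.outer(u - mu, x - mx)).sum() / n
    r = cov / np.sqrt(var_x * var_u)
    r = float(np.clip(r, -1.0, 1.0))
    stat = (n - 1) * r * r
    p = float(stats.chi2.sf(stat, df=1))
    return r, float(stat), p


def counts_from_fpkm(fpkm, count_scale: float = 1.0) -> np.ndarray:
    """Integer pseudo-counts for the trend table: FPKM * scale, rounded, floored at 0."""
    return np.maximum(np.rint(np.asarray(fpkm, dtype=float) * count_scale), 0.0)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def trend_table(table: IsoformUsageTable, cond_ct: str = "CT", cond_in: str = "IN",
                count_scale: float = 1.0) -> pd.DataFrame:
    """Run the per-gene trend test over every eligible gene of a usage table.

    Eligibility: >= 2 transcripts with annotated 3'UTR lengths, defined
    proportions (non-zero gene total) in both conditions, and a
    non-degenerate count table.  Skipped genes are logged with the reason.
    Returns a DataFrame with :data:`TREND_COLUMNS`, BH-adjusted q-values,
    and the three-way trend class from the sign of r.
    """
    rows = []
    skipped: dict[str, str] = {}
    undefined = table.undefined_genes(cond_ct) | table.undefined_genes(cond_in)
    for gene_id, g in table.genes():
        g = g.dropna(subset=["utr3_length"])
        if len(g) < 2:
            skipped[gene_id] = "fewer than 2 transcripts with annotated 3'UTR"
            continue
        if gene_id in undefined:
            skipped[gene_id] = "undefined proportions (zero total FPKM)"
            continue
        lengths = g["utr3_length"].to_numpy(dtype=float)
        delta = weighted_delta_length(lengths,
                                      g[f"p_{cond_ct}"].to_numpy(),
                                      g[f"p_{cond_in}"].to_numpy())
        counts = np.vstack([
            counts_from_fpkm(g[f"fpkm_{cond_ct}"], count_scale),
            counts_from_fpkm(g[f"fpkm_{cond_in}"], count_scale),
        ])
        try:
            r, stat, p = cmh_trend_test(counts, lengths)
        except DegenerateTableError as exc:
            skipped[gene_id] = str(exc)
            continue
        rows.append((gene_id, len(g), delta, r, stat, p))
    if skipped:
        logger.info("trend_table: skipped %d genes (%s ...)", len(skipped),
                    next(iter(skipped.items())))
    df = pd.DataFrame(rows, columns=["gene_id", "n_transcripts", "delta_len",
                                     "trend_r", "cmh_stat", "p_value"])
    if len(df):
        df["q_value"] = fdr_adjust(df["p_value"])
        df["trend_class"] = np.select(
            [df["trend_r"] > 0, df["trend_r"] < 0], ["positive", "negative"], "none")
    else:
        df["q_value"] = []
        df["trend_class"] = []
    df.attrs["skipped"] = skipped
    return df[TREND_COLUMNS]


def global_shift_test(values, alternative: str = "two-sided") -> tuple[float, float]:
    """One-sample Wilcoxon signed-rank of per-gene trend values against zero.

    ``values`` may be the per-gene trend correlations or the weighted length
    differences.  All-zero input yields (0, 1): no evidence of a shift.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("global_shift_test needs >= 10 genes")
    nonzero = values[values != 0]
    if nonzero.size == 0:
        return 0.0, 1.0
    stat, p = stats.wilcoxon(nonzero, alternative=alternative)
    return float(stat), float(p)


def compare_fractions(total: pd.DataFrame, poly: pd.DataFrame) -> tuple[float, float]:
    """Compare trend outcomes between total and polysomal RNA fractions.

    Returns ``(chi2_p, trend_corr)``: the p-value of a fraction x trend-class
    contingency test (classes with zero counts in both fractions dropped)
    and the Pearson correlation of per-gene trend r over the gene
    intersection.
    """
    merged = total.merge(poly, on="gene_id", suffixes=("_total", "_poly"))
    if len(merged) < 3:
        raise ValueError("compare_fractions: gene intersection below 3")
    classes = ["negative", "none", "positive"]
    tab = np.array([
        [(total["trend_class"] == c).sum() for c in classes],
        [(poly["trend_class"] == c).sum() for c in classes],
    ], dtype=float)
    tab = tab[:, tab.sum(axis=0) > 0]
    if tab.shape[1] < 2 or (tab == tab[0]).all():
        chi2_p = 1.0
    else:
        # plain chi-square (no continuity correction), so the null p stays uniform
        chi2_p = float(stats.chi2_contingency(tab, correction=False)[1])
    r_t = merged["trend_r_total"].to_numpy()
    r_p = merged["trend_r_poly"].to_numpy()
    if np.std(r_t) == 0 or np.std(r_p) == 0:
        trend_corr = float("nan")
    else:
        trend_corr = float(np.corrcoef(r_t, r_p)[0, 1])
    return chi2_p, trend_corr
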