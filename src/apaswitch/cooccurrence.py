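"""Pairwise miRNA co-occurrence on the target matrix, with pairwise-zero filtering.

Co-targeting is measured as the Pearson correlation of two miRNAs' columns
over the transcript rows in which at least one of the pair is present —
pairwise-zero rows (neither miRNA has a site) are removed per pair, since
most transcripts carry neither of any given pair and would swamp the
signal.  Two matrices are compared: the binary presence/absence matrix and
a usage-weighted matrix in which a present site carries the transcript's
usage proportion (a site on an isoform used 30% of the time scores 0.3,
not 1).  With all usage weights equal to 1 the weighted correlation
reduces exactly to the binary one.

p-values come from the t-distribution with n - 2 df; per-matrix BH
adjustment is applied over all computable pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import IsoformUsageTable


@dataclass
class CooccurrenceResult:
    """Binary and usage-weighted correlation for one miRNA pair."""

    mirna_a: str
    mirna_b: str
    r_binary: float
    p_binary: float
    r_weighted: float
    p_weighted: float
    n_rows_used: int
    computable: bool = True


def weighted_target_matrix(targets: pd.DataFrame, table: IsoformUsageTable,
                           weight_condition: str = "IN") -> pd.DataFrame:
    """Presence matrix with each transcript row scaled by its usage weight.

    ``weight_condition`` selects the usage proportion under CT or IN, or
    ``"delta"`` for the IN - CT shift.  Transcripts absent from the usage
    table keep weight 0.
    """
    if weight_condition == "delta":
        w = (table.data["p_IN"] - table.data["p_CT"])
    else:
        col = f"p_{weight_condition}"
        if col not in table.data.columns:
            raise KeyError(f"unknown weight condition {weight_condition!r}")
        w = table.data[col]
    weights = pd.Series(w.to_numpy(), index=table.data["transcript_id"].to_numpy())
    aligned = weights.reindex(targets.index).fillna(0.0)
    return targets.mul(aligned, axis=0)


def pairwise_correlation(binary: pd.DataFrame, pair: tuple[str, str],
                         weighted: pd.DataFrame | None = None,
                         min_rows: int = 3) -> CooccurrenceResult:
    """Correlate one miRNA pair after dropping pairwise-zero rows.

    Filtering keys on binary presence (a row survives when at least one of
    the pair has a site) for both matrices, and never consults any third
    column.  Pairs with fewer than ``min_rows`` surviving rows or a
    zero-variance column are flagged not-computable.
    """
    a, b = pair
    pa = binary[a].to_numpy(dtype=float)
    pb = binary[b].to_numpy(dtype=float)
    keep = (pa != 0) | (pb != 0)
    n = int(keep.sum())
    if weighted is None:
        weighted = binary
    wa = weighted[a].to_numpy(dtype=float)[keep]
    wb = weighted[b].to_numpy(dtype=float)[keep]
    pa, pb = pa[keep], pb[keep]
    if n < min_rows:
        nan = float("nan")
        return CooccurrenceResult(a, b, nan, nan, nan, nan, n, computable=False)
    rb, pvb = _corr(pa, pb)
    rw, pvw = _corr(wa, wb)
    return CooccurrenceResult(a, b, rb, pvb, rw, pvw, n,
                              computable=not np.isnan(rb))


def _corr(u: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Pearson r with t-distribution p, with the exact-co-occurrence convention.

    Identical columns survive pairwise-zero filtering only as (1, 1) rows,
    so their correlation is formally undefined; perfect agreement over the
    surviving rows is reported as r = 1, p = 0 instead.  Any other
    zero-variance column leaves the pair not-computable.
    """
    if np.ptp(u) == 0 and np.ptp(v) == 0 and np.array_equal(u, v):
        return 1.0, 0.0
    if np.ptp(u) == 0 or np.ptp(v) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(u, v)
    return float(r), float(p)


def all_pairs(binary: pd.DataFrame, weighted: pd.DataFrame | None = None,
              min_rows: int = 3, fdr: float = 0.05) -> pd.DataFrame:
    """Every unordered miRNA pair with enough surviving rows, BH-adjusted.

    Adjustment is applied separately to the binary and weighted p-values.
    Returns a DataFrame sorted by binary q then |r|.
    """
    from .apa_trend import fdr_adjust

    rows = []
    for a, b in combinations(binary.columns, 2):
        res = pairwise_correlation(binary, (a, b), weighted, min_rows=min_rows)
        if res.computable:
            rows.append(vars(res))
    df = pd.DataFrame(rows)
    if len(df):
        df["q_binary"] = fdr_adjust(df["p_binary"])
        df["q_weighted"] = fdr_adjust(df["p_weighted"])
        df["significant"] = df["q_binary"] < fdr
        df = df.sort_values(["q_binary", "p_binary"], kind="mergesort").reset_index(drop=True)
    return df
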