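"""Usage-weighted miRNA target scores and the binding-site-gain census.

For gene g and miRNA i the usage score is

    score(g, i) = sum_t (p_IN(t) - p_CT(t)) * 1[site of i in transcript t]

the inner product of the per-transcript usage shift with the binary
presence vector.  Scores live in [-1, 1]: +1 means a complete usage switch
onto isoforms carrying the site (the miRNA can act only after induction),
-1 the converse, and 0 when the miRNA targets all or none of a gene's
isoforms (the shift vector sums to zero, so a constant presence vector
annihilates it).  |score| is bounded by the total-variation distance
between the two usage vectors.

The site-gain census asks whether small 3'UTR length differences can still
change miRNA content: for each length difference d it counts genes with at
least one transcript pair whose 3'UTR lengths differ by at most d (but not
zero) and whose target sets differ in at least one miRNA.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import IsoformUsageTable


def usage_score_matrix(table: IsoformUsageTable, targets: pd.DataFrame,
                       cond_ct: str = "CT", cond_in: str = "IN") -> pd.DataFrame:
    """Gene x miRNA matrix of usage-weighted target scores.

    ``targets`` is a transcript x miRNA binary matrix (one-or-more sites
    collapse to 1).  Transcripts absent from ``targets`` contribute an
    all-zero presence row.  Genes with undefined proportions in either
    condition are omitted.
    """
    data = table.data
    defined = table.defined_genes()
    data = data[data["gene_id"].isin(defined)]
    # align presence rows with the usage table; missing transcripts -> 0
    presence = targets.reindex(data["transcript_id"]).fillna(0).to_numpy(dtype=float)
    delta = (data[f"p_{cond_in}"] - data[f"p_{cond_ct}"]).to_numpy(dtype=float)
    weighted = presence * delta[:, None]
    out = pd.DataFrame(weighted, columns=targets.columns)
    out["gene_id"] = data["gene_id"].to_numpy()
    grouped = out.groupby("gene_id", sort=True)
    score = grouped.sum()
    # conservation: a miRNA targeting all (or none) of a gene's transcripts
    # must score exactly 0, since the usage shifts sum to zero per gene --
    # enforce the identity rather than leave float residue
    pres = pd.DataFrame(presence, columns=targets.columns)
    pres["gene_id"] = data["gene_id"].to_numpy()
    pg = pres.groupby("gene_id", sort=True)
    constant = (pg.min() == pg.max())
    score = score.where(~constant, 0.0)
    score.columns.name = "mirna_id"
    return score


def usage_score(gene_rows: pd.DataFrame, targets: pd.DataFrame,
                cond_ct: str = "CT", cond_in: str = "IN") -> pd.Series:
    """Usage score vector over miRNAs for a single gene's usage rows."""
    presence = targets.reindex(gene_rows["transcript_id"]).fillna(0).to_numpy(dtype=float)
    delta = (gene_rows[f"p_{cond_in}"] - gene_rows[f"p_{cond_ct}"]).to_numpy(dtype=float)
    values = presence.T @ delta
    constant = presence.min(axis=0) == presence.max(axis=0)
    values[constant] = 0.0  # exact conservation for all-or-none targeting
    return pd.Series(values, index=targets.columns, name="score")


def scores_long(score: pd.DataFrame, drop_zero: bool = True) -> pd.DataFrame:
    """Long-format (gene_id, mirna_id, score) view, omitting exact zeros."""
    long = score.stack().rename("score").reset_index()
    long.columns = ["gene_id", "mirna_id", "score"]
    if drop_zero:
        long = long[long["score"] != 0.0]
    return long.reset_index(drop=True)


def site_gain_census(table: IsoformUsageTable, targets: pd.DataFrame,
                     length_diffs=(20, 18, 12, 11)) -> dict[int, int]:
    """Count genes where a small 3'UTR length difference changes miRNA content.

    For each difference d, a gene is counted when it has >= 1 transcript
    pair with 0 < |length difference| <= d whose target sets differ in at
    least one miRNA.  The upper-bound reading asks whether differences
    *that small* already alter site content.
    """
    diffs = sorted(int(d) for d in length_diffs)
    if any(d <= 0 for d in diffs):
        raise ValueError("length differences must be positive")
    counts = {d: 0 for d in diffs}
    dmax = diffs[-1]
    for gene_id, g in table.genes():
        g = g.dropna(subset=["utr3_length"])
        if len(g) < 2:
            continue
        lengths = g["utr3_length"].to_numpy(dtype=float)
        pres = targets.reindex(g["transcript_id"]).fillna(0).to_numpy(dtype=np.int8)
        # smallest pairwise length gap with differing target sets
        best = None
        for a in range(len(g)):
            for b in range(a + 1, len(g)):
                gap = abs(lengths[a] - lengths[b])
                if gap == 0 or gap > dmax:
                    continue
                if (pres[a] != pres[b]).any():
                    if best is None or gap < best:
                        best = gap
        if best is not None:
            for d in diffs:
                if best <= d:
                    counts[d] += 1
    return counts
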