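"""Readers, writers and derived per-gene quantities for the pipeline's tables.

The substrate of the whole analysis is an isoform-level abundance table in
the cuffdiff ``fpkm_tracking`` dialect (one FPKM and one quantification
status column per condition), joined with per-transcript 3'UTR lengths from
an Ensembl-style GTF.  From these we derive per-gene, per-condition isoform
usage proportions: a transcript's FPKM divided by the summed FPKM of its
gene in that condition.  Genes whose summed FPKM is zero in a condition have
undefined proportions and are flagged rather than silently zeroed.

All writers emit plain TSV with a single ``#``-prefixed header comment
recording the tool version and the parameters used, so every output file is
self-describing and byte-reproducible.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__

logger = logging.getLogger(__name__)

#: Quantification status accepted by the quality filter.  Every requested
#: condition must carry this status for a transcript to be retained.
STATUS_OK = "OK"

#: Fixed float format for all writers; pinned so outputs are byte-stable.
FLOAT_FORMAT = "%.10g"


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# Isoform usage table
# ---------------------------------------------------------------------------

@dataclass
class IsoformUsageTable:
    """Per-transcript FPKM and usage proportions for a set of conditions.

    Parameters
    ----------
    data
        One row per transcript with columns ``transcript_id``, ``gene_id``,
        ``utr3_length`` and, per condition ``c``, ``fpkm_<c>`` and
        ``p_<c>`` (usage proportion; NaN where the gene total is zero).
    conditions
        Condition names, e.g. ``["CT", "IN"]``.
    n_excluded
        Transcripts dropped by the quantification-status filter at read time.
    """

    data: pd.DataFrame
    conditions: list[str]
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.data["transcript_id"].duplicated().any():
            dup = self.data.loc[self.data["transcript_id"].duplicated(), "transcript_id"].iloc[0]
            raise FormatError(f"duplicate transcript_id: {dup!r}")

    @classmethod
    def from_fpkm(
        cls,
        df: pd.DataFrame,
        conditions: Sequence[str],
        utr3_lengths: Mapping[str, int] | None = None,
        n_excluded: int = 0,
    ) -> "IsoformUsageTable":
        """Build the table from raw FPKM rows, computing usage proportions."""
        data = df.copy()
        if utr3_lengths is not None:
            data["utr3_length"] = data["transcript_id"].map(utr3_lengths)
        if "utr3_length" not in data.columns:
            data["utr3_length"] = np.nan
        for c in conditions:
            col = f"fpkm_{c}"
            if (data[col] < 0).any():
                raise FormatError(f"negative FPKM in condition {c!r}")
            totals = data.groupby("gene_id")[col].transform("sum")
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(totals > 0, data[col] / totals, np.nan)
            data[f"p_{c}"] = p
        return cls(data=data.reset_index(drop=True), conditions=list(conditions),
                   n_excluded=n_excluded)

    def undefined_genes(self, condition: str) -> set[str]:
        """Genes whose summed FPKM is zero (proportions undefined) in a condition."""
        col = f"fpkm_{condition}"
        totals = self.data.groupby("gene_id")[col].sum()
        return set(totals.index[totals == 0])

    def defined_genes(self) -> set[str]:
        """Genes with defined proportions in every condition."""
        out = set(self.data["gene_id"])
        for c in self.conditions:
            out -= self.undefined_genes(c)
        return out

    def gene(self, gene_id: str) -> pd.DataFrame:
        return self.data[self.data["gene_id"] == gene_id]

    def genes(self) -> Iterable[tuple[str, pd.DataFrame]]:
        return self.data.groupby("gene_id", sort=True)

    def write(self, path, params: str = "") -> None:
        write_tsv(self.data, path, params=params)

    @classmethod
    def read(cls, path, conditions: Sequence[str]) -> "IsoformUsageTable":
        df = read_tsv(path)
        return cls(data=df, conditions=list(conditions))


def read_fpkm_tracking(path, conditions: Sequence[str],
                       utr3_lengths: Mapping[str, int] | None = None) -> IsoformUsageTable:
    """Read a cuffdiff-style ``fpkm_tracking`` TSV.

    Expects a header with ``tracking_id`` (or ``transcript_id``), ``gene_id``
    and, for each requested condition ``c``, columns ``<c>_FPKM`` and
    ``<c>_status``.  Transcripts whose status is not ``OK`` in *any*
    requested condition are dropped and counted (the quality filter; the
    per-condition rule is the strictest reading of quality filtering and is
    configurable only at the dialect level).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    id_col = "tracking_id" if "tracking_id" in df.columns else "transcript_id"
    required = [id_col, "gene_id"]
    for c in conditions:
        required += [f"{c}_FPKM", f"{c}_status"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    keep = np.ones(len(df), dtype=bool)
    for c in conditions:
        keep &= df[f"{c}_status"].str.strip().eq(STATUS_OK).to_numpy()
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("read_fpkm_tracking: excluded %d transcripts failing the "
                    "quantification-status filter", n_excluded)
    df = df[keep]
    out = pd.DataFrame({
        "transcript_id": df[id_col].to_numpy(),
        "gene_id": df["gene_id"].to_numpy(),
    })
    for c in conditions:
        out[f"fpkm_{c}"] = pd.to_numeric(df[f"{c}_FPKM"].to_numpy())
    if out["transcript_id"].duplicated().any():
        dup = out.loc[out["transcript_id"].duplicated(), "transcript_id"].iloc[0]
        raise FormatError(f"duplicate transcript_id: {dup!r}")
    return IsoformUsageTable.from_fpkm(out, conditions, utr3_lengths=utr3_lengths,
                                       n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# GTF 3'UTR lengths
# ---------------------------------------------------------------------------

_UTR_FEATURES = {"three_prime_utr", "three_prime_UTR"}


def utr3_lengths_from_gtf(path) -> dict[str, int]:
    """Sum 3'UTR interval lengths per transcript from an Ensembl-dialect GTF.

    GTF coordinates are 1-based inclusive, so an interval contributes
    ``end - start + 1`` bases.  Transcripts with no 3'UTR feature are absent
    from the returned map.  Malformed lines and negative-length intervals
    raise :class:`FormatError` naming the offending line number.

    A direct line reader is used here because the contract demands
    line-precise diagnostics on malformed input.
    """
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"malformed GTF line {lineno}: expected 9 "
                                  f"tab-separated fields, got {len(fields)}")
            feature = fields[2]
            if feature not in _UTR_FEATURES:
                continue
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise FormatError(f"malformed GTF line {lineno}: non-integer "
                                  f"coordinates") from exc
            if end < start:
                raise FormatError(f"negative interval on GTF line {lineno}: "
                                  f"start={start} end={end}")
            tid = _gtf_attribute(fields[8], "transcript_id")
            if tid is None:
                raise FormatError(f"malformed GTF line {lineno}: missing "
                                  f"transcript_id attribute")
            lengths[tid] = lengths.get(tid, 0) + (end - start + 1)
    return lengths


def _gtf_attribute(attr_field: str, key: str) -> str | None:
    for part in attr_field.split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part[len(key):].strip().strip('"')
    return None


# ---------------------------------------------------------------------------
# Gene-level fold change
# ---------------------------------------------------------------------------

def gene_logfc(table: IsoformUsageTable, cond_num: str, cond_den: str,
               pseudocount: float = 0.1) -> pd.Series:
    """Per-gene log2 fold change of summed FPKM between two conditions.

    logFC = log2((sum FPKM_num + pc) / (sum FPKM_den + pc)), summed over the
    gene's retained transcripts.  The pseudocount keeps zero-expression genes
    finite; it must be strictly positive.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    for c in (cond_num, cond_den):
        if c not in table.conditions:
            raise KeyError(f"unknown condition {c!r}; table has {table.conditions}")
    g = table.data.groupby("gene_id")
    num = g[f"fpkm_{cond_num}"].sum() + pseudocount
    den = g[f"fpkm_{cond_den}"].sum() + pseudocount
    out = np.log2(num / den)
    out.name = "logfc_mrna"
    return out


# ---------------------------------------------------------------------------
# Protein fold-change table and symbol matching
# ---------------------------------------------------------------------------

PROTEIN_DAYS = (1, 3, 5, 7)


def read_protein_logfc(path) -> pd.DataFrame:
    """Read a per-gene protein log-fold-change TSV.

    Columns: ``gene_symbol``, ``logfc_day1``, ``logfc_day3``, ``logfc_day5``,
    ``logfc_day7``, ``set_label`` (secreted or nuclear) — the shape of a
    SILAC time-course summary with one row per (gene, set).
    """
    df = read_tsv(path)
    required = ["gene_symbol"] + [f"logfc_day{d}" for d in PROTEIN_DAYS] + ["set_label"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    if df.duplicated(["gene_symbol", "set_label"]).any():
        raise FormatError("duplicate (gene_symbol, set_label) rows")
    return df


@dataclass
class MatchReport:
    """Outcome of a case-insensitive cross-species symbol join."""

    matched: pd.DataFrame
    unmatched: list[str] = field(default_factory=list)


def match_protein_genes(prot: pd.DataFrame, genes: Iterable[str]) -> MatchReport:
    """Join protein rows onto an expression gene set by case-folded symbol.

    Cross-species comparisons (murine proteome vs human transcriptome) are
    joined on symbol equality ignoring case; anything fancier (orthology) is
    out of scope.  Unmatched protein rows are reported, never dropped
    silently; duplicate symbols in the protein table are all joined, with a
    warning.
    """
    lookup = {g.upper(): g for g in genes}
    prot = prot.copy()
    prot["_key"] = prot["gene_symbol"].str.upper()
    if prot["_key"].duplicated().any():
        dups = sorted(prot.loc[prot["_key"].duplicated(), "gene_symbol"])
        logger.warning("match_protein_genes: duplicate symbols joined: %s", dups)
    hit = prot["_key"].isin(lookup)
    matched = prot[hit].copy()
    matched["gene_id"] = matched["_key"].map(lookup)
    matched = matched.drop(columns="_key")
    unmatched = sorted(prot.loc[~hit, "gene_symbol"])
    return MatchReport(matched=matched, unmatched=unmatched)


# ---------------------------------------------------------------------------
# miRNA target matrix
# ---------------------------------------------------------------------------

def read_mirna_targets(path, cooperative: bool = False) -> pd.DataFrame:
    """Read a transcript x miRNA target matrix.

    Accepts either long format (columns ``transcript_id``, ``mirna_id``; one
    row per site) or a wide matrix with ``transcript_id`` as first column.
    By default one-or-more seed sites collapse to presence = 1 and no
    multiplicity is kept; with ``cooperative=True`` site counts are retained
    (long-format duplicates accumulate, wide matrices may hold any
    non-negative integer), for modelling cooperative site effects.
    """
    df = read_tsv(path)
    if set(df.columns) >= {"transcript_id", "mirna_id"} and len(df.columns) == 2:
        df["value"] = 1
        agg = "sum" if cooperative else "max"
        wide = df.pivot_table(index="transcript_id", columns="mirna_id",
                              values="value", fill_value=0, aggfunc=agg)
        wide = wide.astype(np.int16 if cooperative else np.int8)
    else:
        wide = df.set_index("transcript_id")
        vals = wide.to_numpy()
        if cooperative:
            if (vals < 0).any() or not (vals == np.rint(vals)).all():
                raise FormatError("cooperative target matrix must hold "
                                  "non-negative integer site counts")
            wide = wide.astype(np.int16)
        else:
            if not np.isin(vals, (0, 1)).all():
                raise FormatError("miRNA target matrix must be strictly binary")
            wide = wide.astype(np.int8)
    wide.columns.name = "mirna_id"
    return wide


def write_mirna_targets(matrix: pd.DataFrame, path, params: str = "") -> None:
    write_tsv(matrix.reset_index(), path, params=params)


def read_gene_set(path) -> list[str]:
    """Read a gene set: one identifier per line, ``#`` comments allowed."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


# ---------------------------------------------------------------------------
# Canonical TSV i/o
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, params: str = "") -> None:
    """Write a tidy TSV with a version/parameter header comment."""
    header = f"# apaswitch v{__version__}"
    if params:
        header += f" | {params}"
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format=FLOAT_FORMAT)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        fh.write(buf.getvalue())


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
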