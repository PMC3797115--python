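import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from apaswitch.io_formats import IsoformUsageTable
from apaswitch.synthetic_data import worked_toy

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy():
    """The hand-auditable 5-gene / 3-miRNA fixture."""
    return worked_toy()


@pytest.fixture()
def usage_table():
    """A small two-gene usage table with one zero-expression gene."""
    data = pd.DataFrame({
        "transcript_id": ["tA1", "tA2", "tB1", "tB2"],
        "gene_id": ["GA", "GA", "GB", "GB"],
        "utr3_length": [100, 300, 150, 250],
        "fpkm_CT": [3.0, 1.0, 5.0, 5.0],
        "fpkm_IN": [1.0, 3.0, 0.0, 0.0],
    })
    return IsoformUsageTable.from_fpkm(data, ["CT", "IN"])


def make_usage(rows, conditions=("CT", "IN")):
    """Build an IsoformUsageTable from (tid, gene, len, fpkm_ct, fpkm_in) rows."""
    df = pd.DataFrame(rows, columns=["transcript_id", "gene_id", "utr3_length",
                                     "fpkm_CT", "fpkm_IN"])
    return IsoformUsageTable.from_fpkm(df, list(conditions))


def expand_to_units(counts, col_scores, row_scores=(0.0, 1.0)):
    """Literal expansion of a 2 x k count table to unit records.

    Independent oracle for the trend statistic: every count becomes that
    many (row score, column score) records, and the plain Pearson
    correlation over the expanded records is the trend r.
    """
    counts = np.asarray(counts)
    us, xs = [], []
    for i, u in enumerate(row_scores):
        for j, x in enumerate(col_scores):
            c = int(counts[i, j])
            us.extend([u] * c)
            xs.extend([x] * c)
    us, xs = np.asarray(us, float), np.asarray(xs, float)
    r = np.corrcoef(us, xs)[0, 1]
    n = len(us)
    return float(r), float((n - 1) * r * r)
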