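import numpy as np
import pytest

from betameth import CountTable, DesignMatrix, SiteKey


@pytest.fixture
def toy_counts() -> CountTable:
    """4 sites x 4 samples (2 control, 2 case) with a clear group split at
    the last two sites."""
    sites = [
        SiteKey("chr1", 108),
        SiteKey("chr1", 160),
        SiteKey("chr1", 400),
        SiteKey("chr2", 50),
    ]
    totals = np.array([
        [10, 12, 11, 9],
        [8, 10, 9, 12],
        [15, 14, 13, 16],
        [10, 10, 10, 10],
    ])
    meths = np.array([
        [5, 6, 6, 4],
        [2, 3, 7, 9],
        [3, 2, 11, 14],
        [5, 5, 5, 5],
    ])
    return CountTable(sites=sites, samples=["c1", "c2", "t1", "t2"],
                      totals=totals, meths=meths)


@pytest.fixture
def toy_design(toy_counts) -> DesignMatrix:
    return DesignMatrix(
        samples=list(toy_counts.samples),
        factors=["base", "case"],
        X=np.array([[1, 0], [1, 0], [1, 1], [1, 1]]),
    )
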