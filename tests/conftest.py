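import numpy as np
import pandas as pd
import pytest

from translocscape.core import BinnedMatrix, SegmentMap, make_bins
from translocscape.synthgen import SimConfig

TX = ("chr1", 12_000_000, "chr2", 6_000_000)


@pytest.fixture(scope="session")
def tx_config() -> SimConfig:
    """Default toy genome with a reciprocal translocation and a cis loop."""
    return SimConfig(translocation=TX, loop=(2, 14, 5.0), seed=1)


@pytest.fixture(scope="session")
def segment_map(tx_config) -> SegmentMap:
    return tx_config.segment_map()


@pytest.fixture
def small_matrix() -> BinnedMatrix:
    """5-bin two-chromosome matrix with known hand-checkable counts."""
    bins = make_bins({"c1": 2_000_000, "c2": 3_000_000}, 1_000_000)
    counts = np.array(
        [
            [4.0, 2.0, 1.0, 3.0, 2.0],
            [2.0, 6.0, 2.0, 1.0, 3.0],
            [1.0, 2.0, 8.0, 4.0, 2.0],
            [3.0, 1.0, 4.0, 10.0, 5.0],
            [2.0, 3.0, 2.0, 5.0, 12.0],
        ]
    )
    return BinnedMatrix(bins, counts, 1_000_000)


def random_symmetric_matrix(
    rng: np.random.Generator, chrom_bins: dict[str, int], scale: float = 20.0
) -> BinnedMatrix:
    bins = make_bins(
        {c: n * 1_000_000 for c, n in chrom_bins.items()}, 1_000_000
    )
    n = len(bins)
    a = rng.poisson(scale, (n, n)).astype(float)
    counts = np.triu(a) + np.triu(a, 1).T
    return BinnedMatrix(bins, counts, 1_000_000)


def make_pair_table(values: dict[tuple[str, str], float], chroms: list[str]) -> pd.DataFrame:
    table = pd.DataFrame(np.nan, index=chroms, columns=chroms, dtype=float)
    for (a, b), v in values.items():
        table.loc[a, b] = table.loc[b, a] = v
    return table
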