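import numpy as np
import pandas as pd
import pytest

from poolcal.data import records_to_frame, IntensityRecord
from poolcal.polynomial import ClusterCentres
from poolcal.simulate import simulate_panel


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def example_centres():
    """A distorted but calibratable SNP: centres away from (1, 1/2, 0)."""
    return ClusterCentres(f_AA=0.9, f_AB=0.4, f_BB=0.1, n_AA=5, n_AB=5, n_BB=5)


@pytest.fixture
def one_snp_records():
    """Ten called individuals of one SNP with clean cluster structure."""
    rows = []
    for i, (ha, hb, call) in enumerate(
        [(9, 1, "AA"), (8.5, 1.5, "AA"), (9.5, 0.5, "AA"),
         (4, 6, "AB"), (4.5, 5.5, "AB"), (3.5, 6.5, "AB"),
         (1, 9, "BB"), (0.5, 9.5, "BB"), (1.5, 8.5, "BB"), (1, 9, "BB")]
    ):
        rows.append(IntensityRecord("snpX", f"ind{i:02d}", ha, hb, call))
    return records_to_frame(rows)


@pytest.fixture(scope="session")
def small_panel():
    """A small simulated study reused by regression/benchmark tests."""
    return simulate_panel(
        n_snps=4, n_individuals=60, n_pools=8, pool_size=12,
        seed=11, noise_sd=0.05, saturation=0.1,
    )


@pytest.fixture(scope="session")
def small_pairs(small_panel):
    from poolcal.regression import make_training_pairs

    pairs = make_training_pairs(small_panel.records, small_panel.truth)
    ind = pairs[pairs["source"] == "individual"].reset_index(drop=True)
    pools = pairs[pairs["source"] == "pool"].reset_index(drop=True)
    return ind, pools
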