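import numpy as np
import pytest

from snpdiv.simdata import SimulationConfig, simulate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_pop_dataset():
    """Moderately differentiated 2-population dataset, no missing data."""
    config = SimulationConfig(
        n_pops=2,
        pop_sizes=(30, 30),
        n_loci=800,
        bn_F=(0.1, 0.1),
        fis=(0.0, 0.0),
        seed=11,
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def three_pop_missing_dataset():
    """3 populations with 10% combined missingness (for I/O and QC tests)."""
    config = SimulationConfig(
        n_pops=3,
        pop_sizes=(15, 20, 12),
        n_loci=400,
        bn_F=(0.05, 0.1, 0.2),
        fis=(0.0, 0.1, 0.0),
        missing_rate_snp=0.05,
        missing_rate_indiv=0.053,
        seed=7,
    )
    return simulate_dataset(config)
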