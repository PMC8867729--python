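import numpy as np
import pytest

from svjoint.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_truth():
    """One full-size simulated dataset shared across tests (read-only)."""
    return simulate_dataset(SimulationConfig(seed=101))


@pytest.fixture(scope="session")
def small_truth():
    """A small, fast dataset for tests that only need plumbing."""
    config = SimulationConfig(seed=7, n_chrom=2, chrom_len=200_000,
                              n_samples=24, n_longread_samples=4)
    return simulate_dataset(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
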