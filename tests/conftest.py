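import numpy as np
import pytest

from clonevo.model import Region
from clonevo.simulate import SimulationConfig, simulate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Five simulated tumors with read noise, shared across tests."""
    return simulate_cohort(SimulationConfig(n_tumors=5, seed=42))


@pytest.fixture(scope="session")
def noisefree_cohort():
    return simulate_cohort(SimulationConfig(n_tumors=5, seed=7, read_noise=False))


@pytest.fixture()
def region():
    return Region("R1", "T1", purity=0.6, ploidy=2.0, mean_depth=500.0)
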