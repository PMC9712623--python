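import numpy as np
import pytest

from tepra.motifs import dbp_motif, jun_motif
from tepra.synthetic_data import SimulationParams, simulate_subfamily


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    """A scaled-down subfamily for fast unit tests."""
    return SimulationParams(seed=11, root_length=240, n_transposition_leaves=6)


@pytest.fixture(scope="session")
def small_subfamily(small_params):
    return simulate_subfamily(small_params)


@pytest.fixture(scope="session")
def jun():
    return jun_motif()


@pytest.fixture(scope="session")
def dbp():
    return dbp_motif()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
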