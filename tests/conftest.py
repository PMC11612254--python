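import numpy as np
import pytest

from casomics.scoring import load_blosum100
from casomics.simulate import (
    SimulationConfig,
    simulate_multiomics,
    simulate_variant_pair,
)


@pytest.fixture(scope="session")
def blosum():
    return load_blosum100()


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def variant_pair(sim_config):
    return simulate_variant_pair(sim_config)


@pytest.fixture(scope="session")
def multiomics(sim_config):
    return simulate_multiomics(sim_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
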