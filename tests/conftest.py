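import numpy as np
import pytest

from culturesim import PayoffTable, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240686)


@pytest.fixture
def table():
    """Small payoff table with a fixed seed."""
    return PayoffTable(branch_count=10, seed=42)


@pytest.fixture
def base_config():
    """Reference parameter set on a sparse random network."""
    return SimConfig(seed=1, network_family="erdos_renyi", mean_degree=1.0)
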