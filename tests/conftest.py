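import numpy as np
import pytest

from dfle import SimulationConfig, default_schema, simulate_dataset


@pytest.fixture(scope="session")
def schema():
    """Five-year groups 65-94 plus open 95+."""
    return default_schema()


@pytest.fixture(scope="session")
def small_deterministic_dataset():
    """Deterministic 12-region dataset shared across tests."""
    cfg = SimulationConfig(n_regions=12, seed=11, deterministic=True)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
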