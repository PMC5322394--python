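import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete simulated study shared across tests."""
    from crowdscore.crowd_sim import SimulationConfig, simulate_dataset

    config = SimulationConfig(n_patients=80, n_contributors=40)
    return config, simulate_dataset(config, seed=11)
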