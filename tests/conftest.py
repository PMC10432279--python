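import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset():
    """One desk-scale simulated community shared across tests."""
    from paleokin.simulate import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(seed=7, n_generations=4, n_snps=30_000, mean_offspring=3.0)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
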