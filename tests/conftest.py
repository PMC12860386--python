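import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """One moderately structured simulated dataset shared across tests."""
    import plmmkit as pk

    spec = pk.SimSpec(n_samples=80, n_features=200, eta_true=0.6, seed=12)
    g, y, truth, design = pk.simulate_dataset(spec)
    return g, y, truth, design


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
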