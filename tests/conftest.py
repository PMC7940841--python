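import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def rank4_fixture(rng):
    """Noise-free rank-4 genes-by-samples matrix with separated blocks."""
    p, n, k = 200, 40, 4
    U = rng.normal(size=(p, k)) * np.array([10.0, 7.0, 4.0, 2.0])
    V, _ = np.linalg.qr(rng.normal(size=(n, k)))
    return U @ V.T


@pytest.fixture(scope="session")
def sim06():
    """One sigma^2 = 0.6 simulated dataset shared across solver tests."""
    from pl21gpca import simulate

    return simulate(noise_variance=0.6, seed=7)
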