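import numpy as np
import pytest

from chromaflow import EstimatorConfig, generate_gaussian_set


def correlated_cov(rho: float, d: int = 3) -> np.ndarray:
    cov = np.full((d, d), rho)
    np.fill_diagonal(cov, 1.0)
    return cov


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def gaussian_rho06():
    """10^4 samples of a 3D Gaussian with pairwise correlation 0.6."""
    return generate_gaussian_set(10_000, np.zeros(3), correlated_cov(0.6),
                                 seed=42)


@pytest.fixture(scope="session")
def estimator_config():
    return EstimatorConfig()
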