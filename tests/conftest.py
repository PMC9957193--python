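import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hybridpred import SamplerSettings, simulate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A small but structurally complete simulated dataset."""
    return simulate_dataset(
        n_males=4,
        n_females=12,
        n_markers=80,
        n_environments=2,
        n_hybrids_per_env=16,
        overlap_fraction=0.25,
        seed=42,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The default-configuration dataset (study-condition mimic)."""
    return simulate_dataset(seed=7)


@pytest.fixture
def quick_sampler():
    """Short chains for structural tests (not for accuracy assertions)."""
    return SamplerSettings(n_iter=300, burn_in=100, thin=2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_psd(rng: np.random.Generator, n: int) -> np.ndarray:
    A = rng.standard_normal((n, max(n, 2)))
    K = A @ A.T / A.shape[1]
    return (K + K.T) / 2.0
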