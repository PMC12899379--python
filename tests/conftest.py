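import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fbam.spectral import SpectralEstimateSet, fourier_frequencies

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def make_spectra(power: np.ndarray, T: int | None = None) -> SpectralEstimateSet:
    """Wrap an arbitrary (K, M) power matrix as a SpectralEstimateSet."""
    power = np.atleast_2d(np.asarray(power, dtype=float))
    M = power.shape[1]
    if T is None:
        T = 2 * (M + 1)
    assert T // 2 - 1 == M
    return SpectralEstimateSet(
        frequencies=fourier_frequencies(T), power=power, n_tapers=1, T=T
    )


@pytest.fixture
def spectra_factory():
    return make_spectra
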