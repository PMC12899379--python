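"""Synthetic data generators: the three study designs used for validation.

Three families of replicated stationary series, each with three
subpopulations of known membership and closed-form true spectra:

* **Model 1** — piecewise-smooth spectra: three plateaus per group joined by
  cubic transitions of half-width 0.025, with per-replicate plateau levels
  jittered uniformly within +-2 of the group levels.  Group boundaries are
  (0.1, 0.25), (0.2, 0.3), (0.25, 0.4) cycles/sample with group plateau
  levels (15, 7.5, 2), (25, 12.5, 4), (35, 17.5, 6).  Series are drawn by
  Gaussian spectral synthesis, whose expected periodogram equals the target
  spectrum.

* **Model 2 (a/b/c)** — AR(2) processes parameterized by spectral peak
  location psi and bandwidth ell via ``phi1 = 2 cos(2 pi psi) exp(-ell)``,
  ``phi2 = -exp(-2 ell)``, innovation sd 2.25.  Variants a/b/c place the
  three group peaks at (0.23, 0.25, 0.27), (0.21, 0.25, 0.29),
  (0.19, 0.25, 0.31) — increasing separation — with per-replicate peaks
  drawn uniformly within +-0.02 of the group peak and bandwidths within
  +-0.005 of 0.15 (variant a; outer groups use 0.155 in b and 0.165 in c).

* **Model 3** — sums of two independent AR(2) components: a common broad
  low-frequency peak (psi = 0, bandwidth U[0.48, 0.52], sd 2.5) plus a
  group-specific mid-frequency peak (group peaks U[0.2, 0.26, 0.32 +- 0.015],
  bandwidths 0.05 / 0.065 / 0.095, sd 2), so groups differ over only part of
  the frequency range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .exceptions import FBAMError
from .spectral import TimeSeriesSet, fourier_frequencies

__all__ = [
    "Model1Spec",
    "AR2PeakSpec",
    "SimOutput",
    "ar2_coefficients",
    "ar2_spectrum",
    "ar2_variance",
    "simulate_ar2",
    "model1_true_spectrum",
    "simulate_from_spectrum",
    "generate",
    "MODEL_IDS",
]

MODEL_IDS = ("1", "2a", "2b", "2c", "3")

AR_BURN_IN = 500  # |phi2| <= e^{-0.1} in every spec, so transients die well within this


@dataclass(frozen=True)
class Model1Spec:
    """Piecewise-smooth spectrum specification for one group."""

    boundaries: tuple[float, float]
    levels: tuple[float, float, float]
    level_jitter: float = 2.0
    transition_halfwidth: float = 0.025

    def __post_init__(self) -> None:
        b1, b2 = self.boundaries
        h = self.transition_halfwidth
        if not 0 < b1 < b2 < 0.5:
            raise FBAMError("boundaries must satisfy 0 < b1 < b2 < 0.5")
        if b1 + h > b2 - h:
            raise FBAMError("transition windows overlap")


#: The three groups of Model 1.
MODEL1_GROUPS = (
    Model1Spec(boundaries=(0.1, 0.25), levels=(15.0, 7.5, 2.0)),
    Model1Spec(boundaries=(0.2, 0.3), levels=(25.0, 12.5, 4.0)),
    Model1Spec(boundaries=(0.25, 0.4), levels=(35.0, 17.5, 6.0)),
)


@dataclass(frozen=True)
class AR2PeakSpec:
    """AR(2) parameterized by spectral peak location and bandwidth."""

    peak_location: float
    bandwidth: float
    innovation_sd: float

    def coefficients(self) -> tuple[float, float]:
        return ar2_coefficients(self.peak_location, self.bandwidth)


@dataclass
class SimOutput:
    """Generated data plus ground truth for evaluation."""

    data: TimeSeriesSet
    true_labels: np.ndarray
    true_spectra: np.ndarray  # (K, M) on the Fourier grid
    true_boundaries: list[tuple[float, float]] | None = None
    manifest: dict = field(default_factory=dict)


def ar2_coefficients(psi: float, ell: float) -> tuple[float, float]:
    """AR(2) coefficients with a spectral peak near frequency ``psi``.

    ``phi1 = 2 cos(2 pi psi) exp(-ell)``, ``phi2 = -exp(-2 ell)``; always
    stationary for ``ell > 0``.
    """
    if not 0 <= psi < 0.5:
        raise FBAMError("peak location must lie in [0, 0.5)")
    if ell <= 0:
        raise FBAMError("bandwidth must be positive")
    return 2.0 * math.cos(2.0 * math.pi * psi) * math.exp(-ell), -math.exp(-2.0 * ell)


def _check_stationary(phi1: float, phi2: float) -> None:
    if not (abs(phi2) < 1 and phi1 + phi2 < 1 and phi2 - phi1 < 1):
        raise FBAMError(f"nonstationary AR(2) coefficients ({phi1}, {phi2})")


def ar2_spectrum(
    phi1: float, phi2: float, sigma: float, frequencies: np.ndarray
) -> np.ndarray:
    """Closed-form AR(2) spectrum ``sigma^2 / |1 - phi1 z - phi2 z^2|^2``,
    ``z = exp(-2 pi i omega)``."""
    _check_stationary(phi1, phi2)
    omega = np.asarray(frequencies, dtype=float)
    z = np.exp(-2j * np.pi * omega)
    return sigma**2 / np.abs(1.0 - phi1 * z - phi2 * z * z) ** 2


def ar2_variance(phi1: float, phi2: float, sigma: float) -> float:
    """Stationary variance of an AR(2) process (Yule-Walker)."""
    _check_stationary(phi1, phi2)
    return (
        sigma**2 * (1 - phi2) / ((1 + phi2) * ((1 - phi2) ** 2 - phi1**2))
    )


def simulate_ar2(
    phi1: float, phi2: float, sigma: float, T: int, rng: np.random.Generator
) -> np.ndarray:
    """AR(2) recursion with Gaussian innovations; 500-sample burn-in discarded."""
    _check_stationary(phi1, phi2)
    eps = sigma * rng.standard_normal(T + AR_BURN_IN)
    x = lfilter([1.0], [1.0, -phi1, -phi2], eps)
    return x[AR_BURN_IN:]


def _smoothstep(u: np.ndarray) -> np.ndarray:
    return u * u * (3.0 - 2.0 * u)


def model1_true_spectrum(
    spec: Model1Spec,
    frequencies: np.ndarray,
    rng: np.random.Generator | None = None,
    levels: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """One replicate's piecewise-smooth spectrum on an arbitrary grid.

    Plateau levels are ``levels`` if given, otherwise drawn uniformly within
    ``+- level_jitter`` of the group levels (requires ``rng``).  Plateaus are
    joined by cubic (Hermite smoothstep) transitions with zero slope at both
    transition endpoints, so the value at each boundary midpoint is the mean
    of the two adjacent plateau levels.
    """
    if levels is None:
        if rng is None:
            raise FBAMError("either levels or rng must be provided")
        base = np.asarray(spec.levels)
        levels = tuple(rng.uniform(base - spec.level_jitter, base + spec.level_jitter))
    omega = np.asarray(frequencies, dtype=float)
    h = spec.transition_halfwidth
    g = np.full_like(omega, levels[0])
    for i, b in enumerate(spec.boundaries):
        lo, hi = b - h, b + h
        in_trans = (omega >= lo) & (omega < hi)
        u = (omega[in_trans] - lo) / (2.0 * h)
        g[in_trans] = levels[i] + (levels[i + 1] - levels[i]) * _smoothstep(u)
        g[omega >= hi] = levels[i + 1]
    return g


def simulate_from_spectrum(
    g: np.ndarray, T: int, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian spectral synthesis of a series with target spectrum ``g``.

    ``X_t = sum_m sqrt(2 g(omega_m) / T) (A_m cos(2 pi omega_m t)
    + B_m sin(2 pi omega_m t))`` with i.i.d. standard normal A, B over the
    Fourier grid ``m = 1..floor(T/2)-1``; the expected periodogram equals g.
    """
    g = np.asarray(g, dtype=float)
    M = T // 2 - 1
    if g.shape != (M,):
        raise FBAMError(f"need g on the Fourier grid of size {M}")
    if np.any(g < 0):
        raise FBAMError("spectrum must be nonnegative")
    amp = np.sqrt(2.0 * g / T)
    A = rng.standard_normal(M) * amp
    B = rng.standard_normal(M) * amp
    # X_t = Re FFT trick: build the complex sequence c_m = A_m - i B_m and
    # evaluate sum_m (A_m cos + B_m sin) = Re sum_m c_m e^{2 pi i m t / T}
    c = np.zeros(T, dtype=complex)
    c[1 : M + 1] = A - 1j * B
    return np.fft.ifft(c).real * T


def _generate_model1(
    K_j: int, T: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list, dict]:
    freqs = fourier_frequencies(T)
    series, spectra, drawn = [], [], []
    for spec in MODEL1_GROUPS:
        for _ in range(K_j):
            base = np.asarray(spec.levels)
            levels = tuple(
                rng.uniform(base - spec.level_jitter, base + spec.level_jitter)
            )
            g = model1_true_spectrum(spec, freqs, levels=levels)
            series.append(simulate_from_spectrum(g, T, rng))
            spectra.append(g)
            drawn.append({"levels": list(levels)})
    boundaries = [s.boundaries for s in MODEL1_GROUPS]
    manifest = {"model": "1", "replicates": drawn, "boundaries": boundaries}
    return np.asarray(series), np.asarray(spectra), boundaries, manifest


_MODEL2_PEAKS = {"2a": (0.23, 0.25, 0.27), "2b": (0.21, 0.25, 0.29), "2c": (0.19, 0.25, 0.31)}
_MODEL2_BANDWIDTH = {"2a": (0.15, 0.15, 0.15), "2b": (0.155, 0.15, 0.155), "2c": (0.165, 0.15, 0.165)}
_MODEL2_SD = 2.25

_MODEL3_PEAKS = (0.2, 0.26, 0.32)
_MODEL3_BANDWIDTHS = (0.05, 0.065, 0.095)
_MODEL3_LF = {"bandwidth_range": (0.48, 0.52), "sd": 2.5}
_MODEL3_MF_SD = 2.0


def _generate_model2(
    model: str, K_j: int, T: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, dict]:
    freqs = fourier_frequencies(T)
    series, spectra, drawn = [], [], []
    for psi_j, ell_j in zip(_MODEL2_PEAKS[model], _MODEL2_BANDWIDTH[model]):
        for _ in range(K_j):
            psi = rng.uniform(psi_j - 0.02, psi_j + 0.02)
            ell = rng.uniform(ell_j - 0.005, ell_j + 0.005)
            phi1, phi2 = ar2_coefficients(psi, ell)
            series.append(simulate_ar2(phi1, phi2, _MODEL2_SD, T, rng))
            spectra.append(ar2_spectrum(phi1, phi2, _MODEL2_SD, freqs))
            drawn.append({"psi": psi, "bandwidth": ell})
    manifest = {"model": model, "replicates": drawn}
    return np.asarray(series), np.asarray(spectra), manifest


def _generate_model3(
    K_j: int, T: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, dict]:
    freqs = fourier_frequencies(T)
    lo, hi = _MODEL3_LF["bandwidth_range"]
    sd1 = _MODEL3_LF["sd"]
    series, spectra, drawn = [], [], []
    for psi_j, ell_j in zip(_MODEL3_PEAKS, _MODEL3_BANDWIDTHS):
        for _ in range(K_j):
            ell1 = rng.uniform(lo, hi)
            a1, a2 = ar2_coefficients(0.0, ell1)
            psi2 = rng.uniform(psi_j - 0.015, psi_j + 0.015)
            b1, b2 = ar2_coefficients(psi2, ell_j)
            x = simulate_ar2(a1, a2, sd1, T, rng) + simulate_ar2(
                b1, b2, _MODEL3_MF_SD, T, rng
            )
            series.append(x)
            spectra.append(
                ar2_spectrum(a1, a2, sd1, freqs)
                + ar2_spectrum(b1, b2, _MODEL3_MF_SD, freqs)
            )
            drawn.append({"lf_bandwidth": ell1, "psi": psi2, "mf_bandwidth": ell_j})
    manifest = {"model": "3", "replicates": drawn}
    return np.asarray(series), np.asarray(spectra), manifest


def generate(
    model: str, K_j: int, T: int, seed: int | np.random.Generator = 0
) -> SimOutput:
    """Generate 3 groups x K_j series of length T from one model family.

    Returns the series, the true group labels, the true spectra on the
    Fourier grid, true band boundaries (Model 1 only), and a manifest of the
    replicate-level drawn parameters.
    """
    model = str(model)
    if model not in MODEL_IDS:
        raise FBAMError(f"unknown model {model!r}; choose from {MODEL_IDS}")
    if K_j < 1 or T < 64:
        raise FBAMError("need K_j >= 1 and T >= 64")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    boundaries = None
    if model == "1":
        values, spectra, boundaries, manifest = _generate_model1(K_j, T, rng)
    elif model in ("2a", "2b", "2c"):
        values, spectra, manifest = _generate_model2(model, K_j, T, rng)
    else:
        values, spectra, manifest = _generate_model3(K_j, T, rng)
    labels = np.repeat(np.arange(3), K_j)
    ids = [f"g{j + 1}k{k + 1}" for j in range(3) for k in range(K_j)]
    data = TimeSeriesSet(values=values, series_ids=ids)
    return SimOutput(
        data=data,
        true_labels=labels,
        true_spectra=spectra,
        true_boundaries=boundaries,
        manifest=manifest,
    )
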