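"""Band partitions, clusterings, collapsed measures, and the least-squares loss.

A band partition splits the Fourier grid ``{1..M}`` into L contiguous
half-open bands.  Internally cuts are stored as 0-based offsets into the
frequency axis: band ``l`` covers columns ``[b_l, b_{l+1})`` of the power
matrix where ``b_0 = 0`` and ``b_L = M``.  Every band must contain at least
``w_min`` Fourier frequencies (default 5): band averages and the
band-similarity ratio are degenerate on near-empty bands.

The loss of a (clustering, partitions) solution is

    L = (1/T) * sum_j sum_{k in group j} sum_l sum_{omega in band jl}
        (g_k(omega) - ybar_{j.l})**2

where ``ybar_{j.l}`` is the cross-replicate mean of the band-average power.
It plays the role of a K-means objective whose cluster centers are
piecewise-constant (step-function) approximations of the member spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import FBAMError, InvalidPartitionError
from .spectral import SpectralEstimateSet

__all__ = [
    "DEFAULT_W_MIN",
    "BandPartition",
    "Clustering",
    "Solution",
    "CollapsedMeasures",
    "collapsed_power",
    "fbam_loss",
    "refine_partition",
    "mean_collapsed_spectrum",
]

DEFAULT_W_MIN = 5


@dataclass(frozen=True)
class BandPartition:
    """L contiguous frequency bands over a grid of M Fourier frequencies.

    Parameters
    ----------
    cuts : tuple of int
        The L-1 interior band boundaries as 0-based offsets into the
        frequency axis, strictly increasing.
    n_freq : int
        M, the number of Fourier frequencies.
    w_min : int
        Minimum band width in grid points.
    """

    cuts: tuple[int, ...]
    n_freq: int
    w_min: int = DEFAULT_W_MIN

    def __post_init__(self) -> None:
        cuts = tuple(int(c) for c in self.cuts)
        object.__setattr__(self, "cuts", cuts)
        if self.w_min < 1:
            raise InvalidPartitionError("w_min must be >= 1")
        bounds = (0,) + cuts + (self.n_freq,)
        widths = np.diff(bounds)
        if np.any(widths < self.w_min):
            raise InvalidPartitionError(
                f"every band needs >= {self.w_min} frequencies; got widths {list(widths)}"
            )

    @property
    def n_bands(self) -> int:
        return len(self.cuts) + 1

    @property
    def bounds(self) -> np.ndarray:
        """Full boundary vector ``[0, c_1, ..., c_{L-1}, M]``."""
        return np.asarray((0,) + self.cuts + (self.n_freq,), dtype=int)

    @property
    def band_sizes(self) -> np.ndarray:
        return np.diff(self.bounds)

    def cut_frequencies(self, T: int) -> np.ndarray:
        """Interior boundaries in cycles/sample (``(offset + 1) / T``)."""
        return (np.asarray(self.cuts) + 1) / T


@dataclass(frozen=True)
class Clustering:
    """Assignment of K replicates to J nonempty subpopulations (0-based)."""

    labels: np.ndarray
    n_groups: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        J = self.n_groups
        if labels.ndim != 1:
            raise FBAMError("labels must be a vector")
        if labels.min(initial=0) < 0 or (labels.size and labels.max() >= J):
            raise FBAMError(f"labels must lie in [0, {J})")
        present = np.bincount(labels, minlength=J) > 0
        if not present.all():
            missing = np.flatnonzero(~present)
            raise FBAMError(f"empty subpopulation(s): {missing.tolist()}")

    @property
    def n_series(self) -> int:
        return self.labels.size

    def members(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.labels == j)


@dataclass
class Solution:
    """A clustering plus one band partition per subpopulation (a GA chromosome).

    All partitions share the same number of bands L.  ``loss`` caches the
    least-squares objective with respect to the spectra it was last evaluated
    on; :func:`fbam_loss` refreshes it.
    """

    clustering: Clustering
    partitions: list[BandPartition]
    loss: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.partitions) != self.clustering.n_groups:
            raise FBAMError("need one partition per subpopulation")
        Ls = {p.n_bands for p in self.partitions}
        if len(Ls) != 1:
            raise FBAMError("all subpopulations must use the same number of bands")
        Ms = {p.n_freq for p in self.partitions}
        if len(Ms) != 1:
            raise FBAMError("partitions disagree on the frequency grid size")

    @property
    def n_groups(self) -> int:
        return self.clustering.n_groups

    @property
    def n_bands(self) -> int:
        return self.partitions[0].n_bands


@dataclass
class CollapsedMeasures:
    """Band-average power for one subpopulation.

    ``per_replicate[k, l]`` is the mean of replicate k's spectrum over band l;
    ``per_band_mean[l]`` is its cross-replicate mean; ``band_sizes[l]`` the
    number of Fourier frequencies in band l.
    """

    per_replicate: np.ndarray
    per_band_mean: np.ndarray
    band_sizes: np.ndarray


def collapsed_power(power: np.ndarray | SpectralEstimateSet, partition: BandPartition) -> CollapsedMeasures:
    """Band averages per replicate and their cross-replicate means.

    Parameters
    ----------
    power : ndarray (K_j, M) or SpectralEstimateSet
        Spectra of the replicates assigned to one subpopulation.
    """
    if isinstance(power, SpectralEstimateSet):
        power = power.power
    power = np.atleast_2d(np.asarray(power, dtype=float))
    if power.shape[1] != partition.n_freq:
        raise InvalidPartitionError("partition grid size does not match spectra")
    bounds = partition.bounds
    sums = np.add.reduceat(power, bounds[:-1], axis=1)
    per_replicate = sums / partition.band_sizes
    return CollapsedMeasures(
        per_replicate=per_replicate,
        per_band_mean=per_replicate.mean(axis=0),
        band_sizes=partition.band_sizes.copy(),
    )


def fbam_loss(spectra: SpectralEstimateSet, solution: Solution) -> float:
    """The scaled least-squares objective of a solution.

    ``(1/T) * sum over groups, members, bands and in-band frequencies of the
    squared deviation of the member spectrum from the group's mean band
    level``.  The cached ``solution.loss`` is refreshed.
    """
    power = spectra.power
    if solution.partitions[0].n_freq != power.shape[1]:
        raise FBAMError("solution frequency grid does not match the spectra")
    if solution.clustering.n_series != power.shape[0]:
        raise FBAMError("solution labels do not match the number of spectra")
    total = 0.0
    for j in range(solution.n_groups):
        rows = power[solution.clustering.members(j)]
        part = solution.partitions[j]
        cm = collapsed_power(rows, part)
        step = mean_collapsed_spectrum(cm, part)
        total += float(np.sum((rows - step[None, :]) ** 2))
    loss = total / spectra.T
    solution.loss = loss
    return loss


def refine_partition(partition: BandPartition, extra_cut: int) -> BandPartition:
    """Insert one additional interior cut, producing an (L+1)-band partition."""
    extra_cut = int(extra_cut)
    if extra_cut in partition.cuts:
        raise InvalidPartitionError(f"cut {extra_cut} already present")
    cuts = tuple(sorted(partition.cuts + (extra_cut,)))
    return BandPartition(cuts=cuts, n_freq=partition.n_freq, w_min=partition.w_min)


def mean_collapsed_spectrum(cm: CollapsedMeasures, partition: BandPartition) -> np.ndarray:
    """The step function on the full grid whose levels are the band means."""
    return np.repeat(cm.per_band_mean, partition.band_sizes)
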