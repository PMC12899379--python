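"""Band- and subpopulation-similarity criteria and (J, L) selection.

Two cluster-validation-style ratios drive model selection:

* **Band similarity** R1 compares adjacent bands of one subpopulation: the sum
  of the two within-band root-sums-of-squares around each band's mean level,
  divided by the root-sum-of-squares around the pooled (width-weighted) mean
  of the two bands.  Values near 0 indicate the two bands carry genuinely
  different levels; values near (or above) 1 indicate an unnecessary split.

* **Subpopulation similarity** R2 compares two subpopulations: the sum of the
  per-capita within-group spectral variabilities around each group's mean
  collapsed (step-function) spectrum, divided by the Euclidean distance
  between the two step functions on the full grid.

These aggregate into S1 (average band similarity, normalizer 1/(J*L) over the
J*(L-1) adjacent pairs) and S2 (mean over groups of the largest similarity to
any other group).  Over a grid of fitted (J, L) solutions, the joint rule
rescales each criterion by its maximum over the grid (so both have max 1) and
picks the entry minimizing their sum; single-axis modes minimize S1 or S2
alone.  Degenerate ratios (zero denominators) raise inside the similarity
operations but are mapped to +inf during selection so such solutions are
never chosen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import BandPartition, Solution, collapsed_power, mean_collapsed_spectrum
from .exceptions import (
    DegenerateCriterionError,
    FBAMError,
    SelectionError,
    UndefinedCriterionError,
)
from .spectral import SpectralEstimateSet

__all__ = [
    "band_similarity",
    "subpop_similarity",
    "S1",
    "S2",
    "GridEntry",
    "CriterionTable",
    "select",
]


def band_similarity(
    power: np.ndarray | SpectralEstimateSet,
    partition: BandPartition,
    l: int,
) -> float:
    """Similarity ratio between band ``l`` and band ``l+1`` (0-based).

    Parameters
    ----------
    power : ndarray (K_j, M) or SpectralEstimateSet
        Spectra of one subpopulation's replicates.
    l : int
        Index of the left band, ``0 <= l <= L-2``.
    """
    if isinstance(power, SpectralEstimateSet):
        power = power.power
    power = np.atleast_2d(np.asarray(power, dtype=float))
    L = partition.n_bands
    if not 0 <= l <= L - 2:
        raise FBAMError(f"band pair index l={l} out of range for L={L}")
    b = partition.bounds
    left = power[:, b[l] : b[l + 1]]
    right = power[:, b[l + 1] : b[l + 2]]
    y_l = left.mean()
    y_r = right.mean()
    num = math.sqrt(np.sum((left - y_l) ** 2)) + math.sqrt(np.sum((right - y_r) ** 2))
    w_l, w_r = left.shape[1], right.shape[1]
    mu = (w_l * y_l + w_r * y_r) / (w_l + w_r)
    den_sq = float(np.sum((left - mu) ** 2) + np.sum((right - mu) ** 2))
    if den_sq == 0.0:
        raise DegenerateCriterionError(
            "all values identical across the two bands; band similarity undefined"
        )
    return num / math.sqrt(den_sq)


def _within_group_rss(power: np.ndarray, partition: BandPartition) -> float:
    """sum_k sum_l sum_{omega in band l} (g_k - ybar_l)^2 for one group."""
    cm = collapsed_power(power, partition)
    step = mean_collapsed_spectrum(cm, partition)
    return float(np.sum((power - step[None, :]) ** 2))


def subpop_similarity(
    power_i: np.ndarray | SpectralEstimateSet,
    power_j: np.ndarray | SpectralEstimateSet,
    partition_i: BandPartition,
    partition_j: BandPartition,
) -> float:
    """Similarity ratio between two subpopulations.

    Per-capita within-group root-sums-of-squares around each group's mean
    collapsed spectrum, summed, divided by the Euclidean distance between the
    two mean collapsed spectra on the full Fourier grid.
    """
    if isinstance(power_i, SpectralEstimateSet):
        power_i = power_i.power
    if isinstance(power_j, SpectralEstimateSet):
        power_j = power_j.power
    power_i = np.atleast_2d(np.asarray(power_i, dtype=float))
    power_j = np.atleast_2d(np.asarray(power_j, dtype=float))
    if partition_i.n_bands != partition_j.n_bands:
        raise FBAMError("partitions must share the number of bands")
    K_i, K_j = power_i.shape[0], power_j.shape[0]
    num = math.sqrt(_within_group_rss(power_i, partition_i) / K_i) + math.sqrt(
        _within_group_rss(power_j, partition_j) / K_j
    )
    step_i = mean_collapsed_spectrum(collapsed_power(power_i, partition_i), partition_i)
    step_j = mean_collapsed_spectrum(collapsed_power(power_j, partition_j), partition_j)
    den_sq = float(np.sum((step_i - step_j) ** 2))
    if den_sq == 0.0:
        raise DegenerateCriterionError(
            "identical mean collapsed spectra; subpopulation similarity undefined"
        )
    return num / math.sqrt(den_sq)


def S1(
    spectra: SpectralEstimateSet, solution: Solution, normalizer: str = "pairs"
) -> float:
    """Average band similarity over the J*(L-1) adjacent-band pairs.

    ``normalizer="pairs"`` (default) divides the summed ratios by the number
    of terms, J*(L-1), so S1 is a plain average and for identical per-pair
    similarity r, S1 = r.  ``normalizer="JL"`` divides by J*L instead, which
    additionally discounts candidate models by (L-1)/L and therefore leans
    toward fewer bands; with it, identical r gives S1 = r*(L-1)/L.  The
    plain average is the default because the J*L variant systematically
    prefers the 2-band model even on noiseless, well-separated 3-plateau
    spectra where the band structure is unambiguous.
    """
    L = solution.n_bands
    if L < 2:
        raise UndefinedCriterionError("band similarity requires L >= 2")
    if normalizer not in ("pairs", "JL"):
        raise FBAMError(f"unknown normalizer {normalizer!r}")
    J = solution.n_groups
    total = 0.0
    for j in range(J):
        rows = spectra.power[solution.clustering.members(j)]
        part = solution.partitions[j]
        for l in range(L - 1):
            total += band_similarity(rows, part, l)
    return total / (J * (L - 1) if normalizer == "pairs" else J * L)


def _max_mean_aggregate(pairwise: np.ndarray) -> float:
    """Mean over rows of the row-wise max off-diagonal entry."""
    J = pairwise.shape[0]
    mask = ~np.eye(J, dtype=bool)
    return float(np.mean([pairwise[j][mask[j]].max() for j in range(J)]))


def S2(spectra: SpectralEstimateSet, solution: Solution) -> float:
    """Mean over groups of the worst-case similarity to any other group."""
    J = solution.n_groups
    if J < 2:
        raise UndefinedCriterionError("subpopulation similarity requires J >= 2")
    groups = [spectra.power[solution.clustering.members(j)] for j in range(J)]
    pairwise = np.zeros((J, J))
    for i in range(J):
        for j in range(i + 1, J):
            r = subpop_similarity(
                groups[i], groups[j], solution.partitions[i], solution.partitions[j]
            )
            pairwise[i, j] = pairwise[j, i] = r
    return _max_mean_aggregate(pairwise)


@dataclass
class GridEntry:
    """One fitted (J, L) cell: the minimizing solution and its criteria.

    ``s1``/``s2`` are None where undefined (L = 1 / J = 1) and +inf where the
    data produced a degenerate (zero-denominator) ratio.
    """

    solution: Solution
    loss: float
    s1: float | None = None
    s2: float | None = None


@dataclass
class CriterionTable:
    """The grid of fitted solutions with their selection criteria."""

    entries: dict[tuple[int, int], GridEntry] = field(default_factory=dict)

    @staticmethod
    def _finite_max(values: list[float]) -> float | None:
        finite = [v for v in values if v is not None and math.isfinite(v)]
        return max(finite) if finite else None

    @property
    def a1(self) -> float | None:
        """Max finite S1 over the grid (scale normalizer)."""
        return self._finite_max([e.s1 for e in self.entries.values()])

    @property
    def a2(self) -> float | None:
        """Max finite S2 over the grid (scale normalizer)."""
        return self._finite_max([e.s2 for e in self.entries.values()])

    def scaled_sum(self, key: tuple[int, int]) -> float:
        """``S1/a1 + S2/a2`` for one entry; +inf if either piece is degenerate."""
        e = self.entries[key]
        if e.s1 is None or e.s2 is None:
            raise UndefinedCriterionError(f"joint criterion undefined at {key}")
        a1, a2 = self.a1, self.a2
        out = 0.0
        for s, a in ((e.s1, a1), (e.s2, a2)):
            if not math.isfinite(s):
                return math.inf
            if a:  # a == 0 only if every entry has s == 0; the term is then 0
                out += s / a
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (J, L), e in sorted(self.entries.items()):
            try:
                ss = self.scaled_sum((J, L))
            except UndefinedCriterionError:
                ss = None
            rows.append(
                {"J": J, "L": L, "loss": e.loss, "S1": e.s1, "S2": e.s2, "scaled_sum": ss}
            )
        return pd.DataFrame(rows)


def compute_criteria(spectra: SpectralEstimateSet, table: CriterionTable) -> None:
    """Fill S1/S2 for every entry, mapping degenerate ratios to +inf."""
    for entry in table.entries.values():
        sol = entry.solution
        if sol.n_bands >= 2:
            try:
                entry.s1 = S1(spectra, sol)
            except DegenerateCriterionError:
                entry.s1 = math.inf
        if sol.n_groups >= 2:
            try:
                entry.s2 = S2(spectra, sol)
            except DegenerateCriterionError:
                entry.s2 = math.inf


def select(
    table: CriterionTable, mode: str = "joint"
) -> tuple[int, int, Solution]:
    """Pick the grid entry minimizing the requested criterion.

    Modes: ``bands_only`` (minimize S1; J held fixed by the grid),
    ``subpops_only`` (minimize S2), ``joint`` (minimize S1/a1 + S2/a2 over
    entries with J >= 2 and L >= 2).  Ties break toward smaller J, then
    smaller L (parsimony).
    """
    if not table.entries:
        raise SelectionError("empty criterion grid")
    if mode not in ("bands_only", "subpops_only", "joint"):
        raise FBAMError(f"unknown selection mode {mode!r}")
    if len(table.entries) == 1:
        ((J, L), entry), = table.entries.items()
        return J, L, entry.solution

    def score(key: tuple[int, int]) -> float | None:
        e = table.entries[key]
        if mode == "bands_only":
            return e.s1
        if mode == "subpops_only":
            return e.s2
        if e.s1 is None or e.s2 is None:
            return None
        return table.scaled_sum(key)

    best_key, best_score = None, math.inf
    for key in sorted(table.entries):  # sorted => ties resolve to smaller (J, L)
        s = score(key)
        if s is not None and s < best_score:
            best_key, best_score = key, s
    if best_key is None:
        raise SelectionError(f"no grid entry admits mode {mode!r}")
    J, L = best_key
    return J, L, table.entries[best_key].solution
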