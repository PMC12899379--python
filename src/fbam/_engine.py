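"""Vectorized kernels for population-based optimization of the loss.

The GA evaluates thousands of candidate solutions per run, so populations are
held as flat integer arrays rather than :class:`~fbam.bands.Solution`
objects: labels as a (P, K) matrix and band boundaries as a (P, J, L+1)
tensor whose rows are full boundary vectors ``[0, c_1, ..., c_{L-1}, M]``.

The loss admits an O(K*L) evaluation per candidate via prefix sums: with
``S_jl`` the sum of in-group, in-band spectral values and ``n_jl`` the number
of summed terms,

    T * loss = sum(g^2) - sum_jl S_jl^2 / n_jl,

because the band mean minimizes the within-band sum of squares.  Prefix sums
of each replicate's spectrum make every ``S_jl`` a difference of two gathered
values.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["SpectraCache", "batch_loss", "mutate_population", "random_population"]


class SpectraCache:
    """Precomputed prefix sums of the (K, M) power matrix."""

    def __init__(self, power: np.ndarray, T: int):
        power = np.asarray(power, dtype=float)
        self.K, self.M = power.shape
        self.T = T
        self.prefix = np.zeros((self.K, self.M + 1))
        np.cumsum(power, axis=1, out=self.prefix[:, 1:])
        self.ssq_total = float(np.sum(power * power))


def batch_loss(cache: SpectraCache, labels: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Loss of every candidate in a population.

    Parameters
    ----------
    labels : (P, K) int array, values in [0, J)
        Every group must be nonempty in every row (the mutation/init repairs
        guarantee this).
    bounds : (P, J, L+1) int array
        Full boundary vectors per candidate and group.
    """
    P, K = labels.shape
    J = bounds.shape[1]
    # boundary vector of each replicate's own group: (P, K, L+1)
    own = bounds[np.arange(P)[:, None], labels]
    vals = cache.prefix[np.arange(K)[None, :, None], own]
    band_sums = np.diff(vals, axis=2)  # (P, K, L)
    onehot = (labels[:, :, None] == np.arange(J)).astype(float)  # (P, K, J)
    S = np.einsum("pkj,pkl->pjl", onehot, band_sums)
    counts = onehot.sum(axis=1)  # (P, J)
    widths = np.diff(bounds, axis=2)  # (P, J, L)
    denom = counts[:, :, None] * widths
    return (cache.ssq_total - (S * S / denom).sum(axis=(1, 2))) / cache.T


def _repair_labels(labels: np.ndarray, J: int, rng: np.random.Generator) -> None:
    """In-place: reassign a random member of the largest group to each empty group."""
    P, K = labels.shape
    counts = np.stack([np.bincount(row, minlength=J) for row in labels])
    bad_rows = np.flatnonzero((counts == 0).any(axis=1))
    for p in bad_rows:
        row = labels[p]
        cnt = np.bincount(row, minlength=J)
        for g in np.flatnonzero(cnt == 0):
            donor = int(np.argmax(cnt))
            members = np.flatnonzero(row == donor)
            row[members[rng.integers(members.size)]] = g
            cnt = np.bincount(row, minlength=J)


def _repair_bounds(bounds: np.ndarray, M: int, w_min: int) -> None:
    """In-place: sort interior cuts, clamp to feasible ranges, enforce w_min.

    For interior cut i (0-based, i = 0..L-2) the feasible range is
    ``[(i+1)*w_min, M - (L-1-i)*w_min]``; a forward pass then enforces
    ``c_i >= c_{i-1} + w_min``.  Always produces a feasible partition when
    ``L * w_min <= M``.
    """
    L = bounds.shape[-1] - 1
    if L < 2:
        return
    interior = bounds[..., 1:-1]
    interior.sort(axis=-1)
    for i in range(L - 1):
        lo = (i + 1) * w_min
        hi = M - (L - 1 - i) * w_min
        np.clip(interior[..., i], lo, hi, out=interior[..., i])
        if i > 0:
            np.maximum(interior[..., i], interior[..., i - 1] + w_min, out=interior[..., i])


def mutate_population(
    labels: np.ndarray,
    bounds: np.ndarray,
    M: int,
    w_min: int,
    p_m: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Entrywise mutation with repair; returns new (labels, bounds) arrays.

    Each label is resampled uniformly over the J groups with probability
    ``p_m``; each interior cut is jittered with probability ``p_m`` by a
    uniform integer offset in ``[-d, d]``, ``d = ceil(0.05 * M)``.
    """
    P, K = labels.shape
    J = bounds.shape[1]
    L = bounds.shape[2] - 1
    out_labels = labels.copy()
    if p_m > 0:
        mask = rng.random((P, K)) < p_m
        resampled = rng.integers(0, J, size=(P, K))
        out_labels[mask] = resampled[mask]
    _repair_labels(out_labels, J, rng)
    out_bounds = bounds.copy()
    if L >= 2 and p_m > 0:
        d = math.ceil(0.05 * M)
        interior = out_bounds[:, :, 1:-1]
        jmask = rng.random(interior.shape) < p_m
        jitter = rng.integers(-d, d + 1, size=interior.shape)
        interior += np.where(jmask, jitter, 0)
        _repair_bounds(out_bounds, M, w_min)
    return out_labels, out_bounds


def random_cuts(M: int, L: int, w_min: int, rng: np.random.Generator) -> np.ndarray:
    """A uniform draw from the feasible interior cut vectors.

    Feasible cut vectors are in bijection with (L-1)-subsets of
    ``{0, ..., M - L*w_min + L - 2}`` via ``c_i = e_i + (i+1)*w_min - i``
    for the sorted subset ``e``.
    """
    if L * w_min > M:
        raise ValueError(f"infeasible: L*w_min = {L * w_min} > M = {M}")
    if L == 1:
        return np.empty(0, dtype=int)
    slack = M - L * w_min
    e = np.sort(rng.choice(slack + L - 1, size=L - 1, replace=False))
    i = np.arange(L - 1)
    return e + (i + 1) * w_min - i


def _group_prefixes(cache: SpectraCache, labels: np.ndarray, J: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-group prefix sums of power and squared power (J, M+1), plus counts."""
    onehot = (labels[:, None] == np.arange(J)).astype(float)  # (K, J)
    G1 = onehot.T @ cache.prefix
    if not hasattr(cache, "_prefix_sq"):
        power_sq_prefix = np.zeros_like(cache.prefix)
        np.cumsum(np.diff(cache.prefix, axis=1) ** 2, axis=1, out=power_sq_prefix[:, 1:])
        cache._prefix_sq = power_sq_prefix
    G2 = onehot.T @ cache._prefix_sq
    return G1, G2, onehot.sum(axis=0)


def _band_ss(G1: np.ndarray, G2: np.ndarray, count: float, a, b) -> np.ndarray:
    """Within-band sum of squares around the band mean for one group.

    ``a``/``b`` may be arrays of candidate boundaries (vectorized scan).
    """
    n = count * (np.asarray(b) - np.asarray(a))
    s = G1[b] - G1[a]
    return (G2[b] - G2[a]) - s * s / n


def polish_solution(
    cache: SpectraCache,
    labels: np.ndarray,
    bounds: np.ndarray,
    w_min: int,
    max_rounds: int = 20,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Coordinate-descent refinement of a single candidate solution.

    Alternates (a) exact relocation of each interior cut to the position
    minimizing the two adjacent bands' within-band sum of squares (scanning
    all feasible positions via prefix sums) and (b) reassignment of every
    replicate to the group whose mean collapsed (step-function) spectrum is
    closest, with empty groups repaired by stealing from the largest group.
    Deterministic; loss is non-increasing across rounds.  Returns the
    polished (labels, bounds, loss).
    """
    labels = labels.copy()
    bounds = bounds.copy()
    J, Lp1 = bounds.shape
    L = Lp1 - 1
    M = int(bounds[0, -1])
    prev = np.inf
    for _ in range(max_rounds):
        # (a) cut relocation, group by group
        G1, G2, counts = _group_prefixes(cache, labels, J)
        if L >= 2:
            for j in range(J):
                for i in range(1, L):
                    a, b = bounds[j, i - 1], bounds[j, i + 1]
                    pos = np.arange(a + w_min, b - w_min + 1)
                    ss = _band_ss(G1[j], G2[j], counts[j], a, pos) + _band_ss(
                        G1[j], G2[j], counts[j], pos, b
                    )
                    bounds[j, i] = pos[int(np.argmin(ss))]
        # (b) label reassignment against the current step functions
        steps = np.empty((J, M))
        for j in range(J):
            widths = np.diff(bounds[j])
            means = (G1[j][bounds[j, 1:]] - G1[j][bounds[j, :-1]]) / (
                counts[j] * widths
            )
            steps[j] = np.repeat(means, widths)
        power = np.diff(cache.prefix, axis=1)  # (K, M)
        costs = ((power[:, None, :] - steps[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(costs, axis=1)
        cnt = np.bincount(labels, minlength=J)
        for g in np.flatnonzero(cnt == 0):
            donor = int(np.argmax(cnt))
            members = np.flatnonzero(labels == donor)
            # deterministic repair: move the member cheapest to relocate
            steal = members[int(np.argmin(costs[members, g]))]
            labels[steal] = g
            cnt = np.bincount(labels, minlength=J)
        loss = batch_loss(cache, labels[None], bounds[None])[0]
        if prev - loss <= 1e-12 * max(abs(prev), 1.0):
            break
        prev = loss
    loss = float(batch_loss(cache, labels[None], bounds[None])[0])
    return labels, bounds, loss


def random_population(
    P: int,
    K: int,
    M: int,
    J: int,
    L: int,
    w_min: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Initial population: uniform labels (repaired) and uniform feasible cuts."""
    labels = rng.integers(0, J, size=(P, K))
    _repair_labels(labels, J, rng)
    bounds = np.empty((P, J, L + 1), dtype=int)
    bounds[:, :, 0] = 0
    bounds[:, :, -1] = M
    for p in range(P):
        for j in range(J):
            bounds[p, j, 1:-1] = random_cuts(M, L, w_min, rng)
    return labels, bounds
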