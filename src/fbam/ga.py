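"""Island-model genetic algorithm for minimizing the band/cluster loss.

The chromosome is the integer label vector (length K) concatenated with one
sorted interior-cut vector (length L-1) per subpopulation.  Offspring arise
by entrywise mutation only; survivor selection is (mu + lambda) truncation
(parents compete with their offspring), followed by an elitist step in which
the previous generation's best chromosome replaces the current worst.
Several islands evolve independently and exchange chromosomes in a ring every
``migration_interval`` generations, which guards against premature
convergence of any single population on this multimodal objective.

A (J, L) grid is fitted cell by cell (optionally in parallel; per-cell and
per-island random streams are derived from the master seed so results are
identical either way), criteria are computed for every fitted cell, and the
selection rule in :mod:`fbam.criteria` picks the final solution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from joblib import Parallel, delayed

from . import _engine
from .bands import DEFAULT_W_MIN, BandPartition, Clustering, Solution
from .criteria import CriterionTable, GridEntry, compute_criteria, select
from .exceptions import FBAMError
from .spectral import SpectralEstimateSet

__all__ = [
    "GAConfig",
    "IslandState",
    "FBAMResult",
    "random_solution",
    "mutate",
    "evolve_island",
    "migrate",
    "run_ga",
    "fit_grid",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GAConfig:
    """Tuning knobs of the genetic algorithm.

    Defaults follow the island setup used throughout: 6 islands of 50
    chromosomes, ring migration of 5 chromosomes every 50 generations.
    ``mutation_prob`` applies independently to every chromosome entry.
    """

    population_size: int = 50
    n_islands: int = 6
    migration_interval: int = 50
    n_migrants: int = 5
    mutation_prob: float = 0.05
    offspring_per_parent: int = 2
    max_generations: int = 500
    stall_generations: int = 100
    seed: int = 0
    w_min: int = DEFAULT_W_MIN
    polish: bool = True

    def __post_init__(self) -> None:
        if self.n_migrants > self.population_size:
            raise FBAMError("n_migrants cannot exceed population_size")
        for name in (
            "population_size",
            "n_islands",
            "migration_interval",
            "n_migrants",
            "offspring_per_parent",
            "max_generations",
            "stall_generations",
            "w_min",
        ):
            if getattr(self, name) < 1:
                raise FBAMError(f"{name} must be positive")
        if not 0 <= self.mutation_prob <= 1:
            raise FBAMError("mutation_prob must lie in [0, 1]")


@dataclass
class IslandState:
    """One island's population, kept as flat arrays sorted by loss ascending."""

    labels: np.ndarray  # (P, K)
    bounds: np.ndarray  # (P, J, L+1)
    losses: np.ndarray  # (P,)
    elite_labels: np.ndarray
    elite_bounds: np.ndarray
    elite_loss: float
    rng: np.random.Generator
    w_min: int = DEFAULT_W_MIN

    @property
    def n_freq(self) -> int:
        return int(self.bounds[0, 0, -1])

    def _solution(self, labels: np.ndarray, bounds: np.ndarray, loss: float) -> Solution:
        J = bounds.shape[0]
        parts = [
            BandPartition(tuple(bounds[j, 1:-1]), self.n_freq, self.w_min)
            for j in range(J)
        ]
        return Solution(Clustering(labels.copy(), J), parts, loss=float(loss))

    @property
    def population(self) -> list[Solution]:
        """The population as Solution objects, sorted by loss ascending."""
        return [
            self._solution(self.labels[p], self.bounds[p], self.losses[p])
            for p in range(self.labels.shape[0])
        ]

    @property
    def elite(self) -> Solution:
        return self._solution(self.elite_labels, self.elite_bounds, self.elite_loss)


def _solution_to_arrays(sol: Solution) -> tuple[np.ndarray, np.ndarray]:
    M = sol.partitions[0].n_freq
    labels = np.asarray(sol.clustering.labels, dtype=int)
    bounds = np.stack([p.bounds for p in sol.partitions])
    assert bounds[0, -1] == M
    return labels, bounds


def random_solution(
    K: int, M: int, J: int, L: int, rng: np.random.Generator, w_min: int = DEFAULT_W_MIN
) -> Solution:
    """A uniformly random feasible solution (all groups nonempty)."""
    if J > K:
        raise FBAMError(f"cannot split K={K} replicates into J={J} nonempty groups")
    if L * w_min > M:
        raise FBAMError(f"L={L} bands of width >= {w_min} do not fit in M={M}")
    labels, bounds = _engine.random_population(1, K, M, J, L, w_min, rng)
    parts = [BandPartition(tuple(bounds[0, j, 1:-1]), M, w_min) for j in range(J)]
    return Solution(Clustering(labels[0], J), parts)


def mutate(parent: Solution, config: GAConfig, rng: np.random.Generator) -> Solution:
    """One mutated offspring of ``parent``; repair guarantees validity."""
    labels, bounds = _solution_to_arrays(parent)
    M = parent.partitions[0].n_freq
    new_labels, new_bounds = _engine.mutate_population(
        labels[None], bounds[None], M, config.w_min, config.mutation_prob, rng
    )
    J = parent.n_groups
    parts = [
        BandPartition(tuple(new_bounds[0, j, 1:-1]), M, config.w_min) for j in range(J)
    ]
    return Solution(Clustering(new_labels[0], J), parts)


def _sort_island(state: IslandState) -> None:
    order = np.argsort(state.losses, kind="stable")
    state.labels = state.labels[order]
    state.bounds = state.bounds[order]
    state.losses = state.losses[order]


def evolve_island(
    state: IslandState, cache: _engine.SpectraCache, config: GAConfig
) -> IslandState:
    """Advance one island by one generation, in place; returns the state.

    Each parent yields ``offspring_per_parent`` mutated offspring; parents
    and offspring are ranked jointly and the best ``population_size`` kept;
    the previous generation's elite then replaces the current worst, and the
    elite is updated.  The elite loss is therefore non-increasing.
    """
    P = state.labels.shape[0]
    M = state.n_freq
    opp = config.offspring_per_parent
    off_labels = np.repeat(state.labels, opp, axis=0)
    off_bounds = np.repeat(state.bounds, opp, axis=0)
    off_labels, off_bounds = _engine.mutate_population(
        off_labels, off_bounds, M, config.w_min, config.mutation_prob, state.rng
    )
    off_losses = _engine.batch_loss(cache, off_labels, off_bounds)
    all_labels = np.concatenate([state.labels, off_labels])
    all_bounds = np.concatenate([state.bounds, off_bounds])
    all_losses = np.concatenate([state.losses, off_losses])
    order = np.argsort(all_losses, kind="stable")
    # survivor selection with duplicate removal: exact copies (common at low
    # mutation rates) must not crowd out distinct chromosomes
    seen: set = set()
    keep: list[int] = []
    for idx in order:
        key = (all_labels[idx].tobytes(), all_bounds[idx].tobytes())
        if key not in seen:
            seen.add(key)
            keep.append(idx)
            if len(keep) == P:
                break
    if len(keep) < P:  # tiny search spaces: pad with best duplicates
        chosen = set(keep)
        keep.extend(i for i in order if i not in chosen)
        keep = keep[:P]
    state.labels = all_labels[keep]
    state.bounds = all_bounds[keep]
    state.losses = all_losses[keep]
    # elitist step: the previous elite replaces the worst of the new
    # generation when the generation lost it (under parents-compete-with-
    # offspring truncation the elite survives, so this rarely fires)
    if state.elite_loss < state.losses[0]:
        state.labels[-1] = state.elite_labels
        state.bounds[-1] = state.elite_bounds
        state.losses[-1] = state.elite_loss
        _sort_island(state)
    if state.losses[0] < state.elite_loss:
        state.elite_labels = state.labels[0].copy()
        state.elite_bounds = state.bounds[0].copy()
        state.elite_loss = float(state.losses[0])
    return state


def migrate(
    islands: list[IslandState], config: GAConfig, rng: np.random.Generator
) -> list[IslandState]:
    """Ring migration, in place; returns the island list.

    For i = 2..I, N random chromosomes of island i-1's pre-migration
    population replace N randomly selected chromosomes of island i.  For
    i = 1, N random chromosomes of island I replace exactly those island-1
    chromosomes that were sent to island 2.  Chromosomes migrate with their
    cached losses; the total chromosome count is conserved.
    """
    I = len(islands)
    if I < 2:
        warnings.warn("migration requires at least 2 islands; no-op")
        return islands
    N = config.n_migrants
    snaps = [
        (isl.labels.copy(), isl.bounds.copy(), isl.losses.copy()) for isl in islands
    ]
    P = snaps[0][0].shape[0]
    sent_from_first: np.ndarray | None = None
    for i in range(1, I):
        src_idx = rng.choice(P, size=N, replace=False)
        dst_idx = rng.choice(P, size=N, replace=False)
        if i == 1:
            sent_from_first = src_idx
        s_labels, s_bounds, s_losses = snaps[i - 1]
        islands[i].labels[dst_idx] = s_labels[src_idx]
        islands[i].bounds[dst_idx] = s_bounds[src_idx]
        islands[i].losses[dst_idx] = s_losses[src_idx]
    back_idx = rng.choice(P, size=N, replace=False)
    s_labels, s_bounds, s_losses = snaps[I - 1]
    islands[0].labels[sent_from_first] = s_labels[back_idx]
    islands[0].bounds[sent_from_first] = s_bounds[back_idx]
    islands[0].losses[sent_from_first] = s_losses[back_idx]
    for isl in islands:
        _sort_island(isl)
    return islands


def _polish_island(
    state: IslandState, cache: _engine.SpectraCache, config: GAConfig
) -> None:
    """Coordinate-descent refinement of the island elite (deterministic).

    The polished chromosome replaces the island's worst member if it
    improves on the elite, and the elite is updated.
    """
    labels, bounds, loss = _engine.polish_solution(
        cache, state.elite_labels, state.elite_bounds, config.w_min
    )
    if loss < state.elite_loss:
        state.labels[-1] = labels
        state.bounds[-1] = bounds
        state.losses[-1] = loss
        _sort_island(state)
        state.elite_labels = labels.copy()
        state.elite_bounds = bounds.copy()
        state.elite_loss = float(loss)


def _init_island(
    cache: _engine.SpectraCache,
    J: int,
    L: int,
    config: GAConfig,
    seed_seq: np.random.SeedSequence,
) -> IslandState:
    rng = np.random.default_rng(seed_seq)
    labels, bounds = _engine.random_population(
        config.population_size, cache.K, cache.M, J, L, config.w_min, rng
    )
    losses = _engine.batch_loss(cache, labels, bounds)
    state = IslandState(
        labels=labels,
        bounds=bounds,
        losses=losses,
        elite_labels=labels[0].copy(),
        elite_bounds=bounds[0].copy(),
        elite_loss=np.inf,
        rng=rng,
        w_min=config.w_min,
    )
    _sort_island(state)
    state.elite_labels = state.labels[0].copy()
    state.elite_bounds = state.bounds[0].copy()
    state.elite_loss = float(state.losses[0])
    return state


def run_ga(
    spectra: SpectralEstimateSet, J: int, L: int, config: GAConfig
) -> Solution:
    """Minimize the loss at fixed (J, L); returns the global elite.

    Stops at ``max_generations`` or once the global elite has not improved
    by relative tolerance 1e-10 for ``stall_generations`` generations.
    Fully reproducible given ``config.seed`` (per-island streams are derived
    from (seed, J, L, island)).
    """
    K, M = spectra.n_series, spectra.n_freq
    if J > K or J < 1:
        raise FBAMError(f"infeasible number of groups J={J} for K={K}")
    if L < 1 or L * config.w_min > M:
        raise FBAMError(f"infeasible number of bands L={L} for M={M}")
    cache = _engine.SpectraCache(spectra.power, spectra.T)
    islands = [
        _init_island(cache, J, L, config, np.random.SeedSequence([config.seed, J, L, i]))
        for i in range(config.n_islands)
    ]
    mig_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, J, L, 1_000_003])
    )
    best = min(isl.elite_loss for isl in islands)
    stall = 0
    for gen in range(1, config.max_generations + 1):
        for isl in islands:
            evolve_island(isl, cache, config)
        if gen % config.migration_interval == 0:
            if config.polish:
                for isl in islands:
                    _polish_island(isl, cache, config)
            if config.n_islands > 1:
                migrate(islands, config, mig_rng)
            for i, isl in enumerate(islands):
                logger.info(
                    "J=%d L=%d gen=%d island=%d elite_loss=%.6g", J, L, gen, i, isl.elite_loss
                )
        new_best = min(isl.elite_loss for isl in islands)
        if best - new_best > 1e-10 * max(abs(best), 1e-300):
            best = new_best
            stall = 0
        else:
            stall += 1
            if stall >= config.stall_generations:
                break
    if config.polish:
        for isl in islands:
            _polish_island(isl, cache, config)
    champion = min(islands, key=lambda isl: isl.elite_loss)
    return champion.elite


@dataclass
class FBAMResult:
    """Fitted grid, selection criteria, and the selected solution."""

    table: CriterionTable
    selected: tuple[int, int]
    best: Solution
    mode: str
    config: GAConfig
    provenance: dict = field(default_factory=dict)


def fit_grid(
    spectra: SpectralEstimateSet,
    J_grid: list[int] | range,
    L_grid: list[int] | range,
    config: GAConfig | None = None,
    mode: str = "joint",
    n_jobs: int = 1,
) -> FBAMResult:
    """Fit the loss minimizer at every (J, L) cell and select a final model.

    Cells are independent GA runs and may execute in parallel
    (``n_jobs != 1``); per-cell seeds derive deterministically from the
    master seed so serial and parallel runs agree exactly.
    """
    if config is None:
        config = GAConfig()
    J_grid = sorted(set(int(j) for j in J_grid))
    L_grid = sorted(set(int(l) for l in L_grid))
    if not J_grid or not L_grid:
        raise FBAMError("J_grid and L_grid must be nonempty")
    cells = list(product(J_grid, L_grid))
    if n_jobs == 1:
        fitted = [run_ga(spectra, J, L, config) for J, L in cells]
    else:
        fitted = Parallel(n_jobs=n_jobs)(
            delayed(run_ga)(spectra, J, L, config) for J, L in cells
        )
    table = CriterionTable()
    for (J, L), sol in zip(cells, fitted):
        table.entries[(J, L)] = GridEntry(solution=sol, loss=float(sol.loss))
    compute_criteria(spectra, table)
    if mode == "joint" and (max(J_grid) < 2 or max(L_grid) < 2):
        mode = "bands_only" if max(J_grid) < 2 else "subpops_only"
    J_sel, L_sel, best = select(table, mode=mode)
    return FBAMResult(
        table=table,
        selected=(J_sel, L_sel),
        best=best,
        mode=mode,
        config=config,
        provenance={
            "seed": config.seed,
            "T": spectra.T,
            "K": spectra.n_series,
            "M": spectra.n_freq,
            "n_tapers": spectra.n_tapers,
            "J_grid": J_grid,
            "L_grid": L_grid,
        },
    )
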