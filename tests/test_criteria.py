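"""Similarity ratios, their aggregation, and (J, L) selection."""

import math

import numpy as np
import pytest

from fbam.bands import BandPartition, Clustering, Solution
from fbam.criteria import (
    CriterionTable,
    GridEntry,
    S1,
    S2,
    _max_mean_aggregate,
    band_similarity,
    select,
    subpop_similarity,
)
from fbam.exceptions import (
    DegenerateCriterionError,
    SelectionError,
    UndefinedCriterionError,
)
from tests.conftest import make_spectra


def oracle_band_similarity(power, bounds, l):
    """Direct-loop evaluation of the adjacent-band similarity ratio."""
    left = power[:, bounds[l] : bounds[l + 1]]
    right = power[:, bounds[l + 1] : bounds[l + 2]]
    y_l, y_r = left.mean(), right.mean()
    num = 0.0
    for block, y in ((left, y_l), (right, y_r)):
        s = 0.0
        for k in range(block.shape[0]):
            for v in block[k]:
                s += (v - y) ** 2
        num += math.sqrt(s)
    w_l = left.shape[1]
    w_r = right.shape[1]
    mu = (w_l * y_l + w_r * y_r) / (w_l + w_r)
    den = 0.0
    for block in (left, right):
        for k in range(block.shape[0]):
            for v in block[k]:
                den += (v - mu) ** 2
    return num / math.sqrt(den)


def oracle_subpop_similarity(pi, pj, bounds_i, bounds_j):
    """Direct-loop evaluation of the between-group similarity ratio."""
    def step(power, bounds):
        out = np.empty(power.shape[1])
        for l in range(len(bounds) - 1):
            out[bounds[l] : bounds[l + 1]] = power[:, bounds[l] : bounds[l + 1]].mean()
        return out

    def within(power, bounds):
        s = step(power, bounds)
        tot = 0.0
        for k in range(power.shape[0]):
            for m in range(power.shape[1]):
                tot += (power[k, m] - s[m]) ** 2
        return tot

    num = math.sqrt(within(pi, bounds_i) / pi.shape[0]) + math.sqrt(
        within(pj, bounds_j) / pj.shape[0]
    )
    d = step(pi, bounds_i) - step(pj, bounds_j)
    return num / math.sqrt(np.sum(d * d))


class TestBandSimilarity:
    def test_matches_direct_loop_oracle(self, rng):
        power = rng.random((3, 12)) * 4
        part = BandPartition((5,), 12, w_min=3)
        got = band_similarity(power, part, 0)
        want = oracle_band_similarity(power, part.bounds, 0)
        assert got == pytest.approx(want, abs=1e-10)

    def test_two_exact_levels_give_zero(self):
        power = np.tile(np.r_[np.full(5, 3.0), np.full(7, 1.0)], (4, 1))
        part = BandPartition((5,), 12, w_min=3)
        assert band_similarity(power, part, 0) == 0.0

    def test_equal_band_means_give_ratio_at_least_one(self, rng):
        power = rng.standard_normal((5, 12))
        power[:, :6] -= power[:, :6].mean()
        power[:, 6:] -= power[:, 6:].mean()
        power += 5.0  # both bands now have mean exactly 5
        part = BandPartition((6,), 12, w_min=3)
        assert band_similarity(power, part, 0) >= 1.0

    def test_identical_values_degenerate(self):
        power = np.full((2, 12), 2.0)
        part = BandPartition((6,), 12, w_min=3)
        with pytest.raises(DegenerateCriterionError):
            band_similarity(power, part, 0)


class TestSubpopSimilarity:
    def test_symmetric_in_groups(self, rng):
        pi, pj = rng.random((3, 15)), rng.random((4, 15))
        a = BandPartition((7,), 15, w_min=4)
        b = BandPartition((9,), 15, w_min=4)
        assert subpop_similarity(pi, pj, a, b) == pytest.approx(
            subpop_similarity(pj, pi, b, a), abs=1e-12
        )

    def test_flat_distinct_groups_give_zero(self):
        a = np.full((3, 15), 1.0)
        b = np.full((3, 15), 4.0)
        part = BandPartition((7,), 15, w_min=4)
        assert subpop_similarity(a, b, part, part) == 0.0

    def test_matches_direct_loop_oracle(self, rng):
        pi, pj = rng.random((3, 12)) * 2, rng.random((5, 12)) * 2
        a = BandPartition((5,), 12, w_min=3)
        b = BandPartition((8,), 12, w_min=3)
        got = subpop_similarity(pi, pj, a, b)
        want = oracle_subpop_similarity(pi, pj, a.bounds, b.bounds)
        assert got == pytest.approx(want, abs=1e-10)

    def test_identical_step_functions_degenerate(self):
        power = np.tile(np.r_[np.full(7, 2.0), np.full(8, 5.0)], (3, 1))
        part = BandPartition((7,), 15, w_min=4)
        with pytest.raises(DegenerateCriterionError):
            subpop_similarity(power, power.copy(), part, part)


class TestAggregates:
    def _solution(self, rng, K, M, J, L):
        labels = np.repeat(np.arange(J), K // J)
        parts = [
            BandPartition(tuple(range(4, 4 * L, 4))[: L - 1], M, w_min=3)
            for _ in range(J)
        ]
        return Solution(Clustering(labels, J), parts)

    def test_s1_is_mean_of_pair_ratios(self, rng):
        K, M, J, L = 6, 20, 2, 3
        power = rng.random((K, M)) * 3
        sp = make_spectra(power)
        sol = self._solution(rng, K, M, J, L)
        ratios = [
            band_similarity(power[sol.clustering.members(j)], sol.partitions[j], l)
            for j in range(J)
            for l in range(L - 1)
        ]
        assert S1(sp, sol) == pytest.approx(np.mean(ratios), abs=1e-12)
        # printed-normalizer variant discounts by (L-1)/L
        assert S1(sp, sol, normalizer="JL") == pytest.approx(
            np.mean(ratios) * (L - 1) / L, abs=1e-12
        )

    def test_s1_printed_variant_single_group_two_bands(self, rng):
        power = rng.random((3, 12)) * 2
        sp = make_spectra(power)
        part = BandPartition((5,), 12, w_min=3)
        sol = Solution(Clustering(np.zeros(3, dtype=int), 1), [part])
        r = band_similarity(power, part, 0)
        assert S1(sp, sol, normalizer="JL") == pytest.approx(r / 2, abs=1e-12)
        assert S1(sp, sol) == pytest.approx(r, abs=1e-12)

    def test_s1_undefined_for_single_band(self, rng):
        sp = make_spectra(rng.random((3, 12)))
        sol = Solution(
            Clustering(np.zeros(3, dtype=int), 1), [BandPartition((), 12)]
        )
        with pytest.raises(UndefinedCriterionError):
            S1(sp, sol)

    def test_s2_worst_case_mean_aggregation(self):
        # pairwise similarities 0.2, 0.9, 0.5 for pairs (1,2), (1,3), (2,3):
        # row maxima are 0.9, 0.5, 0.9 and their mean is 0.7666...
        pairwise = np.zeros((3, 3))
        pairwise[0, 1] = pairwise[1, 0] = 0.2
        pairwise[0, 2] = pairwise[2, 0] = 0.9
        pairwise[1, 2] = pairwise[2, 1] = 0.5
        assert _max_mean_aggregate(pairwise) == pytest.approx(23 / 30)

    def test_s2_two_groups_reduces_to_single_ratio(self, rng):
        K, M = 6, 20
        power = rng.random((K, M)) * 3
        sp = make_spectra(power)
        sol = self._solution(rng, K, M, 2, 2)
        r = subpop_similarity(
            power[:3], power[3:], sol.partitions[0], sol.partitions[1]
        )
        assert S2(sp, sol) == pytest.approx(r, abs=1e-12)

    def test_s2_undefined_for_single_group(self, rng):
        sp = make_spectra(rng.random((3, 12)))
        sol = Solution(
            Clustering(np.zeros(3, dtype=int), 1), [BandPartition((5,), 12, w_min=3)]
        )
        with pytest.raises(UndefinedCriterionError):
            S2(sp, sol)

    def test_ratios_invariant_to_common_rescaling(self, rng):
        K, M = 6, 20
        power = rng.random((K, M)) * 3
        sol = self._solution(rng, K, M, 2, 3)
        for c in (0.1, 7.0):
            assert S1(make_spectra(c * power), sol) == pytest.approx(
                S1(make_spectra(power), sol), rel=1e-10
            )
            assert S2(make_spectra(c * power), sol) == pytest.approx(
                S2(make_spectra(power), sol), rel=1e-10
            )


def _dummy_solution(J, L, M=40):
    labels = np.repeat(np.arange(J), 2)
    cuts = tuple(range(5, 5 * L, 5))[: L - 1]
    parts = [BandPartition(cuts, M) for _ in range(J)]
    return Solution(Clustering(labels, J), parts, loss=1.0)


def make_table(cells):
    table = CriterionTable()
    for (J, L), (s1, s2) in cells.items():
        table.entries[(J, L)] = GridEntry(
            solution=_dummy_solution(J, L), loss=1.0, s1=s1, s2=s2
        )
    return table


class TestSelect:
    def test_single_entry_grid_returns_it(self):
        table = make_table({(3, 2): (0.5, 0.7)})
        assert select(table, "joint")[:2] == (3, 2)

    def test_joint_minimizes_scaled_sum(self):
        table = make_table({(2, 2): (0.4, 0.8), (3, 3): (0.8, 0.4)})
        # both entries have scaled sum 0.4/0.8 + 0.8/0.8 = 1.5 -> tie:
        # parsimony breaks toward smaller (J, L)
        assert select(table, "joint")[:2] == (2, 2)
        table = make_table({(2, 2): (0.9, 0.9), (3, 3): (0.3, 0.3)})
        assert select(table, "joint")[:2] == (3, 3)

    def test_scale_equalization_makes_maxima_one(self):
        table = make_table({(2, 2): (0.4, 0.8), (3, 3): (0.8, 0.4)})
        s1s = [e.s1 / table.a1 for e in table.entries.values()]
        s2s = [e.s2 / table.a2 for e in table.entries.values()]
        assert max(s1s) == 1.0 and max(s2s) == 1.0

    def test_degenerate_entries_never_selected(self):
        table = make_table({(2, 2): (math.inf, 0.1), (3, 2): (0.9, 0.9)})
        assert select(table, "joint")[:2] == (3, 2)

    def test_single_axis_modes(self):
        table = make_table({(2, 2): (0.2, 0.9), (2, 3): (0.5, 0.3)})
        assert select(table, "bands_only")[:2] == (2, 2)
        assert select(table, "subpops_only")[:2] == (2, 3)

    def test_empty_grid_rejected(self):
        with pytest.raises(SelectionError):
            select(CriterionTable(), "joint")


class TestSelectionRecoversTruth:
    """On well-separated piecewise-constant spectra (estimation bypassed),
    the band criterion is minimized at the true L and the subpopulation
    criterion at the true J."""

    def _make_population(self, rng):
        # 3 groups x 8 replicates, M=60, true L=3 with distinct group layouts
        M = 60
        layouts = [(20, 40), (15, 30), (25, 45)]
        levels = [(10.0, 5.0, 1.0), (20.0, 9.0, 3.0), (30.0, 14.0, 5.0)]
        power, labels = [], []
        for j, (cuts, lvl) in enumerate(zip(layouts, levels)):
            bounds = (0, *cuts, M)
            for _ in range(8):
                spec = np.empty(M)
                for l in range(3):
                    jit = rng.uniform(-0.5, 0.5)
                    spec[bounds[l] : bounds[l + 1]] = lvl[l] + jit
                spec += rng.uniform(-0.05, 0.05, size=M)  # in-band texture
                power.append(spec)
                labels.append(j)
        return make_spectra(np.asarray(power)), np.asarray(labels), layouts

    def test_s1_min_at_true_l_and_s2_min_at_true_j(self, rng):
        from fbam.ga import GAConfig, fit_grid

        sp, labels, layouts = self._make_population(rng)
        cfg = GAConfig(
            n_islands=2, max_generations=80, population_size=30, seed=5
        )
        res = fit_grid(sp, [2, 3, 4], [2, 3, 4], config=cfg, mode="joint")
        s1_by_l = {
            L: res.table.entries[(3, L)].s1 for L in (2, 3, 4)
        }
        s2_by_j = {
            J: res.table.entries[(J, 3)].s2 for J in (2, 3, 4)
        }
        assert min(s1_by_l, key=s1_by_l.get) == 3
        assert min(s2_by_j, key=s2_by_j.get) == 3
        assert res.selected == (3, 3)
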