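"""Markov-CA demand scheduling, allocation, simulation, and map validation."""

import numpy as np
import pytest

from landrisk.ca import (
    SimulationConfig,
    allocate_iteration,
    demand_schedule,
    kappa_coefficient,
    neighborhood_factor,
    overall_accuracy,
    simulate,
)
from landrisk.change import TransitionMatrix, cross_tabulate
from landrisk.grid import ClassScheme, LandCoverGrid
from landrisk.lssvm import SuitabilityStack


def two_class_tm(a12, a21, d1, d2, scheme):
    return TransitionMatrix(np.array([[d1, a12], [a21, d2]], float), scheme)


class TestDemandSchedule:
    def test_largest_remainder_earliest_first(self, two_class_scheme):
        # 100 cells of one transition over 18 iterations: 10 iterations of 6
        # then 8 of 5 (remainder 10 assigned to the earliest iterations).
        tm = two_class_tm(100.0, 0.0, 500.0, 500.0, two_class_scheme)
        sched = demand_schedule(tm, 18, 1.0)
        per_iter = sched[:, 0, 1]
        assert list(per_iter[:10]) == [6] * 10
        assert list(per_iter[10:]) == [5] * 8
        assert per_iter.sum() == 100

    def test_zero_offdiagonal_empty(self, two_class_scheme):
        tm = two_class_tm(0.0, 0.0, 10.0, 10.0, two_class_scheme)
        assert demand_schedule(tm, 5, 1.0).sum() == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_per_pair_conservation(self, seed, two_class_scheme):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 50, (2, 2))
        tm = TransitionMatrix(a + np.diag([200, 200]), two_class_scheme)
        iters = int(rng.integers(1, 25))
        sched = demand_schedule(tm, iters, 1.0)
        counts = np.rint(tm.area).astype(int)
        np.fill_diagonal(counts, 0)
        np.testing.assert_array_equal(sched.sum(axis=0), counts)

    def test_infeasible_demand_names_pair(self):
        # rounding can push summed out-demands past the class's cell count:
        # row (0.2, 0.6, 0.6) ha at 1-ha cells rounds to demands (1, 1) from
        # a 1-cell class.
        scheme = ClassScheme((1, 2, 3), ("a", "b", "c"), (1, 2, 3))
        area = np.array([[0.2, 0.6, 0.6], [0.0, 5.0, 0.0], [0.0, 0.0, 5.0]])
        tm = TransitionMatrix(area, scheme)
        with pytest.raises(ValueError, match="exceeds"):
            demand_schedule(tm, 3, 1.0)


class TestNeighborhoodFactor:
    def test_uniform_target_interior_one(self, grid_factory):
        g = grid_factory(np.ones((5, 5), dtype=int))
        nf = neighborhood_factor(g, 1, 3)
        assert nf[2, 2] == 1.0

    def test_isolated_cell_fully_surrounded(self, grid_factory, two_class_scheme):
        v = np.ones((3, 3), dtype=int)
        v[1, 1] = 2
        g = grid_factory(v, scheme=two_class_scheme)
        assert neighborhood_factor(g, 1, 3)[1, 1] == 1.0

    def test_matches_brute_force_window_scan(self, random_grid_factory):
        rng = np.random.default_rng(0)
        g = random_grid_factory(rng, (12, 12))
        for target in g.scheme.codes:
            nf = neighborhood_factor(g, target, 3)
            H, W = g.shape
            for r in range(H):
                for c in range(W):
                    cnt = hit = 0
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            if (dr, dc) == (0, 0):
                                continue
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < H and 0 <= cc < W:
                                cnt += 1
                                hit += g.values[rr, cc] == target
                    assert nf[r, c] == pytest.approx(hit / cnt)


def uniform_stack(shape, pairs, value=1.0):
    return SuitabilityStack({p: np.full(shape, value) for p in pairs}, shape)


class TestAllocateIteration:
    def test_zero_demand_identity(self, grid_factory, two_class_scheme):
        g = grid_factory(np.ones((5, 5), dtype=int), scheme=two_class_scheme)
        nxt, short = allocate_iteration(
            g, uniform_stack(g.shape, [(1, 2)]), np.zeros((2, 2), int), SimulationConfig()
        )
        np.testing.assert_array_equal(nxt.values, g.values)
        assert short.sum() == 0

    def test_top_scoring_cells_convert(self, grid_factory, two_class_scheme):
        # Distinct suitability values on a 5x5: exactly the top-3 claim.
        g = grid_factory(np.ones((5, 5), dtype=int), scheme=two_class_scheme)
        suit = np.arange(25, dtype=float).reshape(5, 5) / 25.0
        stack = SuitabilityStack({(1, 2): suit}, g.shape)
        demands = np.array([[0, 3], [0, 0]])
        cfg = SimulationConfig(eps=1.0, seed=0)  # neighborhood factor 0 for class 2
        nxt, short = allocate_iteration(g, stack, demands, cfg)
        converted = np.argwhere(nxt.values == 2)
        # enumeration oracle: 3 largest suitability entries
        flat = np.argsort(-suit.ravel())[:3]
        expected = sorted(map(tuple, np.column_stack(np.unravel_index(flat, (5, 5)))))
        assert sorted(map(tuple, converted)) == expected
        assert short.sum() == 0

    def test_immutable_mask_blocks_all(self, grid_factory, two_class_scheme):
        g = grid_factory(np.ones((4, 4), dtype=int), scheme=two_class_scheme)
        cfg = SimulationConfig(immutable_mask=np.ones((4, 4), bool))
        nxt, short = allocate_iteration(
            g, uniform_stack(g.shape, [(1, 2)]), np.array([[0, 5], [0, 0]]), cfg
        )
        np.testing.assert_array_equal(nxt.values, g.values)
        assert short[0, 1] == 5


class TestSimulate:
    def _world(self, seed=0, shape=(20, 20)):
        rng = np.random.default_rng(seed)
        scheme = ClassScheme((1, 2, 3), ("a", "b", "c"), (1, 2, 3))
        g = LandCoverGrid(rng.integers(1, 4, shape).astype(np.int64), 100.0, scheme=scheme)
        pairs = [(i, j) for i in (1, 2, 3) for j in (1, 2, 3) if i != j]
        stack = SuitabilityStack(
            {p: rng.random(shape) for p in pairs}, shape
        )
        return g, stack

    def test_identity_matrix_no_change(self):
        g, stack = self._world()
        tm = TransitionMatrix(np.diag([100.0, 100.0, 100.0]), g.scheme)
        states, _ = simulate(g, tm, stack, SimulationConfig(iterations=4))
        np.testing.assert_array_equal(states[-1].values, g.values)

    def test_same_seed_bit_identical(self):
        g, stack = self._world(1)
        tm = cross_tabulate(g, self._world(2)[0])
        out1, _ = simulate(g, tm, stack, SimulationConfig(iterations=5, seed=9))
        out2, _ = simulate(g, tm, stack, SimulationConfig(iterations=5, seed=9))
        for a, b in zip(out1, out2):
            np.testing.assert_array_equal(a.values, b.values)

    def test_conservation_and_markov_totals_50x50(self):
        rng = np.random.default_rng(4)
        scheme = ClassScheme((1, 2, 3), ("a", "b", "c"), (1, 2, 3))
        v1 = rng.integers(1, 4, (50, 50)).astype(np.int64)
        g1 = LandCoverGrid(v1, 100.0, scheme=scheme)
        # evolve a target map by random flips, then demand its transitions
        v2 = v1.copy()
        flip = rng.random((50, 50)) < 0.2
        v2[flip] = rng.integers(1, 4, int(flip.sum()))
        g2 = LandCoverGrid(v2, 100.0, scheme=scheme)
        tm = cross_tabulate(g1, g2)
        pairs = [(i, j) for i in (1, 2, 3) for j in (1, 2, 3)]
        stack = SuitabilityStack({p: rng.random((50, 50)) for p in pairs}, (50, 50))
        states, report = simulate(g1, tm, stack, SimulationConfig(iterations=10, seed=3))
        ncells = 50 * 50
        for st in states:
            assert int(st.valid_mask.sum()) == ncells
        final = states[-1]
        for c in (1, 2, 3):
            actual = int(np.count_nonzero(final.values == c))
            assert actual == pytest.approx(report.projected_counts[c], rel=0.01)

    def test_contiguity_clustering_with_uniform_suitability(self):
        # With spatially uniform suitability and a small eps, converted cells
        # should sit in denser target neighborhoods than unconverted sources.
        rng = np.random.default_rng(7)
        scheme = ClassScheme((1, 2), ("a", "b"), (1, 2))
        v = np.ones((30, 30), dtype=np.int64)
        v[10:14, 10:14] = 2  # a seed cluster of the target class
        g = LandCoverGrid(v, 100.0, scheme=scheme)
        stack = uniform_stack(g.shape, [(1, 2)], 1.0)
        demands = np.array([[0, 40], [0, 0]])
        cfg = SimulationConfig(eps=0.01, seed=0)
        nf = neighborhood_factor(g, 2, 3)
        nxt, _ = allocate_iteration(g, stack, demands, cfg)
        converted = (g.values == 1) & (nxt.values == 2)
        unconverted = (g.values == 1) & (nxt.values == 1)
        assert nf[converted].mean() >= nf[unconverted].mean()


class TestMapAgreement:
    def test_identical_maps(self, grid_factory):
        g = grid_factory(np.arange(1, 10).reshape(3, 3) % 3 + 1)
        assert overall_accuracy(g, g) == 1.0
        assert kappa_coefficient(g, g) == 1.0

    def test_complementary_maps_zero_accuracy(self, grid_factory, two_class_scheme):
        a = grid_factory(np.ones((4, 4), dtype=int), scheme=two_class_scheme)
        b = grid_factory(np.full((4, 4), 2), scheme=two_class_scheme)
        assert overall_accuracy(a, b) == 0.0

    def test_hand_confusion_kappa(self, two_class_scheme):
        # counts [[40, 10], [20, 30]]: p_o = 0.7, p_e = 0.5, kappa = 0.4
        sim = np.concatenate([np.ones(50, int), np.full(50, 2)])
        obs = np.concatenate([np.ones(40, int), np.full(10, 2), np.ones(20, int), np.full(30, 2)])
        gs = LandCoverGrid(sim.reshape(10, 10), 100.0, scheme=two_class_scheme)
        go = LandCoverGrid(obs.reshape(10, 10), 100.0, scheme=two_class_scheme)
        assert overall_accuracy(gs, go) == pytest.approx(0.7)
        assert kappa_coefficient(gs, go) == pytest.approx(0.4)

    def test_constant_vs_varied_kappa_nonpositive(self, grid_factory, two_class_scheme):
        rng = np.random.default_rng(0)
        sim = grid_factory(np.ones((6, 6), dtype=int), scheme=two_class_scheme)
        obs = grid_factory(rng.integers(1, 3, (6, 6)), scheme=two_class_scheme)
        assert kappa_coefficient(sim, obs) <= 0.0

    def test_against_sklearn_cross_check(self, random_grid_factory):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(3)
        a = random_grid_factory(rng, (15, 15))
        b = random_grid_factory(np.random.default_rng(4), (15, 15))
        b.scheme = a.scheme
        kappa_ref = sklearn_metrics.cohen_kappa_score(a.values.ravel(), b.values.ravel())
        assert kappa_coefficient(a, b) == pytest.approx(kappa_ref, abs=1e-12)
        acc_ref = (a.values == b.values).mean()
        assert overall_accuracy(a, b) == pytest.approx(acc_ref)
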