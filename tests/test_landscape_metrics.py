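"""Landscape metrics against exhaustive small-instance oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from landrisk.grid import ZoneGrid
from landrisk.metrics import (
    PatchSet,
    adjacency_matrix,
    contagion,
    label_patches,
    metric_table,
    pafrac,
    patch_density,
    shdi,
    splitting_index,
)
from landrisk.tables import class_areas

from _oracles import adjacency_oracle, assert_patches_match_oracle, flood_fill_patches


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

# ---------------------------------------------------------------------------
# Patch delineation
# ---------------------------------------------------------------------------

class TestLabelPatches:
    def test_uniform_square(self, grid_factory):
        g = grid_factory(np.ones((4, 4), dtype=int), cell_size=100)
        ps = label_patches(g)
        assert ps.n_patches == 1
        assert ps.areas_ha[0] == pytest.approx(16.0)
        assert ps.perimeters_m[0] == pytest.approx(1600.0)

    @pytest.mark.parametrize("connectivity,expected", [(8, 2), (4, 16)])
    def test_checkerboard_connectivity(self, grid_factory, connectivity, expected):
        v = np.indices((4, 4)).sum(axis=0) % 2 + 1
        g = grid_factory(v)
        assert label_patches(g, connectivity).n_patches == expected

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill(self, random_grid_factory, seed, connectivity):
        rng = np.random.default_rng(seed)
        g = random_grid_factory(rng, (15, 15))
        assert_patches_match_oracle(g, connectivity)

    def test_area_conservation(self, random_grid_factory):
        rng = np.random.default_rng(9)
        g = random_grid_factory(rng, (20, 20))
        ps = label_patches(g)
        assert ps.areas_ha.sum() == pytest.approx(ps.total_area_ha)


# ---------------------------------------------------------------------------
# Composition metrics
# ---------------------------------------------------------------------------

class TestShdi:
    def test_single_class_zero(self):
        assert shdi([10.0]) == 0.0

    @pytest.mark.parametrize("m", [2, 3, 6])
    def test_equal_classes_ln_m(self, m):
        assert shdi([5.0] * m) == pytest.approx(math.log(m))

    @pytest.mark.parametrize(
        "year,expected,tol",
        [(1991, 1.3304, 5e-5), (2004, 1.5168, 1e-3), (2013, 1.6030, 5e-5)],
    )
    def test_published_diversity_from_class_areas(self, year, expected, tol):
        assert shdi(class_areas().loc[year].to_numpy()) == pytest.approx(expected, abs=tol)

    def test_unit_invariance(self):
        a = np.array([3.0, 5.0, 9.0])
        assert shdi(a) == pytest.approx(shdi(a * 12345.6))


class TestPatchDensity:
    def test_unit_definition(self, grid_factory):
        g = grid_factory(np.ones((10, 10), dtype=int), cell_size=100)  # 100 ha
        assert patch_density(label_patches(g)) == pytest.approx(1.0)

    def test_arithmetic(self):
        ps = PatchSet(
            np.array([1] * 5), np.ones(5) * 50, np.ones(5), np.ones(5, dtype=int), 250.0, 8
        )
        assert patch_density(ps) == pytest.approx(2.0)

    def test_matches_oracle_count(self, random_grid_factory):
        rng = np.random.default_rng(3)
        g = random_grid_factory(rng, (20, 20))
        ps = label_patches(g)
        n_oracle = len(flood_fill_patches(g.values, g.nodata, 8))
        assert patch_density(ps) == pytest.approx(n_oracle / ps.total_area_ha * 100)


class TestSplittingIndex:
    def test_single_solid_patch(self, grid_factory):
        g = grid_factory(np.ones((5, 5), dtype=int))
        assert splitting_index(label_patches(g)) == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [2, 4])
    def test_k_equal_patches(self, k):
        ps = PatchSet(
            np.ones(k, dtype=int), np.full(k, 10.0), np.ones(k), np.ones(k, dtype=int),
            10.0 * k, 8,
        )
        assert splitting_index(ps) == pytest.approx(k)

    def test_three_one_split(self):
        ps = PatchSet(
            np.ones(2, dtype=int), np.array([3.0, 1.0]), np.ones(2), np.ones(2, dtype=int),
            4.0, 8,
        )
        assert splitting_index(ps) == pytest.approx(1.6)

    def test_scale_free(self, grid_factory):
        rng = np.random.default_rng(4)
        v = rng.integers(1, 4, (12, 12))
        g100 = grid_factory(v, cell_size=100)
        g30 = grid_factory(v, cell_size=30)
        assert splitting_index(label_patches(g100)) == pytest.approx(
            splitting_index(label_patches(g30))
        )


class TestContagion:
    def test_two_by_two_hand_value(self, grid_factory):
        # P=(1/2,1/2); 4 internal edges, all unlike; double-count g12=g21=4.
        # q = 0.5 each for the two unlike pairs: CONTAG = (1 - ln2/(2 ln2))*100 = 50.
        g = grid_factory([[1, 2], [2, 1]])
        assert contagion(g) == pytest.approx(50.0)

    def test_single_class_error(self, grid_factory):
        with pytest.raises(ValueError):
            contagion(grid_factory(np.ones((3, 3), dtype=int)))

    def test_blocks_more_aggregated_than_random_scramble(self, grid_factory):
        # Scrambling a solid two-block landscape to a random interspersion of
        # the same composition pushes the adjacency distribution toward
        # uniformity over the m^2 pairs, lowering contagion.
        rng = np.random.default_rng(0)
        n = 12
        blocks = np.ones((n, n), dtype=int)
        blocks[:, n // 2 :] = 2
        scrambled = rng.permutation(blocks.ravel()).reshape(n, n)
        assert contagion(grid_factory(blocks)) > contagion(grid_factory(scrambled))

    def test_blocks_trend_monotone_with_size(self, grid_factory):
        # As the interface/area ratio of a two-block landscape shrinks,
        # contagion rises monotonically toward its equal-composition limit.
        prev = -1.0
        for n in (4, 8, 16, 32):
            v = np.ones((n, n), dtype=int)
            v[:, n // 2 :] = 2
            val = contagion(grid_factory(v))
            assert val > prev
            prev = val

    def test_matches_adjacency_oracle(self, random_grid_factory):
        rng = np.random.default_rng(6)
        g = random_grid_factory(rng, (12, 12))
        codes = g.scheme.codes
        g_or = adjacency_oracle(g.values, g.nodata, codes)
        np.testing.assert_array_equal(adjacency_matrix(g), g_or)
        # independent recomputation of the formula from the oracle adjacency
        areas = np.array([np.count_nonzero(g.values == c) for c in codes], float)
        P = areas / areas.sum()
        m = (areas > 0).sum()
        ent = 0.0
        for i in range(len(codes)):
            row = g_or[i].sum()
            if row == 0:
                continue
            for k in range(len(codes)):
                q = P[i] * g_or[i, k] / row
                if q > 0:
                    ent += q * math.log(q)
        expected = (1 + ent / (2 * math.log(m))) * 100
        assert contagion(g) == pytest.approx(expected)


class TestPafrac:
    def test_solid_squares_give_one(self, grid_factory):
        # Squares of sides 1,2,4,8 on one big grid, well separated.
        v = np.full((24, 24), 2, dtype=int)
        v[0:1, 0:1] = 1
        v[3:5, 3:5] = 1
        v[8:12, 8:12] = 1
        v[15:23, 15:23] = 1
        ps = label_patches(grid_factory(v)).of_class(1)
        val, ok = pafrac(ps)
        assert ok
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_hand_ols_triple(self):
        ps = PatchSet(
            np.ones(3, dtype=int),
            np.array([1.0, 4.0, 16.0]),
            np.array([4.0, 8.0, 16.0]),
            np.ones(3, dtype=int),
            21.0,
            8,
        )
        val, ok = pafrac(ps)
        assert ok and val == pytest.approx(1.0)

    def test_matches_independent_ols(self, random_grid_factory):
        rng = np.random.default_rng(8)
        g = random_grid_factory(rng, (20, 20))
        ps = label_patches(g)
        val, ok = pafrac(ps)
        assert ok
        x, y = np.log(ps.perimeters_m), np.log(ps.areas_ha)
        slope = np.cov(x, y, bias=True)[0, 1] / np.var(x)
        assert val == pytest.approx(2.0 / slope)

    def test_undefined_single_patch(self, grid_factory):
        ps = label_patches(grid_factory(np.ones((3, 3), dtype=int)))
        val, ok = pafrac(ps)
        assert not ok and math.isnan(val)


# ---------------------------------------------------------------------------
# Structural properties and zonal evaluation
# ---------------------------------------------------------------------------

class TestProperties:
    def test_merging_patches_never_increases_split_or_pd(self, grid_factory):
        v = np.full((5, 9), 2, dtype=int)
        v[2, 0:4] = 1
        v[2, 5:9] = 1  # two class-1 patches with a gap at (2, 4)
        before = label_patches(grid_factory(v), 4)
        v2 = v.copy()
        v2[2, 4] = 1  # fill the gap: one merged patch
        after = label_patches(grid_factory(v2), 4)
        assert splitting_index(after, class_code=1) <= splitting_index(before, class_code=1)
        assert patch_density(after, class_code=1) <= patch_density(before, class_code=1)


class TestMetricTable:
    def test_uniform_landscape_two_zones(self, grid_factory):
        g = grid_factory(np.ones((6, 6), dtype=int))
        zones = ZoneGrid(np.repeat([[1, 2]], 6, axis=0).repeat(3, axis=1), 100.0)
        mt = metric_table(g, zones)
        for z in ("1", "2"):
            rows = mt[(mt.unit == z) & (mt["class"] == "LAND")].set_index("metric")
            assert rows.loc["SHDI", "value"] == 0.0
            assert rows.loc["SPLIT", "value"] == pytest.approx(1.0)

    def test_whole_grid_zone_equals_landscape_row(self, random_grid_factory):
        rng = np.random.default_rng(2)
        g = random_grid_factory(rng, (10, 10))
        zones = ZoneGrid(np.ones(g.shape, dtype=np.int64), 100.0)
        mt = metric_table(g, zones)
        land = mt[mt.unit == "landscape"].set_index(["class", "metric"])["value"]
        zone = mt[mt.unit == "1"].set_index(["class", "metric"])["value"]
        np.testing.assert_allclose(land.to_numpy(), zone.to_numpy(), atol=1e-12)

    def test_zone_rows_equal_cropped_run(self, random_grid_factory, grid_factory):
        rng = np.random.default_rng(12)
        g = random_grid_factory(rng, (12, 12))
        zvals = np.ones(g.shape, dtype=np.int64)
        zvals[:, 6:] = 2
        zones = ZoneGrid(zvals, 100.0)
        mt = metric_table(g, zones)
        # independent run on the zone-2 crop alone
        crop = grid_factory(g.values[:, 6:], scheme=g.scheme)
        mt_crop = metric_table(crop)
        zone2 = mt[mt.unit == "2"].set_index(["class", "metric"])["value"]
        land = mt_crop[mt_crop.unit == "landscape"].set_index(["class", "metric"])["value"]
        np.testing.assert_allclose(zone2.to_numpy(), land.to_numpy(), atol=1e-12)
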