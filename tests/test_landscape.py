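import math

import numpy as np
import pytest

from vorshealth import landscape
from vorshealth.grids import LandUseGrid, tessellate
from vorshealth.landscape import (PatchSet, awmpfd, cohesion, contagion,
                                  fragmentation_index, label_patches, shdi,
                                  unit_metrics, window_metrics)

from _oracles import (awmpfd_direct, cohesion_direct, contagion_direct,
                      flood_fill_patches, shdi_direct)


class TestLabelPatches:
    def test_uniform_square(self):
        ps = label_patches(np.full((3, 3), 2), connectivity=8)
        assert len(ps) == 1
        assert ps.patches[0].area == 9
        assert ps.patches[0].perimeter == 12

    def test_checkerboard_4conn(self):
        w = np.array([[1, 2], [2, 1]])
        ps = label_patches(w, connectivity=4)
        assert len(ps) == 4
        assert all(p.area == 1 and p.perimeter == 4 for p in ps)

    def test_diagonal_connectivity_semantics(self):
        w = np.array([[1, 2], [2, 1]])
        ones8 = label_patches(w, 8).restrict(1)
        ones4 = label_patches(w, 4).restrict(1)
        assert len(ones8) == 1 and len(ones4) == 2

    def test_empty_window(self):
        with pytest.raises(ValueError, match="empty"):
            label_patches(np.empty((0, 0), dtype=int))

    def test_bad_connectivity(self):
        with pytest.raises(ValueError):
            label_patches(np.ones((2, 2), int), connectivity=6)

    def test_nodata_counts_as_exposed_edge(self):
        w = np.array([[2, -9999], [2, 2]])
        ps = label_patches(w, 8)
        assert len(ps) == 1
        assert ps.patches[0].perimeter == 8

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, random_windows, connectivity):
        for w in random_windows:
            got = sorted((p.class_code, p.area, p.perimeter)
                         for p in label_patches(w, connectivity))
            want = sorted(flood_fill_patches(w, connectivity))
            assert got == want

    def test_areas_partition_cells(self, random_windows):
        for w in random_windows:
            ps = label_patches(w, 8)
            assert sum(p.area for p in ps) == w.size


class TestShdi:
    def test_single_class(self):
        assert shdi([1.0, 0, 0, 0, 0, 0]) == 0.0

    def test_two_even_classes(self):
        assert shdi([0.5, 0.5]) == pytest.approx(math.log(2))

    def test_three_class_mix(self):
        # frozen from direct evaluation of -sum p ln p
        assert shdi([0.5, 0.25, 0.25]) == pytest.approx(1.039720, abs=1e-6)

    def test_matches_oracle(self, random_windows):
        for w in random_windows:
            shares = [(w == c).mean() for c in range(1, 7)]
            assert shdi(shares) == pytest.approx(shdi_direct(w))

    def test_bounds(self, random_windows):
        for w in random_windows:
            shares = [(w == c).mean() for c in range(1, 7)]
            assert 0.0 <= shdi(shares) <= math.log(6) + 1e-12


class TestAwmpfd:
    def test_square_patch_is_one(self):
        for s in (2, 3, 5):
            ps = label_patches(np.full((s, s), 1))
            assert awmpfd(ps, s * s) == pytest.approx(1.0)

    def test_single_cell_guard(self):
        ps = label_patches(np.array([[1, 2], [2, 1]]), connectivity=4)
        assert awmpfd(ps, 4) == pytest.approx(1.0)

    def test_rectangle(self):
        ps = label_patches(np.full((2, 4), 3))
        # p=12, a=8: 2 ln 3 / ln 8
        assert awmpfd(ps, 8) == pytest.approx(2 * math.log(3) / math.log(8))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            awmpfd(PatchSet([], 8), 9)

    def test_matches_oracle(self, random_windows):
        for w in random_windows:
            got = awmpfd(label_patches(w, 8), w.size)
            assert got == pytest.approx(awmpfd_direct(w, 8))


class TestContagion:
    def test_single_class_is_100(self):
        assert contagion(np.full((4, 4), 2)) == 100.0

    def test_two_class_limits(self):
        # structured alternation concentrates the adjacency distribution at
        # (0.5, 0.5), so a 2-class checkerboard sits at exactly 50; maximal
        # disorder (random mixing, adjacencies half like half unlike) is the
        # configuration that approaches 0
        n = 30
        w = (np.indices((n, n)).sum(axis=0) % 2) + 1
        assert contagion(w) == pytest.approx(50.0, abs=1e-9)
        rng = np.random.default_rng(3)
        mixed = rng.integers(1, 3, (n, n))
        assert contagion(mixed) < 2.0

    def test_many_class_interspersion_is_low(self):
        rng = np.random.default_rng(7)
        w = rng.integers(1, 7, (40, 40))
        assert contagion(w) < 12.0

    def test_split_window_matches_hand_tally(self):
        w = np.repeat([[1, 1, 2, 2]], 4, axis=0)
        assert contagion(w) == pytest.approx(contagion_direct(w))

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            contagion(np.array([[1]]))

    def test_matches_oracle(self, random_windows):
        for w in random_windows:
            assert contagion(w) == pytest.approx(contagion_direct(w))

    def test_bounds(self, random_windows):
        for w in random_windows:
            assert -1e-9 <= contagion(w) <= 100.0 + 1e-9


class TestFragmentation:
    def test_one_patch_per_9km2(self):
        ps = label_patches(np.full((3, 3), 1))
        assert fragmentation_index(ps, 9.0) == pytest.approx(1 / 9)

    def test_absent_class_zero(self):
        ps = label_patches(np.full((3, 3), 1)).restrict(4)
        assert fragmentation_index(ps, 9.0) == 0.0

    def test_checkerboard_density(self):
        w = (np.indices((6, 6)).sum(axis=0) % 2) + 1
        ps = label_patches(w, connectivity=4)
        assert fragmentation_index(ps, 36.0) == pytest.approx(1.0)

    def test_nonpositive_area(self):
        with pytest.raises(ValueError):
            fragmentation_index(PatchSet([], 8), 0.0)

    def test_splitting_increases_fi(self):
        w = np.full((5, 5), 2)
        base = fragmentation_index(label_patches(w, 4), 25.0)
        w2 = w.copy()
        w2[2, :] = 1  # cut the patch in two
        split = fragmentation_index(label_patches(w2, 4).restrict(2), 25.0)
        assert split > base


class TestCohesion:
    def test_absent_class_zero(self):
        ps = label_patches(np.full((3, 3), 1)).restrict(4)
        assert cohesion(ps, 9) == 0.0

    def test_full_window_patch(self):
        ps = label_patches(np.full((10, 10), 4))
        # p=40, a=100: (1 - 40/400)/(1 - 0.1)*100
        want = (1 - 40 / (40 * 10)) / (1 - 1 / 10) * 100
        assert cohesion(ps.restrict(4), 100) == pytest.approx(want)

    def test_isolated_cells_less_cohesive(self):
        compact = np.full((6, 6), 1)
        compact[:3, :3] = 4
        scattered = np.full((6, 6), 1)
        scattered[::2, ::2] = 4
        c1 = cohesion(label_patches(compact, 4).restrict(4), 36)
        c2 = cohesion(label_patches(scattered, 4).restrict(4), 36)
        assert c2 < c1

    def test_too_small_window(self):
        with pytest.raises(ValueError):
            cohesion(PatchSet([], 8), 1)

    def test_matches_oracle(self, random_windows):
        for w in random_windows:
            for cls in (1, 2):
                got = cohesion(label_patches(w, 8).restrict(cls), w.size)
                assert got == pytest.approx(cohesion_direct(w, cls, 8))

    def test_bounds(self, random_windows):
        for w in random_windows:
            c = cohesion(label_patches(w, 8).restrict(1), w.size)
            assert 0.0 <= c <= 100.0 + 1e-9


class TestUnitMetrics:
    def test_shape_and_columns(self, small_landuse, small_units):
        df = unit_metrics(small_landuse, small_units)
        assert list(df.columns) == list(landscape.METRIC_NAMES)
        assert len(df) == small_units.n_units

    def test_windows_are_isolated(self, rng):
        # metrics of a unit depend only on its own window
        vals = rng.integers(1, 7, (6, 6))
        g = LandUseGrid(vals)
        units = tessellate(g, 3.0)
        df = unit_metrics(g, units)
        direct = window_metrics(vals[:3, :3])
        for m in landscape.METRIC_NAMES:
            assert df.loc[1, m] == pytest.approx(direct[m])

    def test_default_weights_sum_to_one(self):
        assert sum(landscape.DEFAULT_EO_WEIGHTS.values()) == pytest.approx(1.0)
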