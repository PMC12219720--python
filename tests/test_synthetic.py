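import numpy as np
import pytest
from scipy import ndimage

from vorshealth import synthetic
from vorshealth.geodetector import factor_q
from vorshealth.grids import LANDUSE_CODES
from vorshealth.spatial import build_weights, morans_i
from vorshealth.synthetic import (default_transition_matrix,
                                  generate_counties, generate_drivers,
                                  generate_gaussian_field,
                                  generate_landuse_series, generate_ndvi,
                                  generate_scenario, make_stratified_driver,
                                  threshold_field)


class TestGaussianField:
    def test_white_noise_morans_i(self):
        f = generate_gaussian_field((30, 30), 0, seed=5)
        w = build_weights(30, 30, "queen")
        res = morans_i(f.ravel(), w)
        sd = (res.I - res.expected) / res.z
        assert abs(res.I - res.expected) < 3 * abs(sd)

    def test_determinism(self):
        a = generate_gaussian_field((20, 20), 3, seed=9)
        b = generate_gaussian_field((20, 20), 3, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_smoothed_field_strong_autocorrelation(self):
        f = generate_gaussian_field((100, 100), 10, seed=2)
        w = build_weights(100, 100, "queen")
        assert morans_i(f.ravel(), w).I > 0.5

    def test_standardised(self):
        f = generate_gaussian_field((40, 40), 5, seed=1)
        assert f.mean() == pytest.approx(0.0, abs=1e-12)
        assert f.std() == pytest.approx(1.0)

    def test_bad_shape(self):
        with pytest.raises(ValueError):
            generate_gaussian_field((0, 10), 1, seed=0)


class TestLanduseSeries:
    def test_degenerate_single_class(self):
        series = generate_landuse_series(
            (10, 10), {"forestland": 1.0}, np.eye(6), T=3, seed=0)
        for g in series:
            assert (g.values == 2).all()

    def test_proportions_within_tolerance(self):
        targets = {"farmland": 0.5, "water": 0.5}
        series = generate_landuse_series(
            (200, 200), targets, np.eye(6), T=1, seed=4)
        vals = series[0].values
        for code in (1, 4):
            assert 0.48 <= (vals == code).mean() <= 0.52

    def test_construction_growth_monotone(self):
        P = np.eye(6)
        P[0, 0], P[0, 4] = 0.9, 0.1  # farmland -> construction
        series = generate_landuse_series(
            (60, 60), {"farmland": 0.8, "construction": 0.2}, P, T=4, seed=1)
        shares = [(g.values == 5).mean() for g in series]
        assert all(b > a for a, b in zip(shares, shares[1:]))

    def test_bad_proportions(self):
        with pytest.raises(ValueError, match="sum to 1"):
            generate_landuse_series((5, 5), {"farmland": 0.7}, np.eye(6),
                                    T=1, seed=0)

    def test_bad_transition_matrix(self):
        P = np.eye(6)
        P[0, 0] = 0.5
        with pytest.raises(ValueError, match="rows must sum"):
            generate_landuse_series((5, 5), {"farmland": 1.0}, P, T=2,
                                    seed=0)

    def test_determinism(self):
        args = ((30, 30), {"farmland": 0.6, "water": 0.4},
                default_transition_matrix(), 3)
        a = generate_landuse_series(*args, seed=7)
        b = generate_landuse_series(*args, seed=7)
        for ga, gb in zip(a, b):
            np.testing.assert_array_equal(ga.values, gb.values)

    def test_threshold_field_exact_counts(self, rng):
        f = rng.standard_normal((50, 50))
        targets = np.array([0.25, 0.25, 0.25, 0.25, 0, 0])
        out = threshold_field(f, targets)
        counts = np.bincount(out.ravel(), minlength=7)[1:]
        np.testing.assert_array_equal(counts, [625, 625, 625, 625, 0, 0])


class TestDrivers:
    @pytest.mark.parametrize("dq", [0.0, 0.3, 0.6, 1.0])
    def test_designed_q_recovered_exactly(self, rng, dq):
        strata = rng.integers(1, 6, (60, 60))
        surf = make_stratified_driver(strata, dq, seed=11)
        if dq == 0.0:
            got = factor_q(surf.ravel(), strata.ravel()).q
            assert got == pytest.approx(0.0, abs=1e-12)
        else:
            got = factor_q(surf.ravel(), strata.ravel()).q
            assert got == pytest.approx(dq, abs=1e-9)

    def test_invalid_designed_q(self, rng):
        strata = rng.integers(1, 4, (10, 10))
        with pytest.raises(ValueError):
            make_stratified_driver(strata, 1.5, seed=0)

    def test_generate_drivers_recovery(self):
        series = generate_landuse_series(
            (80, 80), synthetic.DEFAULT_CLASS_TARGETS,
            default_transition_matrix(), T=2, seed=3)
        dq = {"X1": 0.2, "X8": 0.6}
        drivers, strata = generate_drivers(series, dq, seed=5)
        for did, target in dq.items():
            got = factor_q(drivers[did].values.ravel(),
                           strata[did].ravel()).q
            assert got == pytest.approx(target, abs=1e-9)

    def test_x8_covaries_with_construction(self):
        series = generate_landuse_series(
            (80, 80), synthetic.DEFAULT_CLASS_TARGETS,
            default_transition_matrix(), T=2, seed=3)
        drivers, _ = generate_drivers(series, {"X8": 0.9}, seed=5)
        dens = ndimage.gaussian_filter(
            (series[-1].values == 5).astype(float), 4.0, mode="reflect")
        r = np.corrcoef(dens.ravel(), drivers["X8"].values.ravel())[0, 1]
        assert r > 0.5

    def test_unknown_driver_id(self):
        series = generate_landuse_series(
            (10, 10), {"farmland": 1.0}, np.eye(6), T=1, seed=0)
        with pytest.raises(ValueError, match="unknown driver"):
            generate_drivers(series, {"X99": 0.5}, seed=0)


class TestCounties:
    def test_single_county(self):
        labels = generate_counties((8, 8), 1, seed=0)
        assert (labels == 1).all()

    def test_64_counties_nonempty(self):
        labels = generate_counties((200, 200), 64, seed=1)
        uniq, counts = np.unique(labels, return_counts=True)
        np.testing.assert_array_equal(uniq, np.arange(1, 65))
        assert counts.min() >= 1

    def test_counties_connected(self):
        labels = generate_counties((100, 100), 30, seed=2)
        for lab in range(1, 31):
            _, n = ndimage.label(labels == lab)
            assert n == 1

    def test_determinism(self):
        a = generate_counties((50, 50), 10, seed=3)
        b = generate_counties((50, 50), 10, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_too_many_counties(self):
        with pytest.raises(ValueError):
            generate_counties((3, 3), 10, seed=0)


@pytest.fixture(scope="module")
def scenario():
    return generate_scenario(shape=(60, 60), T=3, n_counties=9, seed=42)


class TestScenario:
    def test_shapes_consistent(self, scenario):
        shp = scenario.landuse_series[0].shape
        assert all(g.shape == shp for g in scenario.landuse_series)
        assert all(g.shape == shp for g in scenario.ndvi_series)
        assert all(g.shape == shp for g in scenario.drivers.values())
        assert scenario.county_labels.shape == shp

    def test_landuse_codes_valid(self, scenario):
        for g in scenario.landuse_series:
            assert set(np.unique(g.values)) <= set(LANDUSE_CODES)

    def test_ndvi_range(self, scenario):
        for g in scenario.ndvi_series:
            assert g.values.min() >= -1.0 and g.values.max() <= 1.0

    def test_county_partition(self, scenario):
        labels = np.unique(scenario.county_labels)
        np.testing.assert_array_equal(labels, np.arange(1, 10))

    def test_truth_tables(self, scenario):
        props = scenario.truth.class_proportions_per_time
        np.testing.assert_allclose(props.sum(axis=1), 1.0, atol=1e-12)
        assert scenario.truth.planted_hotspot_mask.any()
        P = scenario.truth.transition_matrix
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_ndvi_correlates_with_cover(self, scenario):
        lu = scenario.landuse_series[0].values
        nd = scenario.ndvi_series[0].values
        outside = ~scenario.truth.planted_hotspot_mask
        forest = nd[(lu == 2) & outside].mean()
        water = nd[(lu == 4) & outside].mean()
        assert forest > water

    def test_determinism(self):
        a = generate_scenario(shape=(40, 40), T=2, n_counties=4, seed=5)
        b = generate_scenario(shape=(40, 40), T=2, n_counties=4, seed=5)
        for ga, gb in zip(a.landuse_series, b.landuse_series):
            np.testing.assert_array_equal(ga.values, gb.values)
        for ga, gb in zip(a.ndvi_series, b.ndvi_series):
            np.testing.assert_array_equal(ga.values, gb.values)
        for k in a.drivers:
            np.testing.assert_array_equal(a.drivers[k].values,
                                          b.drivers[k].values)
        np.testing.assert_array_equal(a.county_labels, b.county_labels)
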