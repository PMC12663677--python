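import numpy as np
import pytest

from tercab.attribution import (DriverScenario, attribute_stack,
                                attribution_summary, classify_driver,
                                contribution_levels, fit_climate_model)
from tercab.gridio import AnnualStack, Grid
from tercab.synthetic import (HumanPatch, SceneConfig, generate_scene,
                              inject_climate_signal)
from tercab.trend import pixel_slope


class TestFitClimateModel:
    def test_exact_recovery(self, rng):
        T = rng.uniform(20, 28, size=23)
        P = rng.uniform(1, 3, size=23)
        cb = 0.2 * T + 3.0 * P + 100.0
        fit = fit_climate_model(cb, T, P)
        assert fit.a == pytest.approx(0.2, rel=1e-9)
        assert fit.b == pytest.approx(3.0, rel=1e-9)
        assert fit.c == pytest.approx(100.0, rel=1e-9)
        np.testing.assert_allclose(fit.cb_ha, 0.0, atol=1e-9)

    def test_residuals_orthogonal_to_design(self, rng):
        T = rng.normal(size=23)
        P = rng.normal(size=23)
        cb = rng.normal(size=23)
        fit = fit_climate_model(cb, T, P)
        assert np.dot(fit.cb_ha, T) == pytest.approx(0.0, abs=1e-9)
        assert np.dot(fit.cb_ha, P) == pytest.approx(0.0, abs=1e-9)
        assert fit.cb_ha.sum() == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(50):
            T = rng.normal(size=23)
            P = rng.normal(size=23)
            cb = rng.normal(size=23)
            fit = fit_climate_model(cb, T, P)
            X = np.column_stack([T, P, np.ones(23)])
            beta = np.linalg.solve(X.T @ X, X.T @ cb)
            np.testing.assert_allclose([fit.a, fit.b, fit.c], beta, atol=1e-8)

    def test_noise_only_mean_slope_cc_near_zero(self, rng):
        slopes = []
        T = rng.uniform(20, 28, size=23)
        P = rng.uniform(1, 3, size=23)
        for _ in range(200):
            cb = rng.normal(size=23)
            fit = fit_climate_model(cb, T, P)
            slopes.append(pixel_slope(fit.cb_cc))
        assert np.mean(slopes) == pytest.approx(0.0, abs=0.01)

    def test_rank_deficiency_raises(self):
        T = np.full(23, 25.0)
        P = np.full(23, 2.0)
        with pytest.raises(np.linalg.LinAlgError):
            fit_climate_model(np.arange(23, dtype=float), T, P)

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_climate_model(np.ones(3), np.ones(3), np.ones(3))


class TestClassifyDriver:
    def test_both_positive_ratio_split(self):
        scen, cc, ha = classify_driver(1.0, 0.3, 0.7)
        assert scen is DriverScenario.IMPROVE_CC_HA
        assert cc == pytest.approx(30.0)
        assert ha == pytest.approx(70.0)

    def test_improve_climate_only(self):
        scen, cc, ha = classify_driver(1.0, 1.5, -0.5)
        assert scen is DriverScenario.IMPROVE_CC
        assert (cc, ha) == (100.0, 0.0)

    def test_degrade_human_only(self):
        # observed declining, climate pushing up, human pulling down
        scen, cc, ha = classify_driver(-1.0, 0.4, -1.4)
        assert scen is DriverScenario.DEGRADE_HA
        assert (cc, ha) == (0.0, 100.0)

    def test_degrade_climate_only(self):
        scen, cc, ha = classify_driver(-1.0, -1.4, 0.4)
        assert scen is DriverScenario.DEGRADE_CC
        assert (cc, ha) == (100.0, 0.0)

    def test_both_negative_ratio_split(self):
        scen, cc, ha = classify_driver(-1.0, -0.25, -0.75)
        assert scen is DriverScenario.DEGRADE_CC_HA
        assert cc == pytest.approx(25.0)
        assert ha == pytest.approx(75.0)

    def test_no_change_tolerance(self):
        scen, cc, ha = classify_driver(1e-15, 1e-15, 0.0)
        assert scen is DriverScenario.NO_CHANGE
        assert np.isnan(cc) and np.isnan(ha)

    def test_same_sign_contributions_sum_to_100(self, rng):
        for _ in range(100):
            cc_s = rng.uniform(0, 1)
            ha_s = rng.uniform(0, 1)
            _, cc, ha = classify_driver(cc_s + ha_s, cc_s, ha_s)
            assert cc + ha == pytest.approx(100.0, abs=1e-9)


class TestContributionLevels:
    @pytest.mark.parametrize("value,expected", [
        (85.0, "80-100"),
        (0.0, "0-20"),
        (20.0, "20-40"),   # left-closed bins
        (100.0, "80-100"),
        (59.999, "40-60"),
    ])
    def test_bins(self, value, expected):
        assert contribution_levels(value) == expected

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            contribution_levels(101.0)


class TestAttributeStack:
    def test_slope_additivity(self, rng):
        tmpl = Grid(np.zeros((5, 6)))
        yrs = range(2000, 2023)
        cb = AnnualStack.from_array(yrs, rng.normal(size=(23, 5, 6)), tmpl)
        T = AnnualStack.from_array(yrs, rng.normal(size=(23, 5, 6)), tmpl)
        P = AnnualStack.from_array(yrs, rng.normal(size=(23, 5, 6)), tmpl)
        maps = attribute_stack(cb, T, P)
        np.testing.assert_allclose(
            maps.slope_cc.values + maps.slope_ha.values,
            maps.slope_obs.values, atol=1e-10)

    def test_decomposition_identity(self, rng):
        """cb_cc + cb_ha == cb_obs via per-pixel refit."""
        tmpl = Grid(np.zeros((3, 3)))
        yrs = range(2000, 2023)
        arrs = rng.normal(size=(3, 23, 3, 3))
        cb, T, P = (AnnualStack.from_array(yrs, a, tmpl) for a in arrs)
        maps = attribute_stack(cb, T, P)
        for r in range(3):
            for c in range(3):
                fit = fit_climate_model(arrs[0][:, r, c], arrs[1][:, r, c],
                                        arrs[2][:, r, c])
                np.testing.assert_allclose(fit.cb_cc + fit.cb_ha,
                                           arrs[0][:, r, c], atol=1e-10)
                assert maps.a.values[r, c] == pytest.approx(fit.a, abs=1e-8)
                assert maps.slope_cc.values[r, c] == pytest.approx(
                    pixel_slope(fit.cb_cc), abs=1e-10)

    def test_pure_climate_scene_all_cc(self):
        scene = generate_scene(SceneConfig(shape=(10, 12), seed=21))
        cb = inject_climate_signal(scene, 0.2, 3.0, 100.0)
        maps = attribute_stack(cb, scene.temperature, scene.precipitation)
        defined = maps.scenario.values > 0
        assert defined.mean() > 0.95
        assert np.all(maps.contrib_cc.values[defined] > 99.999)

    def test_parameter_recovery_improves_as_noise_shrinks(self, rng):
        scene = generate_scene(SceneConfig(shape=(8, 8), seed=3))
        t = scene.temperature.to_array()
        p = scene.precipitation.to_array()
        tmpl = scene.temperature.template
        yrs = scene.temperature.years
        errs = []
        for sd in (1.0, 0.1, 0.001):
            cb_arr = 0.2 * t + 3.0 * p + 100.0 + rng.normal(0, sd, size=t.shape)
            cb = AnnualStack.from_array(yrs, cb_arr, tmpl)
            maps = attribute_stack(cb, scene.temperature, scene.precipitation)
            errs.append(np.nanmean(np.abs(maps.a.values - 0.2)))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-3

    def test_human_footprint_has_higher_ha_contribution(self):
        scene = generate_scene(SceneConfig(shape=(20, 20), seed=5))
        t = scene.temperature.to_array()
        p = scene.precipitation.to_array()
        cb_arr = 0.3 * t + 2.0 * p + 120.0
        fp = np.zeros((20, 20), dtype=bool)
        fp[5:12, 5:12] = True
        years = np.arange(len(scene.temperature.years))
        # human-driven decline on the footprint only
        cb_arr[:, fp] -= 2.0 * years[:, None]
        cb = AnnualStack.from_array(scene.temperature.years, cb_arr,
                                    scene.temperature.template)
        maps = attribute_stack(cb, scene.temperature, scene.precipitation)
        inside = np.nanmean(maps.contrib_ha.values[fp])
        outside = np.nanmean(maps.contrib_ha.values[~fp])
        assert inside > outside

    def test_rank_deficient_pixels_flagged(self):
        tmpl = Grid(np.zeros((2, 2)))
        yrs = range(2000, 2023)
        const = np.ones((23, 2, 2))
        cb = AnnualStack.from_array(yrs, np.random.default_rng(0).normal(size=(23, 2, 2)), tmpl)
        maps = attribute_stack(cb, AnnualStack.from_array(yrs, const, tmpl),
                               AnnualStack.from_array(yrs, const * 2, tmpl))
        assert (maps.scenario.values == -1).all()


def test_attribution_summary_improved_share():
    scene = generate_scene(SceneConfig(shape=(10, 10), seed=2))
    # strictly increasing observed balance everywhere
    years = np.arange(len(scene.temperature.years))
    t = scene.temperature.to_array()
    p = scene.precipitation.to_array()
    cb_arr = 0.1 * t + 1.0 * p + 100.0 + 0.5 * years[:, None, None]
    cb = AnnualStack.from_array(scene.temperature.years, cb_arr,
                                scene.temperature.template)
    maps = attribute_stack(cb, scene.temperature, scene.precipitation)
    summary = attribution_summary(maps, pixel_area_km2=0.01)
    assert summary.loc["improved", "share_pct"] == pytest.approx(100.0)
    assert summary.loc["degraded", "area_km2"] == 0.0
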