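import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vegclim import grid_core as gc
from vegclim import projection as pj
from vegclim import sensitivity as sn
from vegclim import synthetic_data as sd


def _linearized(model: sn.SensitivityModel) -> sn.SensitivityModel:
    def lin(s):
        return sn.QuadraticSurface(
            (0.0, 0.0, 0.0, *s.coeffs[3:]), s.predictors, s.regime, s.response_scale
        )

    return sn.SensitivityModel(
        snow_surface=lin(model.snow_surface),
        snowfree_surface=lin(model.snowfree_surface),
        snow_threshold=model.snow_threshold,
    )


def _toy_run(sc=0.0, sw=0.0, e=0.0, lai_start=1.0, lai_end=np.e):
    geo = gc.GridGeometry(lat=np.array([0.0, 10.0]), lon=np.array([0.0, 10.0]))
    years = [2015, 2016]
    time = np.array([[y, m] for y in years for m in range(1, 13)])

    def f(v_by_year, units):
        vals = np.stack(
            [np.full(geo.shape, v_by_year[y]) for y in years for _ in range(12)]
        )
        return gc.GridField(geometry=geo, time=time, values=vals, units=units)

    return pj.ScenarioRun(
        model="toy", scenario="s",
        lai=f({2015: lai_start, 2016: lai_end}, "m2/m2"),
        sc=f({2015: sc, 2016: sc}, "%"),
        sw=f({2015: sw, 2016: sw}, "W/m2"),
        e=f({2015: e, 2016: e}, "mm/day"),
        carbon=np.array([0.4, 0.5]),
        warming=np.array([0.0, 1.0]),
        baseline_year=2015,
    )


class TestBiophysicalDeltaT:
    def test_zero_lai_change(self):
        run = _toy_run(lai_end=1.0)
        out = pj.biophysical_delta_T(sn.published_surfaces(), run, 2016)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-15)

    def test_snowfree_unit_ln_change(self):
        run = _toy_run()  # SC=0, E=0, SW=0, LAI 1 -> e
        out = pj.biophysical_delta_T(sn.published_surfaces(), run, 2016)
        np.testing.assert_allclose(out.values, 0.42, rtol=1e-12)

    def test_snow_branch_absolute_change(self):
        run = _toy_run(sc=50.0, sw=100.0, lai_start=1.0, lai_end=2.0)
        out = pj.biophysical_delta_T(sn.published_surfaces(), run, 2016)
        expect = sn.eval_surface(sn.published_surfaces().snow_surface, 50.0, 100.0)
        np.testing.assert_allclose(out.values, expect, rtol=1e-12)

    def test_oracle_equivalence(self, small_scenario_ensemble):
        _, runs, truth = small_scenario_ensemble
        run = runs[0]
        for year in (2015, 2050, 2100):
            a = pj.biophysical_delta_T(truth.model, run, year).values
            b = sd.ground_truth_delta_T(truth, run, year).values
            np.testing.assert_array_equal(a, b)


class TestFactorialAttribution:
    def test_baseline_drivers_give_zero_climate_effect(self):
        run = _toy_run(sc=30.0, sw=150.0, e=2.0)  # drivers constant in time
        att = pj.factorial_attribution(sn.published_surfaces(), run)
        np.testing.assert_allclose(att.climate_effect, 0.0, atol=1e-15)
        for term in att.driver_terms.values():
            np.testing.assert_allclose(term, 0.0, atol=1e-15)

    def test_exact_closure(self, small_scenario_ensemble):
        _, runs, truth = small_scenario_ensemble
        att = pj.factorial_attribution(truth.model, runs[3])
        np.testing.assert_array_equal(
            att.climate_effect, att.all_effects - att.lai_effect
        )

    def test_linear_surface_additivity(self, small_scenario_ensemble):
        # pick a weak scenario so no cell-month crosses the snow threshold
        _, runs, truth = small_scenario_ensemble
        run = next(r for r in runs if r.scenario == "ssp126")
        lin = _linearized(truth.model)
        att = pj.factorial_attribution(lin, run)
        total = sum(att.driver_terms.values())
        assert np.nanmax(np.abs(att.climate_effect - total)) < 1e-9

    def test_regime_flip_residual_is_reported(self, small_scenario_ensemble):
        # under strong snow decline cells cross the 1% threshold and the
        # driver terms need not add up; the shortfall must be surfaced
        _, runs, truth = small_scenario_ensemble
        run = next(r for r in runs if r.scenario == "ssp585")
        att = pj.factorial_attribution(_linearized(truth.model), run)
        total = sum(att.driver_terms.values())
        np.testing.assert_allclose(
            att.closure_residual, att.climate_effect - total, atol=1e-15
        )

    def test_missing_baseline_raises(self):
        run = _toy_run()
        with pytest.raises(pj.ProjectionError):
            pj.factorial_attribution(sn.published_surfaces(), run, baseline_year=1999)


class TestBiochemicalDeltaT:
    def test_unit_carbon(self):
        assert abs(pj.biochemical_delta_T(1.0)) == pytest.approx(2.2)

    def test_sign_is_cooling(self):
        assert pj.biochemical_delta_T(1.0) < 0

    def test_zero(self):
        assert pj.biochemical_delta_T(0.0) == 0.0

    def test_half(self):
        assert abs(pj.biochemical_delta_T(0.5)) == pytest.approx(1.1)

    @given(st.floats(-10, 10), st.floats(0.1, 5))
    @settings(max_examples=50, deadline=None)
    def test_degree_one_homogeneity(self, db, k):
        assert pj.biochemical_delta_T(k * db) == pytest.approx(
            k * pj.biochemical_delta_T(db), rel=1e-12, abs=1e-12
        )


class TestLinearTrend:
    def test_exact_line(self):
        years = np.arange(2000, 2020)
        vals = 0.01 * (years - 2000.0)
        out = pj.linear_trend(vals[:, None, None], years)
        assert out[0, 0] == pytest.approx(0.01, rel=1e-9)

    def test_constant_series(self):
        years = np.arange(2000, 2010)
        out = pj.linear_trend(np.ones((10, 1, 1)), years)
        assert out[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_three_points(self):
        out = pj.linear_trend(np.array([0.0, 1.0, 2.0])[:, None], [0, 1, 2])
        assert out[0] == pytest.approx(1.0)

    def test_decadal_scaling(self):
        years = np.arange(2000, 2020)
        vals = 0.01 * (years - 2000.0)
        out = pj.linear_trend(vals[:, None], years, per=10.0)
        assert out[0] == pytest.approx(0.1, rel=1e-9)

    def test_too_few_points_raises(self):
        with pytest.raises(pj.ProjectionError):
            pj.linear_trend(np.zeros((2, 1)), [0, 1])


class TestEnsembleStats:
    def test_identical_members(self):
        out = pj.ensemble_stats([np.ones(4)] * 3)
        np.testing.assert_array_equal(out["median"], out["min"])
        np.testing.assert_array_equal(out["median"], out["max"])

    def test_three_values(self):
        out = pj.ensemble_stats([np.array([1.0]), np.array([2.0]), np.array([4.0])])
        assert out["median"][0] == 2.0
        assert out["min"][0] == 1.0 and out["max"][0] == 4.0

    def test_quartile_convention(self):
        members = [np.array([v]) for v in (1.0, 2.0, 3.0, 4.0)]
        out = pj.ensemble_stats(members)
        assert out["q1"][0] == pytest.approx(1.75)
        assert out["q3"][0] == pytest.approx(3.25)

    def test_single_member_raises(self):
        with pytest.raises(pj.ProjectionError):
            pj.ensemble_stats([np.ones(3)])


class TestClimateZoneAggregate:
    def _setup(self, lats=(-10.0, 10.0)):
        geo = gc.GridGeometry(lat=np.asarray(lats), lon=np.array([0.0, 10.0]))
        zones = gc.ClimateZoneMap(geometry=geo, zone=np.full(geo.shape, 1))
        weights = gc.cell_area_weights(geo)
        return geo, zones, weights

    def test_constant_field(self):
        geo, zones, weights = self._setup()
        vals = np.full((3, 12, *geo.shape), 2.5)
        annual, seasonal = pj.climate_zone_aggregate(vals, [0, 1, 2], zones, weights)
        np.testing.assert_allclose(annual.loc["Equatorial"], 2.5)
        np.testing.assert_allclose(seasonal.loc["Equatorial"], 2.5)

    def test_single_zone_equals_area_weighted_mean(self):
        geo, zones, weights = self._setup(lats=(0.0, 60.0))
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(1, 12, *geo.shape))
        annual, _ = pj.climate_zone_aggregate(vals, [0], zones, weights)
        expect = np.mean(
            [gc.area_weighted_mean(vals[0, m], weights) for m in range(12)]
        )
        assert annual.loc["Equatorial", 0] == pytest.approx(expect, rel=1e-12)

    def test_hand_weighted_two_cells(self):
        # weights 1 and 0.5 via latitudes 0/60, values 3 and 0 -> 2
        geo = gc.GridGeometry(lat=np.array([0.0, 60.0]), lon=np.array([0.0, 10.0]))
        zones = gc.ClimateZoneMap(geometry=geo, zone=np.full(geo.shape, 2))
        weights = gc.cell_area_weights(geo)
        vals = np.full((1, 12, *geo.shape), np.nan)
        vals[:, :, 0, 0] = 3.0
        vals[:, :, 1, 0] = 0.0
        annual, _ = pj.climate_zone_aggregate(vals, [0], zones, weights)
        assert annual.loc["Arid", 0] == pytest.approx(2.0, rel=1e-12)

    def test_southern_cycle_shifted(self):
        geo = gc.GridGeometry(lat=np.array([-20.0, -10.0]), lon=np.array([0.0, 10.0]))
        zones = gc.ClimateZoneMap(geometry=geo, zone=np.full(geo.shape, 1))
        weights = gc.cell_area_weights(geo)
        cycle = np.arange(1.0, 13.0)
        vals = np.broadcast_to(cycle[None, :, None, None], (1, 12, 2, 2)).copy()
        _, seasonal = pj.climate_zone_aggregate(vals, [0], zones, weights)
        np.testing.assert_allclose(
            seasonal.loc["Equatorial"], [7, 8, 9, 10, 11, 12, 1, 2, 3, 4, 5, 6]
        )

    def test_polar_excluded(self):
        geo, _, weights = self._setup()
        zones = gc.ClimateZoneMap(geometry=geo, zone=np.full(geo.shape, 5))
        vals = np.ones((1, 12, *geo.shape))
        annual, _ = pj.climate_zone_aggregate(vals, [0], zones, weights)
        assert annual.empty


class TestLinearLaiRun:
    def test_identity_on_linear_trajectory(self):
        run = _toy_run(lai_start=1.0, lai_end=1.5)  # two points: exactly linear
        lin = pj.linear_lai_run(run)
        np.testing.assert_allclose(lin.lai.values, run.lai.values, rtol=1e-12)
        model = sn.published_surfaces()
        a = pj.biophysical_delta_T(model, run, 2016).values
        b = pj.biophysical_delta_T(model, lin, 2016).values
        np.testing.assert_allclose(a, b, rtol=1e-10)

    def test_smooths_nonlinear_trajectory(self):
        geo = gc.GridGeometry(lat=np.array([0.0, 10.0]), lon=np.array([0.0, 10.0]))
        years = [2015, 2016, 2017]
        time = np.array([[y, m] for y in years for m in range(1, 13)])
        traj = {2015: 1.0, 2016: 1.1, 2017: 1.4}  # convex, not linear

        def f(v_by_year, units):
            vals = np.stack(
                [np.full(geo.shape, v_by_year[y]) for y in years for _ in range(12)]
            )
            return gc.GridField(geometry=geo, time=time, values=vals, units=units)

        run = pj.ScenarioRun(
            model="toy", scenario="s",
            lai=f(traj, "m2/m2"), sc=f(dict.fromkeys(years, 0.0), "%"),
            sw=f(dict.fromkeys(years, 0.0), "W/m2"),
            e=f(dict.fromkeys(years, 0.0), "mm/day"),
            carbon=np.zeros(3), warming=np.zeros(3), baseline_year=2015,
        )
        lin = pj.linear_lai_run(run)
        assert not np.allclose(lin.lai.values, run.lai.values)
        # OLS slope through {1.0, 1.1, 1.4} is 0.2/yr
        np.testing.assert_allclose(
            lin.lai.sel(2016, 1) - lin.lai.sel(2015, 1), 0.2, rtol=1e-12
        )


class TestZonePartitionRefinement:
    def test_refined_zones_recombine_to_coarse_aggregate(self):
        geo = gc.GridGeometry(
            lat=np.array([0.0, 20.0, 40.0, 60.0]), lon=np.array([0.0, 10.0])
        )
        weights = gc.cell_area_weights(geo)
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(2, 12, *geo.shape))
        coarse = gc.ClimateZoneMap(geometry=geo, zone=np.full(geo.shape, 1))
        fine_codes = np.full(geo.shape, 1)
        fine_codes[2:] = 2
        fine = gc.ClimateZoneMap(geometry=geo, zone=fine_codes)
        a_coarse, _ = pj.climate_zone_aggregate(vals, [0, 1], coarse, weights)
        a_fine, _ = pj.climate_zone_aggregate(vals, [0, 1], fine, weights)
        w1 = weights.w[fine_codes == 1].sum()
        w2 = weights.w[fine_codes == 2].sum()
        recombined = (
            w1 * a_fine.loc["Equatorial"] + w2 * a_fine.loc["Arid"]
        ) / (w1 + w2)
        np.testing.assert_allclose(
            a_coarse.loc["Equatorial"], recombined, rtol=1e-12
        )


class TestRelativeMitigation:
    def test_ten_percent(self):
        assert pj.relative_mitigation(0.5, 5.0) == pytest.approx(10.0)

    def test_zero_cooling(self):
        assert pj.relative_mitigation(0.0, 3.0) == 0.0

    def test_headline_ratio_structure(self):
        assert pj.relative_mitigation(0.7, 2.0) == pytest.approx(35.0)

    def test_zero_warming_raises(self):
        with pytest.raises(pj.ProjectionError):
            pj.relative_mitigation(0.5, 0.0)


class TestMitigationSummary:
    def test_summary_structure_and_signs(self, small_scenario_ensemble):
        cfg, runs, truth = small_scenario_ensemble
        weights = gc.cell_area_weights(cfg.geometry)
        out = pj.mitigation_summary(truth.model, runs, weights)
        assert set(out["scenario"]) == {name for name, _ in cfg.scenarios}
        med = out[out["stat"] == "median"].set_index("scenario")
        # biophysical + biochemical are coolings, warming positive
        assert (med["biophysical"] < 0).all()
        assert (med["biochemical"] < 0).all()
        assert (med["warming"] > 0).all()
        assert (med["relative_pct"] > 0).all()

    def test_relative_declines_with_scenario_strength(self, small_scenario_ensemble):
        cfg, runs, truth = small_scenario_ensemble
        weights = gc.cell_area_weights(cfg.geometry)
        out = pj.mitigation_summary(truth.model, runs, weights)
        med = out[out["stat"] == "median"].set_index("scenario")
        rel = [med.loc[name, "relative_pct"] for name, _ in cfg.scenarios]
        assert rel[0] > rel[-1]
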