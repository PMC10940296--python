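import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cropsuit.engine import (ClimateStack, EngineConfig, cell_suitability,
                             duration_months, growing_window, map_suitability,
                             ph_suitability, rain_suitability_season,
                             temp_suitability_season, trapezoid_suitability)
from cropsuit.geo import GeometryError, GridGeometry

from conftest import random_params, random_stack
from oracles import cell_suitability_loop, map_suitability_loop, trapezoid_scalar


class TestTrapezoid:
    def test_optimum_plateau(self):
        assert trapezoid_suitability(15, 0, 10, 20, 30) == 1.0
        assert trapezoid_suitability(10, 0, 10, 20, 30) == 1.0

    def test_absolute_bounds_zero(self):
        assert trapezoid_suitability(0, 0, 10, 20, 30) == 0.0
        assert trapezoid_suitability(30, 0, 10, 20, 30) == 0.0
        assert trapezoid_suitability(-5, 0, 10, 20, 30) == 0.0

    def test_linear_midpoints(self):
        assert trapezoid_suitability(5, 0, 10, 20, 30) == pytest.approx(0.5)
        assert trapezoid_suitability(25, 0, 10, 20, 30) == pytest.approx(0.5)

    def test_degenerate_step(self):
        # amin == omin: step up at the bound
        assert trapezoid_suitability(10, 10, 10, 20, 30) == 1.0
        assert trapezoid_suitability(9.999, 10, 10, 20, 30) == 0.0
        # omax == amax: step down past the bound
        assert trapezoid_suitability(20, 0, 10, 20, 20) == 1.0
        assert trapezoid_suitability(20.001, 0, 10, 20, 20) == 0.0

    def test_ordering_violation_raises(self):
        with pytest.raises(ValueError):
            trapezoid_suitability(5, 10, 5, 20, 30)

    def test_nan_propagates(self):
        assert np.isnan(trapezoid_suitability(float("nan"), 0, 10, 20, 30))

    def test_vectorized_matches_scalar(self):
        x = np.linspace(-10, 40, 101)
        got = trapezoid_suitability(x, 0, 10, 20, 30)
        expected = [trapezoid_scalar(v, 0, 10, 20, 30) for v in x]
        np.testing.assert_allclose(got, expected)

    @given(bounds=st.lists(st.floats(-50, 50), min_size=4, max_size=4),
           x=st.floats(-100, 100))
    def test_range_invariant(self, bounds, x):
        amin, omin, omax, amax = sorted(bounds)
        v = trapezoid_suitability(x, amin, omin, omax, amax)
        assert 0.0 <= v <= 1.0


class TestDurationAndWindow:
    def test_half_up_rounding(self, simple_params):
        # (90 + 120)/60 = 3.5 -> 4
        assert duration_months(simple_params) == 4

    def test_full_year_clamp(self, simple_params):
        assert duration_months(simple_params.replace(gmin=360, gmax=360)) == 12
        assert duration_months(simple_params.replace(gmin=365, gmax=365)) == 12

    def test_lower_clamp(self, simple_params):
        assert duration_months(simple_params.replace(gmin=30, gmax=30)) == 1

    def test_wraparound(self):
        assert growing_window(11, 4) == [11, 12, 1, 2]

    def test_whole_year(self):
        assert growing_window(1, 12) == list(range(1, 13))

    def test_single_month(self):
        assert growing_window(6, 1) == [6]

    def test_invalid_duration(self):
        with pytest.raises(ValueError):
            growing_window(1, 13)
        with pytest.raises(ValueError):
            growing_window(1, 0)
        with pytest.raises(ValueError):
            growing_window(0, 3)


class TestSeasonScores:
    def test_optimal_months_score_one(self, simple_params, engine_config):
        tmean = [20.0] * 12
        assert temp_suitability_season(tmean, simple_params, [1, 2, 3],
                                       engine_config) == 1.0

    def test_kill_month_zeroes_window(self, simple_params, engine_config):
        tmean = [20.0] * 12
        tminm = [15.0] * 12
        tminm[1] = simple_params.ktmp + engine_config.frost_buffer - 0.1
        assert temp_suitability_season(tmean, simple_params, [1, 2, 3],
                                       engine_config, tminm) == 0.0

    def test_minimum_over_months(self, simple_params, engine_config):
        # months engineered to score 1.0, 0.6, 0.8 on the lower ramp
        tmean = [20.0] * 12
        tmean[1] = 13.0   # (13-10)/5 = 0.6
        tmean[2] = 14.0   # 0.8
        got = temp_suitability_season(tmean, simple_params, [1, 2, 3], engine_config)
        scores = [trapezoid_scalar(tmean[m - 1], 10, 15, 25, 30) for m in [1, 2, 3]]
        assert got == pytest.approx(min(scores)) == pytest.approx(0.6)

    def test_missing_month_returns_nan(self, simple_params, engine_config):
        tmean = [20.0] * 12
        tmean[2] = float("nan")
        assert np.isnan(temp_suitability_season(tmean, simple_params, [1, 2, 3],
                                                engine_config))

    def test_rain_total_at_optimum(self, simple_params):
        prec = [100.0] * 12
        assert rain_suitability_season(prec, simple_params, [1, 2, 3]) == 1.0

    def test_rain_zero_with_positive_rmin(self, simple_params):
        assert rain_suitability_season([0.0] * 12, simple_params, [1, 2, 3]) == 0.0

    def test_rain_lower_ramp_midpoint(self, simple_params):
        # total 250 = (200 + 300)/2 -> 0.5
        prec = [250.0 / 3] * 12
        got = rain_suitability_season(prec, simple_params, [1, 2, 3])
        assert got == pytest.approx(0.5)

    def test_ph_plateau_and_bounds(self, simple_params):
        assert ph_suitability(6.0, simple_params) == 1.0
        assert ph_suitability(4.0, simple_params) == 0.0
        # midpoint of upper ramp (7.0, 8.5)
        assert ph_suitability(7.75, simple_params) == pytest.approx(0.5)


class TestCellSuitability:
    def test_uniform_optimum_scores_one(self, simple_params):
        assert cell_suitability([20.0] * 12, [150.0] * 12, 6.0,
                                simple_params) == 1.0

    def test_everywhere_frozen_scores_zero(self, simple_params, engine_config):
        tmean = [20.0] * 12
        tminm = [simple_params.ktmp + engine_config.frost_buffer - 1] * 12
        assert cell_suitability(tmean, [150.0] * 12, 6.0, simple_params,
                                engine_config, tminm) == 0.0

    def test_single_viable_window_product(self, simple_params, engine_config):
        # only months 1-4 escape frost; temp ramp gives 0.8, rain gives 0.5
        tmean = [13.0] * 12    # below tmin+... -> (13-10)/5 = 0.6? use 14: 0.8
        tmean = [14.0] * 12
        tminm = [1.0] * 12     # < ktmp+4 -> frozen everywhere ...
        for m in range(4):
            tminm[m] = 10.0    # ... except months 1-4
        prec = [0.0] * 12
        for m in range(4):
            prec[m] = 62.5     # total 250 -> rain 0.5
        got = cell_suitability(tmean, prec, 6.0, simple_params, engine_config, tminm)
        assert got == pytest.approx(0.8 * 0.5)
        oracle = cell_suitability_loop(tmean, prec, 6.0, simple_params, tminm=tminm)
        assert got == pytest.approx(oracle)

    def test_matches_loop_oracle_random(self, engine_config):
        rng = np.random.default_rng(7)
        for _ in range(25):
            tmean = list(rng.uniform(0, 40, 12))
            prec = list(rng.uniform(0, 300, 12))
            ph = float(rng.uniform(3, 10))
            p = random_params(rng)
            got = cell_suitability(tmean, prec, ph, p, engine_config)
            expected = cell_suitability_loop(tmean, prec, ph, p)
            assert got == pytest.approx(expected, abs=1e-12)


class TestMapSuitability:
    def test_all_optimal_toy_world(self, simple_params):
        geom = GridGeometry.from_bounds(0, 1, 0, 1, 0.5)
        tmean = np.full((12, 2, 2), 20.0)
        prec = np.full((12, 2, 2), 150.0)
        stack = ClimateStack(geom, tmean, prec)
        out = map_suitability(stack, np.full((2, 2), 6.0), simple_params)
        np.testing.assert_array_equal(out.values, 1.0)

    def test_masked_cell_missing(self, simple_params):
        geom = GridGeometry.from_bounds(0, 1, 0, 1, 0.5)
        mask = np.array([[True, False], [True, True]])
        stack = ClimateStack(geom, np.full((12, 2, 2), 20.0),
                             np.full((12, 2, 2), 150.0), land_mask=mask)
        out = map_suitability(stack, np.full((2, 2), 6.0), simple_params)
        assert np.isnan(out.values[0, 1])
        assert out.values[1, 1] == 1.0

    def test_missing_ph_missing_out(self, simple_params):
        geom = GridGeometry.from_bounds(0, 1, 0, 1, 0.5)
        stack = ClimateStack(geom, np.full((12, 2, 2), 20.0),
                             np.full((12, 2, 2), 150.0))
        ph = np.full((2, 2), 6.0)
        ph[0, 0] = np.nan
        out = map_suitability(stack, ph, simple_params)
        assert np.isnan(out.values[0, 0])

    def test_geometry_mismatch_raises(self, simple_params):
        geom = GridGeometry.from_bounds(0, 1, 0, 1, 0.5)
        stack = ClimateStack(geom, np.full((12, 2, 2), 20.0),
                             np.full((12, 2, 2), 150.0))
        with pytest.raises(GeometryError):
            map_suitability(stack, np.full((3, 3), 6.0), simple_params)

    def test_equals_scalar_loop_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            stack = random_stack(rng)
            ph = rng.uniform(3, 10, size=stack.geom.shape)
            p = random_params(rng)
            got = map_suitability(stack, ph, p).values
            expected = map_suitability_loop(stack, ph, p)
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_invalid_params_raise(self, simple_params):
        geom = GridGeometry.from_bounds(0, 1, 0, 1, 0.5)
        stack = ClimateStack(geom, np.full((12, 2, 2), 20.0),
                             np.full((12, 2, 2), 150.0))
        bad = simple_params.replace(topmin=26, topmax=25)
        with pytest.raises(ValueError, match="invalid crop parameters"):
            map_suitability(stack, np.full((2, 2), 6.0), bad)


class TestEngineProperties:
    def test_output_range(self):
        rng = np.random.default_rng(3)
        stack = random_stack(rng, 8, 8)
        ph = rng.uniform(3, 10, size=stack.geom.shape)
        p = random_params(rng)
        v = map_suitability(stack, ph, p).values
        assert np.nanmin(v) >= 0.0 and np.nanmax(v) <= 1.0

    @pytest.mark.parametrize("k", [1, 3, 6, 11])
    def test_cyclic_invariance(self, k):
        rng = np.random.default_rng(5)
        stack = random_stack(rng, 6, 6)
        ph = rng.uniform(3, 10, size=stack.geom.shape)
        p = random_params(rng)
        base = map_suitability(stack, ph, p).values
        rotated = map_suitability(stack.rotated(k), ph, p).values
        np.testing.assert_array_equal(base, rotated)

    def test_niche_widening_monotonicity(self):
        rng = np.random.default_rng(9)
        stack = random_stack(rng, 6, 6)
        ph = rng.uniform(3, 10, size=stack.geom.shape)
        p = random_params(rng)
        base = map_suitability(stack, ph, p).values
        wider = p.replace(rmin=max(0.0, p.rmin - 100),
                          ropmin=max(0.0, p.ropmin - 50))
        v = map_suitability(stack, ph, wider).values
        assert np.all(v[~np.isnan(v)] >= base[~np.isnan(base)] - 1e-12)
        cooler = p.replace(tmin=p.tmin - 5, ktmp=p.ktmp - 5)
        v2 = map_suitability(stack, ph, cooler).values
        assert np.all(v2[~np.isnan(v2)] >= base[~np.isnan(base)] - 1e-12)

    def test_product_rule_below_min_rule(self):
        rng = np.random.default_rng(13)
        stack = random_stack(rng, 6, 6)
        ph = rng.uniform(3, 10, size=stack.geom.shape)
        p = random_params(rng)
        prod = map_suitability(stack, ph, p, EngineConfig()).values
        mn = map_suitability(stack, ph, p,
                             EngineConfig(combine_rule="min", ph_rule="min")).values
        assert np.all(prod[~np.isnan(prod)] <= mn[~np.isnan(mn)] + 1e-12)

    def test_single_season_no_accumulation(self, engine_config):
        """Final score never exceeds the best single window's climate score."""
        rng = np.random.default_rng(17)
        stack = random_stack(rng, 5, 5)
        ph = rng.uniform(3, 10, size=stack.geom.shape)
        p = random_params(rng)
        got = map_suitability(stack, ph, p).values
        # oracle: best single window, combined with pH (never summed)
        expected = map_suitability_loop(stack, ph, p)
        np.testing.assert_allclose(got, expected, atol=1e-12)
        assert np.nanmax(got) <= 1.0


class TestClimateStackValidation:
    def test_negative_precip_rejected(self):
        geom = GridGeometry.from_bounds(0, 1, 0, 1, 0.5)
        prec = np.full((12, 2, 2), 10.0)
        prec[0, 0, 0] = -1
        with pytest.raises(ValueError, match="non-negative"):
            ClimateStack(geom, np.full((12, 2, 2), 20.0), prec)

    def test_tminm_above_tmean_rejected(self):
        geom = GridGeometry.from_bounds(0, 1, 0, 1, 0.5)
        tmean = np.full((12, 2, 2), 20.0)
        with pytest.raises(ValueError, match="minimum temperature"):
            ClimateStack(geom, tmean, np.full((12, 2, 2), 10.0), tminm=tmean + 1)

    def test_shape_mismatch_rejected(self):
        geom = GridGeometry.from_bounds(0, 1, 0, 1, 0.5)
        with pytest.raises(GeometryError):
            ClimateStack(geom, np.full((11, 2, 2), 20.0), np.full((12, 2, 2), 1.0))
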