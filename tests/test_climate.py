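import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dvvrisk.climate import (
    DAYS_IN_MONTH,
    PERIODS,
    CoverageError,
    PeriodDefinition,
    ReferencePeriod,
    SeasonWindow,
    WarmingSchedule,
    anomaly_map,
    apply_warming,
    gdd,
    presence_anomaly_overlap,
    warm_season_mean,
    warming_delta,
)
from dvvrisk.grids import GridSpec, MonthlyClimateGrid
from dvvrisk.synthetic import ClimatologyParams, generate_annual_series

from conftest import constant_grid


class TestWarmingSchedule:
    @pytest.mark.parametrize(
        "year,expected",
        [(2024, 1.4), (2029, 1.6), (2034, 1.8), (2039, 2.0), (2044, 2.2), (2049, 2.4), (2054, 2.6)],
    )
    def test_printed_schedule_exact(self, year, expected):
        assert warming_delta(year) == pytest.approx(expected, abs=1e-12)

    def test_extrapolation_to_2074(self):
        assert warming_delta(2074) == pytest.approx(3.4, abs=1e-12)

    def test_historical_year_rejected(self):
        with pytest.raises(ValueError, match="anomalies"):
            warming_delta(2023)

    def test_five_year_step_is_constant(self):
        s = WarmingSchedule()
        for y in range(2024, 2070):
            assert s.delta(y + 5) - s.delta(y) == pytest.approx(s.step_per_5yr, abs=1e-12)

    def test_table_matches_delta(self):
        t = WarmingSchedule().table()
        assert list(t["year"]) == [2024, 2029, 2034, 2039, 2044, 2049, 2054]
        assert t["delta_c"].tolist() == pytest.approx([1.4, 1.6, 1.8, 2.0, 2.2, 2.4, 2.6])


class TestApplyWarming:
    def test_identity_and_inverse(self, quiet_climatology):
        assert np.array_equal(apply_warming(quiet_climatology, 0.0).tmean, quiet_climatology.tmean)
        round_trip = apply_warming(apply_warming(quiet_climatology, 1.4), -1.4)
        assert np.allclose(round_trip.tmean, quiet_climatology.tmean, atol=1e-12)

    def test_commutes_with_warm_season_mean(self, quiet_climatology):
        delta = 2.6
        shifted = warm_season_mean(apply_warming(quiet_climatology, delta))
        assert np.allclose(shifted, warm_season_mean(quiet_climatology) + delta, atol=1e-9)

    def test_nonfinite_delta_rejected(self, quiet_climatology):
        with pytest.raises(ValueError):
            apply_warming(quiet_climatology, float("nan"))


class TestAnomalyMap:
    def test_period_equal_reference_is_zero(self, coarse_grid):
        params = ClimatologyParams(seed=3)
        series = generate_annual_series(coarse_grid, params, range(1991, 2021))
        ref = ReferencePeriod()
        dat = anomaly_map(series, PeriodDefinition("ref", ref.start, ref.end), ref)
        assert np.allclose(dat, 0.0, atol=1e-12)

    def test_uniform_offset_recovered(self, coarse_grid, quiet_params):
        series = generate_annual_series(coarse_grid, quiet_params, range(1991, 2022))
        series[2021] = MonthlyClimateGrid(coarse_grid, series[2021].tmean + 1.0)
        base = anomaly_map(series, PeriodDefinition("p", 2021, 2021), ReferencePeriod())
        expected = 1.0 + quiet_params.trend_per_year * (2021 - 2005.5)
        assert np.allclose(base, expected, atol=1e-9)

    def test_matches_two_mean_oracle(self, coarse_grid):
        """Vectorized DAT equals brute-force per-cell averaging."""
        params = ClimatologyParams(seed=9)
        series = generate_annual_series(coarse_grid, params, range(1991, 2025))
        period = PERIODS[-1]  # 1992-2024
        dat = anomaly_map(series, period)
        stack_p = np.array([series[y].tmean.mean(axis=0) for y in period.years])
        stack_r = np.array([series[y].tmean.mean(axis=0) for y in range(1991, 2021)])
        oracle = stack_p.mean(axis=0) - stack_r.mean(axis=0)
        assert np.allclose(dat, oracle, atol=1e-9)

    def test_missing_years_rejected(self, coarse_grid, quiet_params):
        series = generate_annual_series(coarse_grid, quiet_params, range(1991, 2000))
        with pytest.raises(CoverageError):
            anomaly_map(series, PERIODS[-1])


class TestGdd:
    def test_warm_season_arithmetic(self):
        months = [0, 0, 0, 20, 20, 20, 20, 20, 20, 0, 0, 0]
        assert gdd(months, base=10.0) == pytest.approx((20 - 10) * 183)

    def test_all_months_at_base_is_zero(self):
        assert gdd([10.0] * 12, base=10.0) == 0.0

    def test_monotone_in_base_cellwise(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(-5, 30, size=(12, 8, 8))
        assert (gdd(t, base=10.0) >= gdd(t, base=12.0)).all()

    def test_wrong_month_count_rejected(self):
        with pytest.raises(ValueError):
            gdd([20.0] * 11)

    @given(
        st.lists(st.floats(-20, 40, allow_nan=False), min_size=12, max_size=12),
        st.floats(-5, 15, allow_nan=False),
        st.floats(-3, 3, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_translation_consistency(self, months, base, shift):
        """gdd(T + c, base + c) == gdd(T, base)."""
        shifted = gdd(np.asarray(months) + shift, base=base + shift)
        assert shifted == pytest.approx(gdd(months, base=base), rel=1e-9, abs=1e-6)


class TestWarmSeasonMean:
    def test_constant_grid(self):
        g = constant_grid(GridSpec(lon_min=0, lon_max=2, lat_min=40, lat_max=42, resolution=1.0), [15.0] * 12)
        assert np.allclose(warm_season_mean(g), 15.0)

    def test_window_arithmetic(self):
        months = [0, 0, 0, 10, 12, 14, 16, 18, 20, 0, 0, 0]
        g = constant_grid(GridSpec(lon_min=0, lon_max=1, lat_min=40, lat_max=41, resolution=1.0), months)
        assert np.allclose(warm_season_mean(g), 15.0)

    def test_matches_month_loop_oracle(self, coarse_grid):
        rng = np.random.default_rng(4)
        g = MonthlyClimateGrid(coarse_grid, rng.normal(10, 8, size=(12, coarse_grid.nlat, coarse_grid.nlon)))
        w = SeasonWindow()
        oracle = sum(g.month(m) for m in w.months) / w.length
        assert np.allclose(warm_season_mean(g, w), oracle, atol=1e-12)


class TestPresenceOverlap:
    def _grid(self):
        return GridSpec(lon_min=0, lon_max=4, lat_min=40, lat_max=44, resolution=1.0)

    def test_all_above_threshold(self):
        g = self._grid()
        dat = np.full(g.shape, 2.0)
        pts = [(0.5, 40.5), (3.5, 43.5)]
        assert presence_anomaly_overlap(pts, dat, g, threshold=1.0) == 1.0

    def test_checkerboard_half(self):
        g = self._grid()
        dat = np.indices(g.shape).sum(axis=0) % 2 * 2.0  # 0 / 2 checkerboard
        pts = [(x + 0.5, y + 0.5) for x in range(4) for y in range(40, 44)]
        assert presence_anomaly_overlap(pts, dat, g, threshold=1.0) == pytest.approx(0.5)

    def test_outside_point_excluded_with_warning(self):
        g = self._grid()
        dat = np.full(g.shape, 2.0)
        with pytest.warns(UserWarning, match="outside grid"):
            frac = presence_anomaly_overlap([(0.5, 40.5), (99.0, 0.0)], dat, g, 1.0)
        assert frac == 1.0

    def test_empty_returns_nan_sentinel(self):
        g = self._grid()
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(presence_anomaly_overlap([], np.zeros(g.shape), g, 1.0))
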