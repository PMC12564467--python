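import numpy as np
import pytest

from dvvrisk.geo import haversine_km
from dvvrisk.grids import GridSpec
from dvvrisk.spread import (
    CATEGORY_CODES,
    DispersalConfig,
    InfestationState,
    LogisticParams,
    affected_categories,
    fit_logistic_rate,
    fit_logistic_series,
    logistic_fraction,
    simulate_spread,
    spread_series,
)


class TestLogistic:
    def test_t_zero_is_p0(self):
        assert logistic_fraction(0.0) == pytest.approx(0.40, abs=1e-15)

    def test_zero_rate_is_constant(self):
        p = LogisticParams(r=0.0)
        for t in (0, 5, 50):
            assert logistic_fraction(t, p) == pytest.approx(p.p0, abs=1e-15)

    def test_default_endpoint_2054(self):
        """Defaults put 95% of suitable area infested 30 years on."""
        assert logistic_fraction(30.0) == pytest.approx(0.950, abs=1e-3)

    def test_strictly_increasing(self):
        t = np.linspace(0, 60, 200)
        p = np.asarray(logistic_fraction(t))
        assert (np.diff(p) > 0).all() and p.max() < 1.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            LogisticParams(p0=0.0)
        with pytest.raises(ValueError):
            LogisticParams(p0=1.2, k=1.0)
        with pytest.raises(ValueError):
            logistic_fraction(-1.0)

    def test_matches_forward_euler_oracle(self):
        """Closed form vs dP/dt = rP(1 - P/k) integrated at dt = 0.01."""
        p = LogisticParams()
        dt = 0.01
        P = p.p0
        for step in range(int(50 / dt)):
            P += dt * p.r * P * (1 - P / p.k)
            t = (step + 1) * dt
            if abs(t - round(t)) < 1e-9:
                exact = logistic_fraction(round(t), p)
                assert abs(P - exact) / exact < 1e-3


class TestFitLogisticRate:
    def test_calibrated_rate_round_trips(self):
        r = fit_logistic_rate(0.40, 0.95, 30.0)
        assert r == pytest.approx(0.11166, abs=5e-5)
        assert logistic_fraction(30.0, LogisticParams(p0=0.40, r=r)) == pytest.approx(0.95, abs=1e-12)

    def test_rate_vanishes_at_degenerate_target(self):
        assert fit_logistic_rate(0.40, 0.400001, 30.0) < 1e-5

    def test_doubling_horizon_halves_rate(self):
        assert fit_logistic_rate(0.4, 0.95, 60.0) == pytest.approx(
            fit_logistic_rate(0.4, 0.95, 30.0) / 2, rel=1e-12
        )

    def test_target_below_start_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic_rate(0.5, 0.4, 30.0)

    def test_parameter_recovery_from_noisy_series(self):
        """Refit from 31 noisy annual points (sigma = 1 %-point) recovers
        r within 10% and p0 within 0.05 for every one of 100 seeds."""
        p = LogisticParams()
        t = np.arange(31.0)
        truth = 100 * np.asarray(logistic_fraction(t, p))
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fit = fit_logistic_series(t, truth + rng.normal(0, 1.0, t.size))
            assert abs(fit.r - p.r) / p.r < 0.10
            assert abs(fit.p0 - p.p0) < 0.05


def _small_grid():
    # 3x3 cells at 0.25 deg around 45 N
    return GridSpec(lon_min=20.0, lon_max=20.75, lat_min=44.5, lat_max=45.25, resolution=0.25)


class TestSimulateSpread:
    def test_zero_radius_state_constant(self):
        g = _small_grid()
        seed = np.zeros(g.shape, bool)
        seed[1, 1] = True
        states = simulate_spread(
            seed, np.ones(g.shape, bool), g, range(2024, 2030),
            params=None, dispersal=DispersalConfig(annual_radius_km=0.0),
        )
        for st in states:
            assert np.array_equal(st.infested, seed)

    def test_single_seed_fills_3x3_in_one_step(self):
        """All 8 neighbours lie within 60 km of the centre at 45 N."""
        g = _small_grid()
        lons, lats = g.lons(), g.lats()
        d = [haversine_km(lons[1], lats[1], lons[j], lats[i]) for i in range(3) for j in range(3)]
        assert max(d) < 60.0  # brute-force haversine precondition
        seed = np.zeros(g.shape, bool)
        seed[1, 1] = True
        states = simulate_spread(
            seed, np.ones(g.shape, bool), g, [2024, 2025],
            params=None, dispersal=DispersalConfig(annual_radius_km=60.0),
        )
        assert states[-1].infested.all()

    def test_unsuitable_seed_rejected(self):
        g = _small_grid()
        seed = np.zeros(g.shape, bool)
        seed[0, 0] = True
        with pytest.raises(ValueError, match="suitable"):
            simulate_spread(seed, ~seed, g, [2024, 2025])

    def test_isolated_seed_logs_shortfall(self, caplog):
        g = GridSpec(lon_min=0, lon_max=10, lat_min=40, lat_max=41, resolution=1.0)
        suitable = np.ones(g.shape, bool)
        suitable[0, 1:5] = False  # moat: nothing within 50 km of the seed
        seed = np.zeros(g.shape, bool)
        seed[0, 0] = True
        with caplog.at_level("WARNING"):
            states = simulate_spread(seed, suitable, g, [2024, 2025], params=None)
        assert states[-1].n_infested == 1
        assert any("shortfall" in r.message for r in caplog.records)

    def test_containment_and_monotone_growth(self):
        g = GridSpec(lon_min=18, lon_max=24, lat_min=42, lat_max=47, resolution=0.5)
        rng = np.random.default_rng(1)
        suitable = rng.random(g.shape) < 0.8
        suitable[5, 5] = True
        seed = np.zeros(g.shape, bool)
        seed[5, 5] = True
        states = simulate_spread(
            seed, suitable, g, range(2024, 2040),
            params=LogisticParams(p0=0.05, r=0.2),
            dispersal=DispersalConfig(annual_radius_km=80.0),
        )
        for prev, cur in zip(states, states[1:]):
            assert (prev.infested <= cur.infested).all()  # never revoked
            assert not (cur.infested & ~suitable).any()  # contained
            grown = cur.year_first != prev.year_first
            assert (cur.year_first[grown] == cur.horizon).all()

    def test_deterministic_across_runs(self):
        g = GridSpec(lon_min=18, lon_max=24, lat_min=42, lat_max=47, resolution=0.5)
        seed = np.zeros(g.shape, bool)
        seed[3, 3] = True
        kw = dict(params=LogisticParams(p0=0.02, r=0.25), dispersal=DispersalConfig(annual_radius_km=100.0))
        a = simulate_spread(seed, np.ones(g.shape, bool), g, range(2024, 2035), **kw)
        b = simulate_spread(seed, np.ones(g.shape, bool), g, range(2024, 2035), **kw)
        for x, y in zip(a, b):
            assert np.array_equal(x.year_first, y.year_first)


class TestAffectedCategories:
    def _state(self):
        yf = np.array([[2054, 2044, 2030, 0]])
        return InfestationState(yf, horizon=2054)

    def test_age_bands(self):
        cats = affected_categories(self._state())
        assert cats.tolist() == [[
            CATEGORY_CODES["newly"],      # infested at the horizon year
            CATEGORY_CODES["recently"],   # 10 years before the horizon
            CATEGORY_CODES["longer"],     # 24 years before
            CATEGORY_CODES["unaffected"],
        ]]

    def test_partition_exhaustive(self):
        rng = np.random.default_rng(0)
        yf = rng.integers(0, 2055, size=(20, 20))
        yf[yf < 2024] = 0
        cats = affected_categories(InfestationState(yf, 2054))
        assert set(np.unique(cats)) <= set(CATEGORY_CODES.values())
        assert ((cats == 0) == (yf == 0)).all()

    def test_future_years_rejected(self):
        with pytest.raises(ValueError):
            affected_categories(InfestationState(np.array([[2060]]), 2054))


class TestSpreadSeries:
    def test_full_infestation_is_100(self):
        g = _small_grid()
        suitable = np.ones(g.shape, bool)
        st = InfestationState(np.full(g.shape, 2024), 2024)
        df = spread_series([st], suitable)
        assert df["spread_pct"].iloc[0] == 100.0

    def test_seed_only_fraction(self):
        yf = np.zeros((10, 20), int)
        yf[0, 0] = 2024
        df = spread_series([InfestationState(yf, 2024)], np.ones((10, 20), bool))
        assert df["spread_pct"].iloc[0] == pytest.approx(0.5)

    def test_no_suitable_cells_rejected(self):
        with pytest.raises(ValueError):
            spread_series([InfestationState(np.zeros((2, 2), int), 2024)], np.zeros((2, 2), bool))

    def test_tracks_logistic_within_quantization(self):
        """On an unconstrained fully suitable grid the realized series equals
        the closed form to within half a cell of the suitable count."""
        g = GridSpec(lon_min=0, lon_max=20, lat_min=40, lat_max=50, resolution=0.5)
        suitable = np.ones(g.shape, bool)
        n = suitable.sum()
        p = LogisticParams()
        seed_n = round(p.p0 * n)
        seed = np.zeros(g.shape, bool)
        seed.ravel()[:seed_n] = True
        states = simulate_spread(
            seed, suitable, g, range(2024, 2055), params=p,
            dispersal=DispersalConfig(annual_radius_km=3000.0),
        )
        df = spread_series(states, suitable)
        for _, row in df.iterrows():
            exact = 100 * logistic_fraction(row["year"] - 2024, p)
            assert abs(row["spread_pct"] - exact) <= 100 * 0.5 / n + 1e-9
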