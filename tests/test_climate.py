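import numpy as np
import pytest

from alpinecast.climate import (ClimateGrid, GcmScenario, apply_gcm_delta,
                                compute_bioclim, interpolate_anomaly,
                                min_temp_coldest_month, simulate_snowpack,
                                summer_precipitation, synthesize_daily_weather,
                                warmth_index)
from alpinecast.config import DailySynthesisConfig, SnowModelParams
from alpinecast.geometry import GridGeometry


def brute_force_wi(temps):
    return sum(max(0.0, t - 5.0) for t in temps)


class TestMonthlyIndices:
    def test_warmth_index_boundary_and_linear_cases(self):
        assert warmth_index([5.0] * 12) == 0.0
        assert warmth_index([10.0] * 12) == 60.0
        temps = [-10, -8, -4, 0, 4, 6, 10, 12, 8, 3, -2, -7]
        assert warmth_index(temps) == pytest.approx(16.0)

    def test_indices_match_brute_force_on_random_months(self, rng):
        for _ in range(200):
            t = rng.uniform(-25, 30, 12)
            assert warmth_index(t) == pytest.approx(brute_force_wi(t))
            assert min_temp_coldest_month(t) == pytest.approx(min(t))
            p = rng.uniform(0, 400, 12)
            assert summer_precipitation(p) == pytest.approx(sum(p[4:9]))

    def test_coldest_month_extremes(self):
        assert min_temp_coldest_month([-3.0] * 12) == -3.0
        t = [-5.0] * 12
        t[3] = -20.0
        assert min_temp_coldest_month(t) == -20.0

    def test_summer_precipitation_constant(self):
        assert summer_precipitation([100.0] * 12) == 500.0
        assert summer_precipitation([0.0] * 12) == 0.0

    @pytest.mark.parametrize("func", [warmth_index, min_temp_coldest_month,
                                      summer_precipitation])
    def test_wrong_month_count_rejected(self, func):
        with pytest.raises(ValueError):
            func([1.0] * 11)


class TestSnowpack:
    params = SnowModelParams(rain_snow_threshold_c=2.0, degree_day_factor=4.0,
                             melt_base_temp_c=0.0)

    def test_warm_days_leave_no_pack(self):
        swe, msw = simulate_snowpack([10.0] * 40, [5.0] * 40, self.params)
        assert msw == 0.0
        assert np.all(swe == 0.0)

    def test_pure_accumulation(self):
        swe, msw = simulate_snowpack([-5.0] * 30, [10.0] * 30, self.params)
        assert msw == 300.0
        np.testing.assert_allclose(swe, 10.0 * np.arange(1, 31))

    def test_hand_stepped_melt_trajectory(self):
        temp = [-5.0] * 10 + [4.0] * 5
        precip = [10.0] * 10 + [0.0] * 5
        swe, msw = simulate_snowpack(temp, precip, self.params)
        expected = list(10.0 * np.arange(1, 11)) + [84.0, 68.0, 52.0, 36.0, 20.0]
        np.testing.assert_allclose(swe, expected)
        assert msw == 100.0

    def test_matches_independent_scalar_simulation(self, rng):
        """Vectorized model agrees exactly with a straightforward day loop."""
        for _ in range(50):
            n = int(rng.integers(30, 365))
            temp = rng.uniform(-15, 15, n)
            precip = rng.uniform(0, 20, n) * (rng.random(n) < 0.5)
            swe, msw = simulate_snowpack(temp, precip, self.params)
            pack, ref = 0.0, []
            for t, p in zip(temp, precip):
                if t < self.params.rain_snow_threshold_c:
                    pack += p
                pack -= min(self.params.degree_day_factor
                            * max(0.0, t - self.params.melt_base_temp_c), pack)
                ref.append(pack)
            np.testing.assert_allclose(swe, ref, rtol=0, atol=1e-9)
            assert msw == pytest.approx(max(ref))

    def test_mass_balance_exact(self, rng):
        """Cumulative snowfall minus cumulative melt equals final SWE."""
        for _ in range(50):
            temp = rng.uniform(-15, 15, 120)
            precip = rng.uniform(0, 20, 120)
            swe, _ = simulate_snowpack(temp, precip, self.params)
            snowfall = precip[temp < self.params.rain_snow_threshold_c].sum()
            melt = np.maximum(
                np.concatenate([[0.0], swe[:-1]])
                + np.where(temp < 2.0, precip, 0.0) - swe, 0.0).sum()
            assert snowfall - melt == pytest.approx(swe[-1], abs=1e-8)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_snowpack([1.0, 2.0], [1.0], self.params)
        with pytest.raises(ValueError):
            simulate_snowpack([1.0], [-1.0], self.params)


def _uniform_climate(nrows=2, ncols=3, tmean=None, tmin=None, precip=None):
    geom = GridGeometry(nrows, ncols, 1000.0)
    tm = np.tile(np.asarray(tmean if tmean is not None
                            else [2, 3, 7, 13, 18, 21, 25, 26, 22, 16, 10, 5],
                            dtype=float)[:, None, None], (1, nrows, ncols))
    tn = (np.tile(np.asarray(tmin, dtype=float)[:, None, None], (1, nrows, ncols))
          if tmin is not None else tm - 6.0)
    pr = np.tile(np.asarray(precip if precip is not None else [100.0] * 12,
                            dtype=float)[:, None, None], (1, nrows, ncols))
    return ClimateGrid(tm, tn, pr, geom)


class TestDailySynthesis:
    def test_trig_interpolation_hits_month_midpoints(self):
        monthly = np.array([2, 3, 7, 13, 18, 21, 25, 26, 22, 16, 10, 5.0])
        cfg = DailySynthesisConfig(temp_noise_sd_c=0.0, seed=3)
        t, _ = synthesize_daily_weather(monthly, np.full(12, 100.0), cfg)
        # mid-January (day index: Sep..Dec = 30+31+30+31 = 122; Jan 15th ~ 137)
        assert t[137] == pytest.approx(2.0, abs=0.5)
        assert t.min() > -5 and t.max() < 30

    def test_monthly_precip_totals_conserved(self):
        cfg = DailySynthesisConfig(seed=5)
        monthly = np.arange(1.0, 13.0) * 10
        _, p = synthesize_daily_weather(np.zeros(12), monthly, cfg)
        assert p.sum() == pytest.approx(monthly.sum())

    def test_deterministic_given_seed(self):
        cfg = DailySynthesisConfig(seed=11)
        a = synthesize_daily_weather(np.zeros(12), np.full(12, 50.0), cfg)
        b = synthesize_daily_weather(np.zeros(12), np.full(12, 50.0), cfg)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestDownscaling:
    def _scenario(self, d_mean, d_min=None, ratio=1.0, lattice=(2, 2)):
        nr, nc = lattice
        geom = GridGeometry(nr, nc, max(3000.0 / nc, 2000.0 / nr))
        return GcmScenario("s", np.full((nr, nc), d_mean, dtype=float),
                           None if d_min is None else np.full((nr, nc), d_min),
                           np.full((nr, nc), ratio, dtype=float), geom)

    def test_identity_scenario_is_bitwise_identity(self):
        base = _uniform_climate()
        fut = apply_gcm_delta(base, self._scenario(0.0, ratio=1.0))
        np.testing.assert_array_equal(fut.monthly_mean_temp, base.monthly_mean_temp)
        np.testing.assert_array_equal(fut.monthly_min_temp, base.monthly_min_temp)
        np.testing.assert_array_equal(fut.monthly_precip, base.monthly_precip)

    def test_uniform_delta_shifts_all_months_exactly(self):
        base = _uniform_climate()
        fut = apply_gcm_delta(base, self._scenario(3.0))
        np.testing.assert_allclose(
            fut.monthly_mean_temp - base.monthly_mean_temp, 3.0, atol=0)

    def test_bilinear_midpoint_is_corner_mean(self, rng):
        deltas = rng.normal(size=(2, 2))
        geom = GridGeometry(2, 2, 1000.0)
        scen = GcmScenario("s", deltas, deltas, np.ones((2, 2)), geom)
        # one target cell whose center coincides with the coarse lattice midpoint
        target = GridGeometry(1, 1, 2000.0)
        d_mean, _, _ = interpolate_anomaly(scen, target)
        assert d_mean[0, 0] == pytest.approx(deltas.mean())

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            self._scenario(0.0, ratio=-0.5)


class TestComputeBioclim:
    snow = SnowModelParams()
    daily = DailySynthesisConfig(seed=2)

    def test_uniformly_warm_climate_has_zero_msw(self):
        base = _uniform_climate(tmean=[15.0] * 12)
        bio = compute_bioclim(base, self.snow, self.daily)
        assert np.all(bio.msw == 0.0)

    def test_wi_shift_under_uniform_warming(self):
        base = _uniform_climate(tmean=[10.0] * 12)
        warm = _uniform_climate(tmean=[11.0] * 12)
        b0 = compute_bioclim(base, self.snow, self.daily)
        b1 = compute_bioclim(warm, self.snow, self.daily)
        np.testing.assert_allclose(b1.wi - b0.wi, 12.0)

    def test_grid_matches_per_cell_scalar_oracle(self, rng):
        geom = GridGeometry(2, 2, 1000.0)
        tm = rng.uniform(-10, 25, (12, 2, 2))
        tn = tm - rng.uniform(0, 8, (12, 2, 2))
        pr = rng.uniform(0, 300, (12, 2, 2))
        bio = compute_bioclim(ClimateGrid(tm, tn, pr, geom), self.snow, self.daily)
        for r in range(2):
            for c in range(2):
                assert bio.wi[r, c] == pytest.approx(brute_force_wi(tm[:, r, c]))
                assert bio.tmc[r, c] == pytest.approx(tn[:, r, c].min())
                assert bio.prs[r, c] == pytest.approx(pr[4:9, r, c].sum())

    def test_warming_monotonicity(self):
        """Uniform warming never decreases WI or TMC and never increases MSW."""
        base = _uniform_climate(nrows=2, ncols=2,
                                tmean=[-8, -7, -3, 2, 8, 12, 16, 17, 12, 6, 0, -5],
                                precip=[150.0] * 12)
        b0 = compute_bioclim(base, self.snow, self.daily)
        geom2 = GridGeometry(1, 1, 3000.0)
        for delta in (1.0, 3.0, 6.0):
            scen = GcmScenario("w", np.full((1, 1), delta), None,
                               np.ones((1, 1)), geom2)
            b1 = compute_bioclim(apply_gcm_delta(base, scen), self.snow, self.daily)
            assert np.all(b1.wi >= b0.wi)
            assert np.all(b1.tmc >= b0.tmc)
            assert np.all(b1.msw <= b0.msw)

    def test_identity_scenario_reproduces_bioclim_bitwise(self):
        base = _uniform_climate()
        geom2 = GridGeometry(1, 1, 3000.0)
        scen = GcmScenario("id", np.zeros((1, 1)), None, np.ones((1, 1)), geom2)
        b0 = compute_bioclim(base, self.snow, self.daily)
        b1 = compute_bioclim(apply_gcm_delta(base, scen), self.snow, self.daily)
        for a, b in zip(b0.stack(), b1.stack()):
            np.testing.assert_array_equal(a, b)
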