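"""Generator behaviour: seasonality, policy coding, trajectories, ARMA noise."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import itsim
from itsim import (ConfigError, Scenario, SimulationConfig, expected_trajectory,
                   policy_covariate, scenario_config, seasonal_pattern,
                   simulate_series, true_deaths_prevented)


class TestSeasonalPattern:
    def test_null_offsets_give_zero(self):
        config = scenario_config(1, 5.0, 9, seasonal_offsets=np.zeros(12))
        assert all(seasonal_pattern(m, config) == 0.0 for m in range(1, 13))

    def test_default_cosine_closed_form(self):
        config = scenario_config(1, 5.0, 9, seasonal_amplitude=7.0)
        months = np.arange(1, 13)
        expected = 7.0 * np.cos(2 * np.pi * (months - 1) / 12)
        np.testing.assert_allclose(seasonal_pattern(months, config), expected, atol=1e-12)
        assert seasonal_pattern(1, config) == pytest.approx(7.0)
        assert seasonal_pattern(7, config) == pytest.approx(-7.0)

    def test_offsets_are_centred_and_periodic(self):
        rng = np.random.default_rng(3)
        config = scenario_config(1, 5.0, 9, seasonal_offsets=rng.normal(5, 3, 12))
        values = seasonal_pattern(np.arange(1, 13), config)
        assert abs(values.mean()) < 1e-12
        # the pattern enters the trajectory with period 12
        mu, _ = expected_trajectory(config.replace(effect_size=0.0,
                                                   level_component=0.0,
                                                   slope_component=0.0))
        detrended = mu - (config.intercept + config.trend_slope * np.arange(1, 217))
        np.testing.assert_allclose(detrended[:12], detrended[12:24], atol=1e-10)

    def test_month_out_of_range_rejected(self):
        config = scenario_config(1, 5.0, 9)
        with pytest.raises(ConfigError):
            seasonal_pattern(0, config)
        with pytest.raises(ConfigError):
            seasonal_pattern(13, config)


class TestPolicyCovariate:
    @pytest.mark.parametrize("t,T,lag,expected", [
        (48, 49, 0, 0.0),     # any month before T is unexposed
        (48, 49, 24, 0.0),
        (61, 49, 24, 0.5),    # halfway through the 24-month ramp
        (49, 49, 0, 1.0),     # abrupt effect: exposed from T itself
        (49, 49, 24, 0.0),    # ramp starts at zero at T
        (73, 49, 24, 1.0),    # fully exposed at T + lag
        (200, 49, 24, 1.0),
    ])
    def test_step_and_ramp_values(self, t, T, lag, expected):
        assert policy_covariate(t, T, lag) == pytest.approx(expected)

    def test_negative_lag_rejected(self):
        with pytest.raises(ConfigError):
            policy_covariate(10, 5, -1)

    @given(T=st.integers(2, 200), lag=st.integers(0, 48))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, T, lag):
        t = np.arange(1, 241)
        values = policy_covariate(t, T, lag)
        assert np.all(values >= 0.0) and np.all(values <= 1.0)
        assert np.all(np.diff(values) >= -1e-15)


class TestExpectedTrajectory:
    def test_zero_effect_trajectories_coincide(self):
        config = scenario_config(1, 0.0, 9, level_component=0.0, slope_component=0.0)
        mu, cf = expected_trajectory(config)
        np.testing.assert_array_equal(mu, cf)

    def test_level_only_difference_is_level(self):
        config = scenario_config(1, 5.0, 5)
        mu, cf = expected_trajectory(config)
        T = config.intervention_month
        diff = cf - mu
        assert np.all(diff[: T - 1] == 0.0)
        np.testing.assert_allclose(diff[T:], 5.0)

    def test_lagged_ramp_midpoint(self):
        config = SimulationConfig(scenario=Scenario.LAGGED, effect_size=5.0,
                                  intervention_year=5, level_component=5.0,
                                  slope_component=0.0)
        mu, cf = expected_trajectory(config)
        T = config.intervention_month
        assert (cf - mu)[T + 12 - 1] == pytest.approx(2.5)


class TestSimulateSeries:
    def test_noiseless_series_equals_trajectory(self, noiseless_configs):
        for config in noiseless_configs.values():
            series = simulate_series(config)
            np.testing.assert_array_equal(series.rate, series.mu)

    def test_seed_reproducibility(self):
        config = scenario_config(2, 10.0, 9, seed=11)
        a = simulate_series(config)
        b = simulate_series(config)
        np.testing.assert_array_equal(a.rate, b.rate)
        c = simulate_series(config.replace(seed=12))
        assert not np.array_equal(a.rate, c.rate)

    def test_arma_lag1_autocorrelation_matches_closed_form(self):
        a, m = 0.3, 0.2
        config = scenario_config(1, 0.0, 9, level_component=0.0, slope_component=0.0,
                                 n_months=10_000, trend_slope=0.0,
                                 seasonal_amplitude=0.0, ar_coef=a, ma_coef=m,
                                 sigma=1.0, seed=5)
        series = simulate_series(config)
        u = series.rate - series.mu
        rho1 = np.corrcoef(u[:-1], u[1:])[0, 1]
        expected = (1 + a * m) * (a + m) / (1 + m * m + 2 * a * m)
        assert rho1 == pytest.approx(expected, abs=0.03)

    def test_stationary_variance_matches_closed_form(self):
        a, m, sigma = 0.3, 0.2, 2.0
        config = scenario_config(1, 0.0, 9, level_component=0.0, slope_component=0.0,
                                 n_months=100_000, trend_slope=0.0,
                                 seasonal_amplitude=0.0, ar_coef=a, ma_coef=m,
                                 sigma=sigma, seed=17)
        series = simulate_series(config)
        u = series.rate - series.mu
        expected = sigma ** 2 * (1 + m * m + 2 * a * m) / (1 - a * a)
        assert np.var(u) == pytest.approx(expected, rel=0.05)

    def test_noise_is_unbiased_at_fixed_month(self):
        config = scenario_config(1, 10.0, 9, seed=0)
        t_idx = 100
        devs = np.array([
            simulate_series(config.replace(seed=s)).rate[t_idx]
            - simulate_series(config.replace(seed=s)).mu[t_idx]
            for s in range(300)
        ])
        stationary_sd = config.sigma * np.sqrt(
            (1 + config.ma_coef ** 2 + 2 * config.ar_coef * config.ma_coef)
            / (1 - config.ar_coef ** 2))
        assert abs(devs.mean()) < 4 * stationary_sd / np.sqrt(devs.size)


class TestTrueDeathsPrevented:
    def test_zero_effect_gives_zero(self):
        config = scenario_config(1, 0.0, 9, level_component=0.0, slope_component=0.0)
        assert true_deaths_prevented(config) == 0.0

    def test_lagged_level_only_hand_computation(self):
        # sum of ramp values h/24 over h=1..12, times level 5: 5*78/24
        config = SimulationConfig(scenario=Scenario.LAGGED, effect_size=5.0,
                                  intervention_year=5, level_component=5.0,
                                  slope_component=0.0)
        assert true_deaths_prevented(config) == pytest.approx(16.25)

    def test_linearity_in_effect_components(self):
        base = scenario_config(2, 10.0, 9)
        doubled = base.replace(effect_size=20.0,
                               level_component=2 * base.level_component,
                               slope_component=2 * base.slope_component)
        assert true_deaths_prevented(doubled) == pytest.approx(
            2 * true_deaths_prevented(base))

    def test_population_scaling(self):
        config = scenario_config(1, 5.0, 9, population=50_000.0)
        assert true_deaths_prevented(config) == pytest.approx(30.0)

    def test_horizon_beyond_series_rejected(self):
        config = scenario_config(1, 5.0, 9, n_months=100)
        with pytest.raises(ConfigError):
            true_deaths_prevented(config, horizon_months=12)


class TestConfigValidation:
    def test_component_sum_enforced_for_abrupt_scenarios(self):
        with pytest.raises(ConfigError, match="sum"):
            SimulationConfig(scenario=Scenario.LEVEL_ONLY, effect_size=7.0,
                             intervention_year=9, level_component=4.0,
                             slope_component=2.0)

    def test_nonstationary_ar_rejected(self):
        with pytest.raises(ConfigError, match="AR"):
            scenario_config(1, 5.0, 9, ar_coef=1.0)

    def test_lag_only_for_lagged_scenario(self):
        with pytest.raises(ConfigError, match="lag"):
            SimulationConfig(scenario=Scenario.LEVEL_ONLY, effect_size=5.0,
                             intervention_year=9, lag_months=24)

    def test_intervention_inside_series(self):
        with pytest.raises(ConfigError, match="intervention"):
            scenario_config(1, 5.0, 13, n_months=120)
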