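"""Effect quantification: estimated and predicted approaches."""

import numpy as np
import pytest

import itsim
from itsim import (EstimationError, ModelSpec, PreInterventionForecaster,
                   estimated_effect, fit_its, fit_pre_intervention,
                   forecast_counterfactual, predicted_effect, scenario_config,
                   simulate_series, true_deaths_prevented)


@pytest.fixture(scope="module")
def noiseless_fits(noiseless_configs):
    out = {}
    for s, config in noiseless_configs.items():
        series = simulate_series(config)
        out[s] = (config, series, fit_its(series, ModelSpec.for_model(s)))
    return out


class TestEstimatedEffect:
    def test_level_only_beta_times_twelve(self, noiseless_fits):
        """A level coefficient of -5 converts to 60 deaths over 12 months."""
        config, series, _ = noiseless_fits[1]
        series5 = simulate_series(scenario_config(
            1, 5.0, 5, sigma=0.0, ar_coef=0.0, ma_coef=0.0))
        fit = fit_its(series5, ModelSpec.for_model(1))
        eff = estimated_effect(fit, series5)
        assert fit.coefficients["level"] == pytest.approx(-5.0, abs=1e-8)
        assert eff.deaths_prevented == pytest.approx(60.0, abs=1e-6)

    def test_zero_effect_centred_interval(self):
        config = scenario_config(1, 0.0, 9, level_component=0.0, slope_component=0.0,
                                 sigma=0.0, ar_coef=0.0, ma_coef=0.0)
        series = simulate_series(config)
        eff = estimated_effect(fit_its(series, ModelSpec.for_model(1)), series)
        assert eff.deaths_prevented == pytest.approx(0.0, abs=1e-8)
        assert eff.ci_low == pytest.approx(-eff.ci_high, abs=1e-8)

    def test_noiseless_recovers_truth_every_matched_pair(self, noiseless_fits):
        for s, (config, series, fit) in noiseless_fits.items():
            eff = estimated_effect(fit, series)
            assert eff.deaths_prevented == pytest.approx(
                true_deaths_prevented(config), abs=1e-6)

    def test_population_averaging(self):
        config = scenario_config(1, 5.0, 5, sigma=0.0, ar_coef=0.0, ma_coef=0.0,
                                 population=np.full(216, 200_000.0))
        series = simulate_series(config)
        eff = estimated_effect(fit_its(series, ModelSpec.for_model(1)), series)
        assert eff.deaths_prevented == pytest.approx(120.0, abs=1e-6)

    def test_interval_contains_point(self, default_series):
        eff = estimated_effect(fit_its(default_series, ModelSpec.for_model(1)),
                               default_series)
        assert eff.ci_low <= eff.deaths_prevented <= eff.ci_high
        assert eff.variance > 0


class TestPreInterventionFit:
    def test_noiseless_forecasts_reproduce_trajectory(self, noiseless_fits):
        config, series, _ = noiseless_fits[1]
        prefit = fit_pre_intervention(series)
        months, mean, var, lo, hi = forecast_counterfactual(prefit)
        T = config.intervention_month
        np.testing.assert_allclose(mean, series.mu_counterfactual[T:T + 12], atol=1e-6)
        np.testing.assert_allclose(var, 0.0, atol=1e-8)
        np.testing.assert_allclose(lo, hi, atol=1e-7)

    def test_noiseless_slope_recovery(self, noiseless_fits):
        config, series, _ = noiseless_fits[1]
        prefit = fit_pre_intervention(series)
        idx = prefit.result.column_names.index("trend")
        assert prefit.result.beta[idx] == pytest.approx(config.trend_slope, abs=1e-6)

    def test_short_pre_period_rejected(self):
        series = simulate_series(scenario_config(1, 5.0, 2, seed=0))
        with pytest.raises(EstimationError, match="pre-intervention"):
            fit_pre_intervention(series)

    def test_aic_search_prefers_true_white_noise(self):
        """With i.i.d. innovations the AIC search picks (0,0) in a clear
        majority of replicates.  (AIC admits each one-parameter superset
        with roughly chi2_1 > 2 probability, ~16%, so the white-noise
        order wins on the order of 65-80% of the time, not always.)"""
        picked = []
        for seed in range(40):
            config = scenario_config(1, 10.0, 9, ar_coef=0.0, ma_coef=0.0, seed=seed)
            series = simulate_series(config)
            prefit = fit_pre_intervention(series, aic_search=True)
            picked.append(prefit.result.method.startswith("ols")
                          or (abs(prefit.result.ar) < 1e-8 and abs(prefit.result.ma) < 1e-8))
        assert np.mean(picked) >= 0.6


class TestPredictedEffect:
    def test_observed_equal_forecast_gives_zero(self, noiseless_fits):
        config, series, _ = noiseless_fits[1]
        prefit = fit_pre_intervention(series)
        forecasts = forecast_counterfactual(prefit)
        # remove the policy effect: observe exactly the counterfactual
        cf_series = simulate_series(config.replace(effect_size=0.0,
                                                   level_component=0.0,
                                                   slope_component=0.0))
        eff = predicted_effect(cf_series, forecasts)
        assert eff.deaths_prevented == pytest.approx(0.0, abs=1e-6)

    def test_noiseless_matches_truth_and_estimated(self, noiseless_fits):
        for s, (config, series, fit) in noiseless_fits.items():
            prefit = fit_pre_intervention(series)
            pred = predicted_effect(series, forecast_counterfactual(prefit))
            est = estimated_effect(fit, series)
            truth = true_deaths_prevented(config)
            assert pred.deaths_prevented == pytest.approx(truth, abs=1e-6)
            assert pred.deaths_prevented == pytest.approx(
                est.deaths_prevented, abs=1e-6)

    def test_uses_pre_period_only_for_forecasts(self, default_series):
        """Permuting post-intervention rates must not change the forecasts."""
        prefit = fit_pre_intervention(default_series)
        months, mean, var, *_ = forecast_counterfactual(prefit)
        rng = np.random.default_rng(0)
        T = default_series.intervention_month
        permuted = default_series.rate.copy()
        permuted[T:] = rng.permutation(permuted[T:])
        from itsim import MonthlySeries
        shuffled = MonthlySeries(
            t=default_series.t, rate=permuted, policy=default_series.policy,
            month_of_year=default_series.month_of_year,
            population=default_series.population,
            intervention_month=T, lag_months=default_series.lag_months)
        prefit2 = fit_pre_intervention(shuffled)
        months2, mean2, var2, *_ = forecast_counterfactual(prefit2)
        np.testing.assert_allclose(mean2, mean, atol=1e-10)
        np.testing.assert_allclose(var2, var, atol=1e-10)
        eff1 = predicted_effect(default_series, (months, mean, var))
        eff2 = predicted_effect(shuffled, (months2, mean2, var2))
        # only the observed differences moved the estimate
        delta_obs = np.sum((default_series.rate[T:T + 12] - permuted[T:T + 12])
                           * default_series.population[T:T + 12] / 1e5)
        assert eff2.deaths_prevented - eff1.deaths_prevented == pytest.approx(
            delta_obs, abs=1e-9)

    def test_missing_observed_months_rejected(self, default_series):
        prefit = fit_pre_intervention(default_series)
        forecasts = forecast_counterfactual(prefit)
        short = default_series.pre_intervention()
        with pytest.raises(EstimationError):
            predicted_effect(short, forecasts)


class TestForecasterEstimator:
    def test_fit_forecast_effect_pipeline(self, default_series):
        forecaster = PreInterventionForecaster().fit(default_series)
        eff = forecaster.effect()
        assert eff.approach == "predicted"
        assert eff.per_month_differences.shape == (12,)
        assert eff.ci_low <= eff.deaths_prevented <= eff.ci_high

    def test_params_roundtrip(self):
        f = PreInterventionForecaster(aic_search=True)
        clone = PreInterventionForecaster().set_params(**f.get_params())
        assert clone.get_params() == f.get_params()
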