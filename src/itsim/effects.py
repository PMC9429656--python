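"""Policy-effect quantification: deaths prevented over a 12-month horizon.

Two approaches are implemented:

* **estimated** — the classic segmented-regression reading: the fitted
  intervention coefficients, evaluated through the model's own policy
  coding over the 12 months following the intervention, are converted
  to deaths through the average post-intervention population.  The
  interval comes from the coefficient covariance (delta method).

* **predicted** — a forecast-counterfactual reading: a trend+season+ARMA
  model fitted to pre-intervention data only is used to forecast the 12
  post-intervention months; the summed observed-minus-forecast rate
  differences, scaled by the per-month population, estimate the deaths
  prevented.  Monthly forecast variances (which include regression-
  coefficient uncertainty) are summed under an independence convention.

Both intervals use the 1.96 normal quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arma import RegArmaResult, fit_reg_arma
from .config import EFFECT_HORIZON
from .dgp import policy_covariate
from .models import FittedITSModel, ModelSpec, seasonal_basis_matrix
from .series import MonthlySeries

Z95 = 1.96
MIN_PRE_MONTHS = 48


class EstimationError(RuntimeError):
    """Raised when an effect cannot be computed from the given inputs."""


@dataclass
class EffectEstimate:
    """Deaths prevented over the post-intervention horizon, with 95% CI."""

    approach: str  # "estimated" or "predicted"
    deaths_prevented: float
    ci_low: float
    ci_high: float
    variance: float
    horizon_months: int = EFFECT_HORIZON
    model_id: int | None = None
    scenario: str | None = None
    per_month_differences: np.ndarray | None = None
    #: estimated approach only: the fitted level-change coefficient and its SE
    level_coef: float | None = None
    level_coef_se: float | None = None

    def __post_init__(self):
        if not (self.ci_low - 1e-9 <= self.deaths_prevented <= self.ci_high + 1e-9):
            raise ValueError("confidence interval must contain the point estimate")

    def ci_contains(self, value: float, tol: float = 1e-6) -> bool:
        # the tolerance keeps zero-width (noiseless) intervals sensible
        return self.ci_low - tol <= value <= self.ci_high + tol


def _policy_weights(spec: ModelSpec, T: int, horizon: int) -> tuple[float, float]:
    """Sums of the model's own policy covariates over months T+1..T+horizon."""
    t = np.arange(T + 1, T + horizon + 1, dtype=float)
    w_level = float(np.sum(policy_covariate(t, T, spec.lag_months)))
    w_slope = float(np.sum(np.maximum(0.0, t - T - spec.lag_months)))
    return w_level, w_slope


def estimated_effect(fit: FittedITSModel, series: MonthlySeries,
                     horizon: int = EFFECT_HORIZON) -> EffectEstimate:
    """Deaths prevented read off the fitted intervention coefficients."""
    if not fit.converged:
        raise EstimationError(
            "refusing to compute an effect from a non-converged fit "
            f"(method={fit.result.method}, loglik={fit.result.loglik:.3f})"
        )
    T = series.intervention_month
    if T + horizon > len(series):
        raise EstimationError(f"series has fewer than {horizon} months after the intervention")
    w_level, w_slope = _policy_weights(fit.spec, T, horizon)
    idx = np.arange(T + 1, T + horizon + 1, dtype=int) - 1
    pop_scale = float(np.mean(series.population[idx])) / 100_000.0

    names = fit.result.column_names
    grad = np.zeros(len(names))
    grad[names.index("level")] = -w_level * pop_scale
    if fit.spec.include_slope_change:
        grad[names.index("slope_change")] = -w_slope * pop_scale
    deaths = float(grad @ fit.result.beta)
    variance = float(grad @ fit.result.cov_beta @ grad)
    half = Z95 * np.sqrt(variance)
    i_level = names.index("level")
    return EffectEstimate(
        approach="estimated", deaths_prevented=deaths,
        ci_low=deaths - half, ci_high=deaths + half, variance=variance,
        horizon_months=horizon, model_id=fit.spec.model_id,
        level_coef=float(fit.result.beta[i_level]),
        level_coef_se=float(fit.result.bse[i_level]),
    )


@dataclass
class PreInterventionFit:
    """Trend + season + ARMA model fitted to pre-intervention months only."""

    result: RegArmaResult
    spec: ModelSpec
    intervention_month: int
    last_month: float

    @property
    def converged(self) -> bool:
        return self.result.converged

    def design_rows(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        month = ((t.astype(int) - 1) % 12) + 1
        sb, _ = seasonal_basis_matrix(month, self.spec.seasonal_basis, self.spec.seasonal_df)
        cols = [np.ones(t.shape[0]), t]
        return np.column_stack(cols + ([sb] if sb.size else []))


def fit_pre_intervention(series: MonthlySeries, spec: ModelSpec | None = None,
                         min_pre_months: int = MIN_PRE_MONTHS,
                         aic_search: bool = False) -> PreInterventionFit:
    """Fit the counterfactual model to months strictly before the intervention.

    By default the error process is fixed at ARMA(1,1), matching the
    fitting family; with ``aic_search=True`` the four orders
    (p, q) in {0, 1}^2 are compared by AIC.
    """
    spec = spec or ModelSpec.for_model(1)
    pre = series.pre_intervention()
    if len(pre) < min_pre_months:
        raise EstimationError(
            f"need at least {min_pre_months} pre-intervention months, got {len(pre)}"
        )
    month = pre.month_of_year.astype(int)
    sb, snames = seasonal_basis_matrix(month, spec.seasonal_basis, spec.seasonal_df)
    X = np.column_stack([np.ones(len(pre)), pre.t] + ([sb] if sb.size else []))
    names = ["const", "trend"] + snames
    if aic_search:
        candidates = [
            fit_reg_arma(X, pre.rate, error_structure=spec.error_structure,
                         order=order, column_names=names)
            for order in ((0, 0), (1, 0), (0, 1), (1, 1))
        ]
        result = min(candidates, key=lambda r: r.aic)
    else:
        result = fit_reg_arma(X, pre.rate, error_structure=spec.error_structure,
                              column_names=names)
    return PreInterventionFit(result=result, spec=spec,
                              intervention_month=series.intervention_month,
                              last_month=float(pre.t[-1]))


def forecast_counterfactual(prefit: PreInterventionFit, horizon: int = EFFECT_HORIZON,
                            include_param_uncertainty: bool = True):
    """Forecast the counterfactual rates for months T+1 .. T+horizon.

    Returns ``(months, mean, variance, pi_low, pi_high)``.  Forecasting
    starts from the last pre-intervention month, so month T+h is an
    (h+1)-step-ahead forecast; the variance follows the ARMA state-space
    recursion and includes regression-coefficient uncertainty unless
    disabled.
    """
    if horizon <= 0:
        raise ValueError("forecast horizon must be positive")
    if not prefit.converged:
        raise EstimationError("refusing to forecast from a non-converged pre-intervention fit")
    T = prefit.intervention_month
    # steps 1..horizon+1 ahead cover months T .. T+horizon
    months = np.arange(prefit.last_month + 1, T + horizon + 1)
    X_future = prefit.design_rows(months)
    mean, var = prefit.result.forecast(X_future, include_param_uncertainty)
    keep = months > T
    months, mean, var = months[keep][:horizon], mean[keep][:horizon], var[keep][:horizon]
    sd = np.sqrt(var)
    return months, mean, var, mean - Z95 * sd, mean + Z95 * sd


def predicted_effect(series: MonthlySeries, forecasts, horizon: int = EFFECT_HORIZON,
                     model_id: int | None = None) -> EffectEstimate:
    """Deaths prevented as summed forecast-minus-observed differences."""
    months, mean, var = forecasts[0], forecasts[1], forecasts[2]
    T = series.intervention_month
    wanted = np.arange(T + 1, T + horizon + 1)
    if len(months) < horizon or not np.array_equal(np.asarray(months[:horizon], dtype=int), wanted):
        raise EstimationError("forecasts must cover months T+1..T+horizon")
    idx = wanted - 1
    if idx[-1] >= len(series):
        raise EstimationError("observed series is missing post-intervention months")
    observed = series.rate[idx]
    pop_scale = series.population[idx] / 100_000.0
    diffs = (np.asarray(mean[:horizon]) - observed) * pop_scale
    deaths = float(np.sum(diffs))
    variance = float(np.sum(np.asarray(var[:horizon]) * pop_scale ** 2))
    half = Z95 * np.sqrt(variance)
    return EffectEstimate(
        approach="predicted", deaths_prevented=deaths,
        ci_low=deaths - half, ci_high=deaths + half, variance=variance,
        horizon_months=horizon, model_id=model_id,
        per_month_differences=diffs,
    )


class PreInterventionForecaster:
    """Sklearn-style wrapper: fit on pre-intervention data, then forecast."""

    def __init__(self, seasonal_basis: str = "month_effects", seasonal_df: int = 11,
                 error_structure: str = "arma11", aic_search: bool = False,
                 min_pre_months: int = MIN_PRE_MONTHS):
        self.seasonal_basis = seasonal_basis
        self.seasonal_df = seasonal_df
        self.error_structure = error_structure
        self.aic_search = aic_search
        self.min_pre_months = min_pre_months

    def get_params(self, deep: bool = True) -> dict:
        return {
            "seasonal_basis": self.seasonal_basis,
            "seasonal_df": self.seasonal_df,
            "error_structure": self.error_structure,
            "aic_search": self.aic_search,
            "min_pre_months": self.min_pre_months,
        }

    def set_params(self, **params) -> "PreInterventionForecaster":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r} for PreInterventionForecaster")
            setattr(self, key, value)
        return self

    def fit(self, series: MonthlySeries) -> "PreInterventionForecaster":
        spec = ModelSpec.for_model(1, seasonal_basis=self.seasonal_basis,
                                   seasonal_df=self.seasonal_df,
                                   error_structure=self.error_structure)
        self.prefit_ = fit_pre_intervention(series, spec,
                                            min_pre_months=self.min_pre_months,
                                            aic_search=self.aic_search)
        self.series_ = series
        return self

    def forecast(self, horizon: int = EFFECT_HORIZON):
        if not hasattr(self, "prefit_"):
            raise RuntimeError("PreInterventionForecaster instance is not fitted yet")
        return forecast_counterfactual(self.prefit_, horizon)

    def effect(self, horizon: int = EFFECT_HORIZON) -> EffectEstimate:
        return predicted_effect(self.series_, self.forecast(horizon), horizon)
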