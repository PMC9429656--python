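"""Segmented-regression ITS models with seasonal adjustment and ARMA errors.

Three fitting models are supported, mirroring the classic segmented-
regression hierarchy:

* Model 1 — level change only:      rate ~ trend + level + season
* Model 2 — level and slope change: rate ~ trend + level + slope_change + season
* Model 3 — lagged effect: the level covariate is the 24-month linear
  ramp, and the slope-change covariate starts once the ramp completes.

The ``level`` covariate is always re-coded from the *fitting* model's lag
assumption and the series' intervention month — never copied from the
generating scenario — which is what makes model misspecification
analyses possible.

The seasonal term is a cyclic function of calendar month.  At monthly
resolution a 12-knot cyclic cubic spline is saturated (it can represent
any periodic function of the 12 months exactly), so the default basis is
the equivalent set of 11 sum-to-zero month-effect columns; a truncated
Fourier ("harmonic") basis is available for lower-variance fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arma import RegArmaResult, SingularDesignError, fit_reg_arma
from .dgp import policy_covariate
from .series import MonthlySeries

MIN_OBSERVATIONS = 24


class FitInfeasibleError(ValueError):
    """Raised when a series cannot support the requested fit."""


@dataclass(frozen=True)
class ModelSpec:
    """Structural specification of one fitting model."""

    model_id: int = 1
    include_slope_change: bool = False
    lag_months: int = 0
    seasonal_basis: str = "month_effects"  # or "harmonic"
    seasonal_df: int = 11
    error_structure: str = "arma11"  # or "iid"

    def __post_init__(self):
        if self.model_id not in (1, 2, 3):
            raise ValueError(f"model_id must be 1, 2 or 3, got {self.model_id}")
        expected = {1: (False, 0), 2: (True, 0), 3: (True, 24)}[self.model_id]
        if (self.include_slope_change, self.lag_months) != expected:
            raise ValueError(
                f"Model {self.model_id} requires (include_slope_change, lag_months)="
                f"{expected}, got {(self.include_slope_change, self.lag_months)}"
            )
        if self.seasonal_basis not in ("month_effects", "harmonic", "none"):
            raise ValueError(f"unknown seasonal_basis {self.seasonal_basis!r}")
        if self.error_structure not in ("arma11", "iid"):
            raise ValueError(f"unknown error_structure {self.error_structure!r}")

    @classmethod
    def for_model(cls, model_id: int, **overrides) -> "ModelSpec":
        base = {
            1: dict(model_id=1, include_slope_change=False, lag_months=0),
            2: dict(model_id=2, include_slope_change=True, lag_months=0),
            3: dict(model_id=3, include_slope_change=True, lag_months=24),
        }[model_id]
        base.update(overrides)
        return cls(**base)


def seasonal_basis_matrix(month_of_year: np.ndarray, basis: str, df: int) -> tuple[np.ndarray, list[str]]:
    """Centred periodic basis evaluated at calendar months 1..12."""
    m = np.asarray(month_of_year, dtype=int)
    if basis == "none":
        return np.empty((m.shape[0], 0)), []
    if basis == "month_effects":
        dummies = np.zeros((m.shape[0], 12))
        dummies[np.arange(m.shape[0]), m - 1] = 1.0
        cols = dummies[:, :11] - dummies[:, [11]]
        names = [f"month_{i + 1}" for i in range(11)]
        return cols, names
    if basis == "harmonic":
        n_harm = max(1, df // 2)
        angle = 2 * np.pi * (m - 1) / 12.0
        cols, names = [], []
        for j in range(1, n_harm + 1):
            cols.append(np.cos(j * angle))
            names.append(f"cos_{j}")
            if j < 6:
                cols.append(np.sin(j * angle))
                names.append(f"sin_{j}")
        return np.column_stack(cols), names
    raise ValueError(f"unknown seasonal basis {basis!r}")


def build_design(series: MonthlySeries, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix and response for one ITS fit.

    Columns: intercept, trend (t), level (the spec's own policy coding),
    slope_change (months since the policy reached full effect) when the
    spec includes it, and the centred seasonal basis.
    """
    n = len(series)
    if n < MIN_OBSERVATIONS:
        raise FitInfeasibleError(f"need at least {MIN_OBSERVATIONS} observations, got {n}")
    T = series.intervention_month
    t = series.t
    level = policy_covariate(t, T, spec.lag_months)
    if np.all(level == 0):
        raise FitInfeasibleError("no post-intervention observations: level column is all zero")
    if np.all(level > 0):
        raise FitInfeasibleError("no pre-intervention observations")
    cols = [np.ones(n), t, level]
    names = ["const", "trend", "level"]
    if spec.include_slope_change:
        cols.append(np.maximum(0.0, t - T - spec.lag_months))
        names.append("slope_change")
    sb, snames = seasonal_basis_matrix(series.month_of_year, spec.seasonal_basis, spec.seasonal_df)
    X = np.column_stack(cols + ([sb] if sb.size else []))
    return X, series.rate.copy(), names + snames


@dataclass
class FittedITSModel:
    """A fitted segmented regression with ARMA(1,1)-correlated errors."""

    spec: ModelSpec
    result: RegArmaResult
    intervention_month: int
    n_obs: int

    @property
    def coefficients(self) -> dict:
        return dict(zip(self.result.column_names, self.result.beta))

    @property
    def standard_errors(self) -> dict:
        return dict(zip(self.result.column_names, self.result.bse))

    @property
    def covariance(self) -> np.ndarray:
        return self.result.cov_beta

    @property
    def ar_hat(self) -> float:
        return self.result.ar

    @property
    def ma_hat(self) -> float:
        return self.result.ma

    @property
    def sigma_hat(self) -> float:
        return self.result.sigma

    @property
    def aic(self) -> float:
        return self.result.aic

    @property
    def converged(self) -> bool:
        return self.result.converged

    @property
    def fitted_values(self) -> np.ndarray:
        return self.result.fitted_mean

    def coef_index(self, name: str) -> int:
        return self.result.column_names.index(name)


def fit_its(series: MonthlySeries, spec: ModelSpec) -> FittedITSModel:
    """Fit one ITS model to a monthly series (exact ML, deterministic)."""
    X, y, names = build_design(series, spec)
    result = fit_reg_arma(X, y, error_structure=spec.error_structure, column_names=names)
    return FittedITSModel(spec=spec, result=result,
                          intervention_month=series.intervention_month, n_obs=len(series))


class ITSRegression:
    """Scikit-learn-style estimator wrapping :func:`fit_its`.

    Parameters follow :class:`ModelSpec`; after ``fit`` the instance
    exposes ``coef_``, ``bse_``, ``cov_params_``, ``ar_``, ``ma_``,
    ``sigma_``, ``aic_``, ``converged_`` and ``fitted_values_``.
    """

    def __init__(self, model_id: int = 1, seasonal_basis: str = "month_effects",
                 seasonal_df: int = 11, error_structure: str = "arma11"):
        self.model_id = model_id
        self.seasonal_basis = seasonal_basis
        self.seasonal_df = seasonal_df
        self.error_structure = error_structure

    # minimal get/set_params so the class composes with sklearn utilities
    def get_params(self, deep: bool = True) -> dict:
        return {
            "model_id": self.model_id,
            "seasonal_basis": self.seasonal_basis,
            "seasonal_df": self.seasonal_df,
            "error_structure": self.error_structure,
        }

    def set_params(self, **params) -> "ITSRegression":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r} for ITSRegression")
            setattr(self, key, value)
        return self

    def _spec(self) -> ModelSpec:
        return ModelSpec.for_model(
            self.model_id,
            seasonal_basis=self.seasonal_basis,
            seasonal_df=self.seasonal_df,
            error_structure=self.error_structure,
        )

    def fit(self, series: MonthlySeries) -> "ITSRegression":
        fitted = fit_its(series, self._spec())
        self.model_ = fitted
        self.coef_ = fitted.result.beta
        self.coef_names_ = list(fitted.result.column_names)
        self.bse_ = fitted.result.bse
        self.cov_params_ = fitted.result.cov_beta
        self.ar_ = fitted.ar_hat
        self.ma_ = fitted.ma_hat
        self.sigma_ = fitted.sigma_hat
        self.aic_ = fitted.aic
        self.converged_ = fitted.converged
        self.fitted_values_ = fitted.fitted_values
        return self

    def predict(self, series: MonthlySeries) -> np.ndarray:
        """Mean-structure prediction for the months of ``series``."""
        if not hasattr(self, "model_"):
            raise RuntimeError("ITSRegression instance is not fitted yet")
        X, _, _ = build_design(series, self.model_.spec)
        return X @ self.coef_
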