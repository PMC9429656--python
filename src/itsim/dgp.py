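"""Data-generating process: trend + seasonality + policy effect + ARMA noise.

The observed rate is

    y_t = d_t + u_t,        u_t = a1 * u_{t-1} + eps_t + m1 * eps_{t-1},

with i.i.d. Gaussian innovations eps_t ~ N(0, sigma^2) and deterministic
component

    d_t = b0 + b1 * t + s(month_t)
          - level * policy(t)  -  slope * max(0, t - T - lag),

where ``policy`` is the step (or, for the lagged scenario, 24-month ramp)
covariate.  Both effect terms are reductions: positive components lower
the mortality rate.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .config import EFFECT_HORIZON, ConfigError, Scenario, SimulationConfig
from .series import MonthlySeries

BURN_IN_MONTHS = 24


def seasonal_pattern(month_of_year, config: SimulationConfig):
    """Centred periodic seasonal offset for calendar month(s) 1..12.

    The default is a single-harmonic cosine, A*cos(2*pi*(m-1)/12), which
    peaks in January and troughs in July — the classic Northern-hemisphere
    winter excess.  A user-supplied 12-vector of monthly offsets (centred
    internally) can replace it.
    """
    m = np.asarray(month_of_year)
    if np.any((m < 1) | (m > 12)) or np.any(m != np.floor(m)):
        raise ConfigError("month_of_year must be an integer in 1..12")
    idx = m.astype(int) - 1
    if config.seasonal_offsets is not None:
        offsets = config.seasonal_offsets - config.seasonal_offsets.mean()
        out = offsets[idx]
    else:
        out = config.seasonal_amplitude * np.cos(2 * np.pi * idx / 12.0)
    return out if out.shape else float(out)


def policy_covariate(t, T: int, lag_months: int):
    """Policy exposure in [0, 1]: 0 before T, linear ramp over the lag, then 1.

    For ``lag_months == 0`` the covariate is the abrupt permanent step
    (1 from month T onward).  With a positive lag the exposure at month t
    is (t - T)/lag, so it is 0 at T itself and reaches 1 at T + lag.
    """
    if lag_months < 0:
        raise ConfigError(f"lag_months={lag_months}: must be non-negative")
    if T < 1:
        raise ConfigError(f"intervention month T={T}: must be >= 1")
    t_arr = np.asarray(t, dtype=float)
    if lag_months == 0:
        out = (t_arr >= T).astype(float)
    else:
        out = np.clip((t_arr - T) / lag_months, 0.0, 1.0)
    return out if out.shape else float(out)


def effect_reduction(config: SimulationConfig, t=None) -> np.ndarray:
    """Reduction in the expected rate attributable to the policy at month t."""
    if t is None:
        t = np.arange(1, config.n_months + 1)
    t = np.asarray(t, dtype=float)
    T = config.intervention_month
    exposure = policy_covariate(t, T, config.lag_months)
    slope_time = np.maximum(0.0, t - T - config.lag_months)
    return config.level_component * exposure + config.slope_component * slope_time


def expected_trajectory(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic expected rate and its no-intervention counterfactual."""
    t = np.arange(1, config.n_months + 1)
    month = (t - 1) % 12 + 1
    baseline = (config.intercept + config.trend_slope * t
                + seasonal_pattern(month, config))
    return baseline - effect_reduction(config, t), baseline


def simulate_series(config: SimulationConfig, rng: np.random.Generator | None = None) -> MonthlySeries:
    """Draw one monthly rate series from the generating process.

    The ARMA(1,1) disturbance is initialised at zero and run through a
    24-month burn-in that is discarded, so the retained disturbance is
    approximately stationary from month 1.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_months
    mu, cf = expected_trajectory(config)
    total = n + BURN_IN_MONTHS
    eps = rng.normal(0.0, config.sigma, size=total)
    # u_t - a*u_{t-1} = eps_t + m*eps_{t-1}  (zero initial conditions)
    u = signal.lfilter([1.0, config.ma_coef], [1.0, -config.ar_coef], eps)
    u = u[BURN_IN_MONTHS:]
    t = np.arange(1, n + 1)
    return MonthlySeries(
        t=t,
        rate=mu + u,
        policy=policy_covariate(t, config.intervention_month, config.lag_months),
        month_of_year=(t - 1) % 12 + 1,
        population=config.population_vector(),
        intervention_month=config.intervention_month,
        lag_months=config.lag_months,
        mu=mu,
        mu_counterfactual=cf,
    )


def true_deaths_prevented(config: SimulationConfig, horizon_months: int = EFFECT_HORIZON) -> float:
    """Design-implied deaths prevented over the months T+1 .. T+horizon.

    The counterfactual-minus-intervention rate difference is converted to
    deaths through the per-month population (rate units are per 100,000).
    """
    T = config.intervention_month
    if T + horizon_months > config.n_months:
        raise ConfigError(
            f"horizon of {horizon_months} months extends beyond the "
            f"{config.n_months}-month series (T={T})"
        )
    t = np.arange(T + 1, T + horizon_months + 1)
    reduction = effect_reduction(config, t)
    pop = config.population_vector()[t.astype(int) - 1]
    return float(np.sum(reduction * pop / 100_000.0))
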