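"""Simulation configuration for monthly mortality-rate series.

A :class:`SimulationConfig` fully specifies one data-generating process:
a Gaussian monthly rate series (deaths per 100,000) with a linear secular
trend, a centred periodic seasonal pattern, ARMA(1,1) serial correlation,
and one of three policy-intervention scenarios:

* ``LEVEL_ONLY`` — an immediate, permanent drop in the rate at the
  intervention month.
* ``LEVEL_AND_SLOPE`` — an immediate drop plus a change in the monthly
  trend from the intervention month onward.
* ``LAGGED`` — the level change accrues linearly over a 24-month ramp,
  and the trend change takes hold only after the ramp completes.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field

import numpy as np

from . import calibration

DEFAULT_N_MONTHS = 216  # 18 years
DEFAULT_LAG_MONTHS = 24
EFFECT_HORIZON = 12  # months over which "deaths prevented" is accounted


class Scenario(enum.Enum):
    LEVEL_ONLY = "level_only"
    LEVEL_AND_SLOPE = "level_and_slope"
    LAGGED = "lagged"

    @classmethod
    def coerce(cls, value) -> "Scenario":
        if isinstance(value, cls):
            return value
        if isinstance(value, int):
            return {1: cls.LEVEL_ONLY, 2: cls.LEVEL_AND_SLOPE, 3: cls.LAGGED}[value]
        key = str(value).strip().lower()
        aliases = {
            "1": cls.LEVEL_ONLY, "scenario1": cls.LEVEL_ONLY,
            "2": cls.LEVEL_AND_SLOPE, "scenario2": cls.LEVEL_AND_SLOPE,
            "3": cls.LAGGED, "scenario3": cls.LAGGED,
        }
        if key in aliases:
            return aliases[key]
        return cls(key)

    @property
    def index(self) -> int:
        return {Scenario.LEVEL_ONLY: 1, Scenario.LEVEL_AND_SLOPE: 2, Scenario.LAGGED: 3}[self]


class ConfigError(ValueError):
    """Raised when a configuration violates a documented constraint."""


@dataclass
class SimulationConfig:
    """Parameters of one simulated monthly mortality-rate series.

    Rate-scale parameters are deaths per 100,000 population per month.
    The nuisance defaults (intercept, trend, seasonal amplitude, ARMA
    coefficients and innovation SD) are calibrated values representative
    of monthly male all-cause mortality in a Baltic-type population; see
    :mod:`itsim.calibration` for how they were fixed.
    """

    scenario: Scenario = Scenario.LEVEL_ONLY
    effect_size: float = 10.0
    intervention_year: int = 9
    n_months: int = DEFAULT_N_MONTHS
    intercept: float = calibration.DEFAULT_INTERCEPT
    trend_slope: float = calibration.DEFAULT_TREND_SLOPE
    seasonal_amplitude: float = calibration.DEFAULT_SEASONAL_AMPLITUDE
    seasonal_offsets: np.ndarray | None = None  # optional 12-vector, centred
    ar_coef: float = calibration.DEFAULT_AR
    ma_coef: float = calibration.DEFAULT_MA
    sigma: float = calibration.DEFAULT_SIGMA
    level_component: float | None = None
    slope_component: float | None = None
    lag_months: int | None = None
    population: float | np.ndarray = 100_000.0
    seed: int = 0

    def __post_init__(self):
        self.scenario = Scenario.coerce(self.scenario)
        if self.lag_months is None:
            self.lag_months = DEFAULT_LAG_MONTHS if self.scenario is Scenario.LAGGED else 0
        if self.level_component is None or self.slope_component is None:
            level, slope = calibration.calibrate_level_slope(self.scenario.index, self.effect_size)
            if self.level_component is None:
                self.level_component = level
            if self.slope_component is None:
                self.slope_component = slope
        if self.seasonal_offsets is not None:
            self.seasonal_offsets = np.asarray(self.seasonal_offsets, dtype=float)
        self.validate()

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        if self.n_months < 24:
            raise ConfigError(f"n_months={self.n_months}: need at least 24 months")
        if not abs(self.ar_coef) < 1:
            raise ConfigError(f"ar_coef={self.ar_coef}: AR(1) coefficient must satisfy |a|<1")
        if not abs(self.ma_coef) < 1:
            raise ConfigError(f"ma_coef={self.ma_coef}: MA(1) coefficient must satisfy |m|<1")
        if self.sigma < 0:
            raise ConfigError(f"sigma={self.sigma}: must be non-negative")
        if self.lag_months < 0:
            raise ConfigError(f"lag_months={self.lag_months}: must be non-negative")
        if self.scenario is not Scenario.LAGGED and self.lag_months != 0:
            raise ConfigError("lag_months must be 0 unless scenario is LAGGED")
        T = self.intervention_month
        if not (1 < T < self.n_months):
            raise ConfigError(
                f"intervention month {T} (year {self.intervention_year}) must fall "
                f"strictly inside the series of {self.n_months} months"
            )
        if self.scenario is not Scenario.LAGGED:
            # For the lagged scenario the calibrated split deliberately does
            # not sum to the nominal effect size; see docs/methods.md.
            total = self.level_component + self.slope_component
            if not math.isclose(total, self.effect_size, rel_tol=0, abs_tol=1e-8):
                raise ConfigError(
                    f"effect_size={self.effect_size} but level_component+slope_component="
                    f"{total}: the components must sum to the effect size"
                )
        if self.seasonal_offsets is not None and self.seasonal_offsets.shape != (12,):
            raise ConfigError("seasonal_offsets must be a length-12 vector")
        pop = np.asarray(self.population, dtype=float)
        if np.any(pop <= 0):
            raise ConfigError("population must be positive")
        if pop.ndim == 1 and pop.shape[0] != self.n_months:
            raise ConfigError("per-month population vector must have length n_months")

    # -- derived quantities -------------------------------------------
    @property
    def intervention_month(self) -> int:
        """First month of the stated implementation year (1-based)."""
        return 12 * (self.intervention_year - 1) + 1

    def population_vector(self) -> np.ndarray:
        pop = np.asarray(self.population, dtype=float)
        if pop.ndim == 0:
            return np.full(self.n_months, float(pop))
        return pop

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenario"] = self.scenario.value
        if isinstance(d.get("seasonal_offsets"), np.ndarray):
            d["seasonal_offsets"] = d["seasonal_offsets"].tolist()
        if isinstance(d.get("population"), np.ndarray):
            d["population"] = d["population"].tolist()
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)


def scenario_config(scenario, effect_size: float, intervention_year: int, **overrides) -> SimulationConfig:
    """Convenience constructor with the calibrated level/slope split."""
    return SimulationConfig(
        scenario=Scenario.coerce(scenario),
        effect_size=effect_size,
        intervention_year=intervention_year,
        **overrides,
    )
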