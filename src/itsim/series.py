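"""The monthly rate-series container shared by the simulator and fitters."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MonthlySeries:
    """A simulated or observed monthly mortality-rate series.

    Attributes
    ----------
    t : month index 1..n.
    rate : observed rate (deaths per 100,000).
    mu : deterministic expected rate under the intervention (NaN if unknown).
    mu_counterfactual : deterministic expected rate with the policy effect
        removed (NaN if unknown).
    policy : policy covariate in [0, 1] used by the generating process.
    month_of_year : calendar month 1..12 (month 1 of the series is January).
    population : person count per month.
    intervention_month : month index T at which the policy starts.
    lag_months : length of the generating ramp (0 for abrupt effects).
    """

    t: np.ndarray
    rate: np.ndarray
    policy: np.ndarray
    month_of_year: np.ndarray
    population: np.ndarray
    intervention_month: int
    lag_months: int = 0
    mu: np.ndarray = field(default=None)
    mu_counterfactual: np.ndarray = field(default=None)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        n = self.t.shape[0]
        for name in ("rate", "policy", "month_of_year", "population"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have the same length as t ({n})")
            setattr(self, name, arr)
        for name in ("mu", "mu_counterfactual"):
            val = getattr(self, name)
            if val is None:
                setattr(self, name, np.full(n, np.nan))
            else:
                setattr(self, name, np.asarray(val, dtype=float))
        # a pre-intervention sub-series keeps T as a reference beyond its end
        if self.intervention_month < 1:
            raise ValueError("intervention_month must be >= 1")
        if np.any(np.diff(self.policy) < -1e-12):
            raise ValueError("policy covariate must be non-decreasing")

    def __len__(self) -> int:
        return self.t.shape[0]

    @property
    def n_pre(self) -> int:
        return int(np.sum(self.t < self.intervention_month))

    @property
    def n_post(self) -> int:
        return len(self) - self.n_pre

    def pre_intervention(self) -> "MonthlySeries":
        """The sub-series strictly before the intervention month."""
        mask = self.t < self.intervention_month
        return MonthlySeries(
            t=self.t[mask], rate=self.rate[mask], policy=self.policy[mask],
            month_of_year=self.month_of_year[mask], population=self.population[mask],
            intervention_month=self.intervention_month, lag_months=self.lag_months,
            mu=self.mu[mask], mu_counterfactual=self.mu_counterfactual[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        t_int = self.t.astype(int)
        return pd.DataFrame({
            "t": t_int,
            "year": (t_int - 1) // 12 + 1,
            "month": self.month_of_year.astype(int),
            "rate": self.rate,
            "mu": self.mu,
            "mu_counterfactual": self.mu_counterfactual,
            "policy": self.policy,
            "population": self.population,
            "intervention_month": self.intervention_month,
            "lag_months": self.lag_months,
        })

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MonthlySeries":
        required = {"t", "rate"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"series CSV is missing columns: {sorted(missing)}")
        t = frame["t"].to_numpy(dtype=float)
        n = len(t)
        if "intervention_month" in frame:
            T = int(frame["intervention_month"].iloc[0])
        else:
            raise ValueError("series CSV must carry an intervention_month column")
        lag = int(frame["lag_months"].iloc[0]) if "lag_months" in frame else 0
        month = (frame["month"].to_numpy(dtype=float) if "month" in frame
                 else (t.astype(int) - 1) % 12 + 1)
        population = (frame["population"].to_numpy(dtype=float) if "population" in frame
                      else np.full(n, 100_000.0))
        if "policy" in frame:
            policy = frame["policy"].to_numpy(dtype=float)
        else:
            from .dgp import policy_covariate
            policy = policy_covariate(t, T, lag)
        kwargs = {}
        for name in ("mu", "mu_counterfactual"):
            if name in frame:
                kwargs[name] = frame[name].to_numpy(dtype=float)
        return cls(t=t, rate=frame["rate"].to_numpy(dtype=float), policy=policy,
                   month_of_year=month, population=population,
                   intervention_month=T, lag_months=lag, **kwargs)
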