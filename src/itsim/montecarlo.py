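"""Monte-Carlo orchestration over (scenario x effect x timing x model) cells.

Each cell simulates ``n_replicates`` independent series, fits the
requested ITS model to every replicate, computes the estimated- and
predicted-approach deaths prevented, and aggregates:

* the mean estimate with its across-replicate 95% interval
  (mean +/- 1.96 * SD of the replicate estimates, the CLT convention),
* the mean of the per-replicate 95% intervals,
* two coverage probabilities over converged replicates:

  - ``coverage`` — fraction of replicates whose own deaths-scale 95%
    interval contains the design-true deaths prevented;
  - ``effect_size_coverage`` — fraction whose 95% interval for the
    level-change coefficient contains the (negative) nominal effect
    size, i.e. coverage on the rate scale (estimated approach only).

Replicate seeds are derived deterministically from the cell's master
seed and the replicate index, so results are independent of evaluation
order and individual cells are reproducible in isolation.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import EFFECT_HORIZON, Scenario, SimulationConfig, scenario_config
from .dgp import simulate_series, true_deaths_prevented
from .effects import (EffectEstimate, EstimationError, Z95, estimated_effect,
                      fit_pre_intervention, forecast_counterfactual, predicted_effect)
from .models import ModelSpec, fit_its

MATCHED_PAIRS = {(1, 1), (2, 2), (3, 3)}
CONVERGENCE_WARN_FRACTION = 0.10


@dataclass(frozen=True)
class CellSpec:
    """One Monte-Carlo cell of the replicate grid."""

    scenario: Scenario
    effect_size: float
    intervention_year: int
    fitting_model_id: int
    n_replicates: int = 1000
    master_seed: int = 0
    approaches: tuple[str, ...] = ("estimated", "predicted")

    def __post_init__(self):
        object.__setattr__(self, "scenario", Scenario.coerce(self.scenario))
        if self.intervention_year not in (5, 9, 13):
            raise ValueError("intervention_year must be one of 5, 9, 13")
        if self.fitting_model_id not in (1, 2, 3):
            raise ValueError("fitting_model_id must be 1, 2 or 3")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        bad = set(self.approaches) - {"estimated", "predicted"}
        if bad:
            raise ValueError(f"unknown approaches: {sorted(bad)}")

    @property
    def matched(self) -> bool:
        return (self.scenario.index, self.fitting_model_id) in MATCHED_PAIRS

    def seed_key(self) -> int:
        tag = f"{self.scenario.value}|{self.effect_size}|{self.intervention_year}|{self.fitting_model_id}"
        return zlib.crc32(tag.encode())

    def replicate_rng(self, replicate: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.master_seed, self.seed_key(), replicate])
        )


@dataclass
class MonteCarloResult:
    """Aggregated estimates for one (cell, approach) pair."""

    cell: CellSpec
    approach: str
    true_value: float
    n_converged: int
    mean_estimate: float
    sd_estimate: float
    across_replicate_ci: tuple[float, float]
    mean_within_ci: tuple[float, float]
    coverage: float
    effect_size_coverage: float | None = None
    estimates: np.ndarray = field(default=None, repr=False)

    @property
    def mc_se(self) -> float:
        return self.sd_estimate / np.sqrt(max(self.n_converged, 1))

    @property
    def bias(self) -> float:
        return self.mean_estimate - self.true_value


def _aggregate(cell: CellSpec, approach: str, truth: float, effect_size: float,
               estimates: list[EffectEstimate]) -> MonteCarloResult:
    values = np.array([e.deaths_prevented for e in estimates])
    n = values.shape[0]
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    lo = np.array([e.ci_low for e in estimates])
    hi = np.array([e.ci_high for e in estimates])
    coverage = float(np.mean([e.ci_contains(truth) for e in estimates]))
    es_cov = None
    if approach == "estimated":
        level = np.array([e.level_coef for e in estimates])
        level_se = np.array([e.level_coef_se for e in estimates])
        inside = np.abs(level - (-effect_size)) <= Z95 * level_se + 1e-12
        es_cov = float(np.mean(inside))
    return MonteCarloResult(
        cell=cell, approach=approach, true_value=truth, n_converged=n,
        mean_estimate=mean, sd_estimate=sd,
        across_replicate_ci=(mean - Z95 * sd, mean + Z95 * sd),
        mean_within_ci=(float(lo.mean()), float(hi.mean())),
        coverage=coverage, effect_size_coverage=es_cov, estimates=values,
    )


def run_cell(cell: CellSpec, config: SimulationConfig | None = None,
             horizon: int = EFFECT_HORIZON) -> dict[str, MonteCarloResult]:
    """Simulate, fit and aggregate one Monte-Carlo cell.

    ``config`` overrides the default calibrated generating process; its
    scenario/effect/timing fields are forced to match the cell.
    """
    base = config if config is not None else scenario_config(
        cell.scenario, cell.effect_size, cell.intervention_year)
    if (base.scenario, base.effect_size, base.intervention_year) != (
            cell.scenario, cell.effect_size, cell.intervention_year):
        base = scenario_config(cell.scenario, cell.effect_size, cell.intervention_year,
                               **{k: getattr(base, k) for k in (
                                   "n_months", "intercept", "trend_slope",
                                   "seasonal_amplitude", "ar_coef", "ma_coef",
                                   "sigma", "population")})
    truth = true_deaths_prevented(base, horizon)
    spec = ModelSpec.for_model(cell.fitting_model_id)
    collected: dict[str, list[EffectEstimate]] = {a: [] for a in cell.approaches}
    n_failed = 0
    for r in range(cell.n_replicates):
        series = simulate_series(base, rng=cell.replicate_rng(r))
        try:
            if "estimated" in cell.approaches:
                fit = fit_its(series, spec)
                collected["estimated"].append(estimated_effect(fit, series, horizon))
            if "predicted" in cell.approaches:
                prefit = fit_pre_intervention(series)
                forecasts = forecast_counterfactual(prefit, horizon)
                collected["predicted"].append(
                    predicted_effect(series, forecasts, horizon, model_id=cell.fitting_model_id))
        except EstimationError:
            n_failed += 1
            continue
    if n_failed > CONVERGENCE_WARN_FRACTION * cell.n_replicates:
        warnings.warn(
            f"cell {cell.scenario.value}/E{cell.effect_size}/year{cell.intervention_year}"
            f"/M{cell.fitting_model_id}: {n_failed} of {cell.n_replicates} replicates "
            "failed to converge", RuntimeWarning)
    return {a: _aggregate(cell, a, truth, cell.effect_size, ests)
            for a, ests in collected.items() if ests}


def results_to_frame(results: list[MonteCarloResult]) -> pd.DataFrame:
    """Long-format summary table, one row per (cell, approach)."""
    rows = []
    for res in results:
        cell = res.cell
        rows.append({
            "scenario": cell.scenario.index,
            "model": cell.fitting_model_id,
            "effect_size": cell.effect_size,
            "year": cell.intervention_year,
            "approach": res.approach,
            "matched": cell.matched,
            "mean": res.mean_estimate,
            "ci_low": res.across_replicate_ci[0],
            "ci_high": res.across_replicate_ci[1],
            "mean_within_ci_low": res.mean_within_ci[0],
            "mean_within_ci_high": res.mean_within_ci[1],
            "coverage": res.coverage,
            "effect_size_coverage": res.effect_size_coverage,
            "truth": res.true_value,
            "n_reps": cell.n_replicates,
            "n_converged": res.n_converged,
            "mc_se": res.mc_se,
        })
    return pd.DataFrame(rows)


def run_grid(cells: list[CellSpec], config: SimulationConfig | None = None,
             horizon: int = EFFECT_HORIZON, progress=None) -> pd.DataFrame:
    """Run many cells and collect one long-format results table."""
    results: list[MonteCarloResult] = []
    for cell in cells:
        out = run_cell(cell, config=config, horizon=horizon)
        results.extend(out.values())
        if progress is not None:
            progress(cell, out)
    return results_to_frame(results)


# ---------------------------------------------------------------------------
# Grid presets mirroring the published table structures
# ---------------------------------------------------------------------------

EFFECT_SIZES = (5.0, 10.0, 15.0)
YEARS = (5, 9, 13)


def matched_cells(n_replicates: int = 1000, master_seed: int = 0,
                  approaches=("estimated", "predicted")) -> list[CellSpec]:
    """The 27 matched cells: 3 scenarios x 3 effect sizes x 3 years."""
    return [
        CellSpec(scenario=s, effect_size=e, intervention_year=y,
                 fitting_model_id=s, n_replicates=n_replicates,
                 master_seed=master_seed, approaches=tuple(approaches))
        for s in (1, 2, 3) for e in EFFECT_SIZES for y in YEARS
    ]


def misspecification_cells(scenarios=(3,), models=(1, 2), n_replicates: int = 1000,
                           master_seed: int = 0,
                           approaches=("estimated", "predicted")) -> list[CellSpec]:
    """Unmatched (scenario, model) cells, by default lagged data with
    the two simpler models."""
    cells = []
    for s in scenarios:
        for m in models:
            if (s, m) in MATCHED_PAIRS:
                continue
            for e in EFFECT_SIZES:
                for y in YEARS:
                    cells.append(CellSpec(scenario=s, effect_size=e,
                                          intervention_year=y, fitting_model_id=m,
                                          n_replicates=n_replicates,
                                          master_seed=master_seed,
                                          approaches=tuple(approaches)))
    return cells


def misspecification_grid(cells: list[CellSpec] | None = None,
                          n_replicates: int = 1000, master_seed: int = 0,
                          config: SimulationConfig | None = None) -> pd.DataFrame:
    """Run the sensitivity grid (matched + unmatched rows) and return the
    long-format table."""
    if cells is None:
        cells = (matched_cells(n_replicates, master_seed)
                 + misspecification_cells(n_replicates=n_replicates,
                                          master_seed=master_seed))
    return run_grid(cells, config=config)
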