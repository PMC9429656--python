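"""Configuration loading, result writers and run manifests."""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .config import ConfigError, Scenario, SimulationConfig
from .montecarlo import CellSpec
from .series import MonthlySeries

_CELL_KEYS = {"scenario", "effect_size", "intervention_year", "fitting_model_id",
              "n_replicates", "master_seed", "approaches"}


def load_config(path) -> SimulationConfig:
    """Load and validate a single simulation configuration (YAML or JSON)."""
    data = _read_mapping(path)
    return SimulationConfig.from_dict(data)


def load_cells(path) -> list[CellSpec]:
    """Load a Monte-Carlo cell list.

    The file is a mapping with a ``cells`` list (each entry a CellSpec
    mapping) and optional top-level defaults applied to every cell, or
    the preset names ``matched`` / ``misspecification``.
    """
    from . import montecarlo

    data = _read_mapping(path)
    preset = data.pop("preset", None)
    entries = data.pop("cells", None)
    defaults = {k: data.pop(k) for k in list(data) if k in _CELL_KEYS}
    if data:
        raise ConfigError(f"unknown configuration keys: {sorted(data)}")
    if preset is not None:
        kwargs = {k: v for k, v in defaults.items()
                  if k in ("n_replicates", "master_seed", "approaches")}
        if preset in ("matched", "table1"):
            return montecarlo.matched_cells(**kwargs)
        if preset in ("misspecification", "table2", "table3"):
            return (montecarlo.matched_cells(**kwargs)
                    + montecarlo.misspecification_cells(**kwargs))
        raise ConfigError(f"unknown preset {preset!r}")
    if not entries:
        raise ConfigError("cell file must contain a 'cells' list or a 'preset'")
    cells = []
    for entry in entries:
        unknown = set(entry) - _CELL_KEYS
        if unknown:
            raise ConfigError(f"unknown cell keys: {sorted(unknown)}")
        merged = {**defaults, **entry}
        if "approaches" in merged:
            merged["approaches"] = tuple(merged["approaches"])
        cells.append(CellSpec(**merged))
    return cells


def _read_mapping(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at the top level")
    return data


def write_series(series: MonthlySeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_series(path) -> MonthlySeries:
    return MonthlySeries.from_frame(pd.read_csv(path, float_precision="round_trip"))


def read_results(path) -> pd.DataFrame:
    """Read a results CSV back with exact float round-tripping."""
    return pd.read_csv(path, float_precision="round_trip")


def write_results(results: pd.DataFrame, path) -> Path:
    """Write the long-format results CSV plus a formatted text table.

    Returns the CSV path; the text table lands next to it with a
    ``.txt`` suffix.  Full float precision is kept so that a round-trip
    read reproduces the values exactly.
    """
    if results is None or len(results) == 0:
        raise ValueError("refusing to write an empty results table")
    path = Path(path)
    results.to_csv(path, index=False)  # default float repr round-trips exactly
    txt = path.with_suffix(".txt")
    txt.write_text(format_results_table(results))
    return path


def format_results_table(results: pd.DataFrame) -> str:
    """Human-readable grouping: deaths prevented and 95% CIs per cell."""
    lines = ["Deaths prevented in the 12 months following the intervention", ""]
    for (scenario, model), block in results.groupby(["scenario", "model"], sort=True):
        matched = "matched" if bool(block["matched"].iloc[0]) else "unmatched"
        lines.append(f"Scenario {scenario}, Model {model} ({matched})")
        header = f"  {'year':>4} {'effect':>6} {'approach':>10} {'mean':>8} {'95% CI':>18} {'coverage':>8} {'truth':>7}"
        lines.append(header)
        for _, row in block.sort_values(["year", "effect_size", "approach"]).iterrows():
            ci = f"({row.ci_low:7.1f},{row.ci_high:7.1f})"
            cov = f"{row.coverage:.3f}" if np.isfinite(row.coverage) else "-"
            lines.append(
                f"  {int(row.year):>4} {row.effect_size:>6.0f} {row.approach:>10} "
                f"{row['mean']:>8.1f} {ci:>18} {cov:>8} {row.truth:>7.1f}"
            )
        lines.append("")
    return "\n".join(lines)


@dataclass
class RunManifest:
    """Reproducibility record written next to every output artifact."""

    command: str
    master_seed: int | None
    config: dict
    outputs: list[str]
    version: str = _version
    timestamp: str = field(default_factory=lambda: datetime.datetime.now().isoformat(timespec="seconds"))
    runtime_seconds: dict = field(default_factory=dict)

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n")
        return path

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def plot_trajectories(configs, path=None):
    """Convenience illustration of the scenario mean trajectories."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .dgp import expected_trajectory

    fig, ax = plt.subplots(figsize=(9, 4.5))
    for config in configs:
        mu, cf = expected_trajectory(config)
        label = f"scenario {config.scenario.index}, effect {config.effect_size:g}"
        ax.plot(np.arange(1, config.n_months + 1), mu, lw=1.2, label=label)
    if configs:
        ax.plot(np.arange(1, configs[0].n_months + 1), cf, "k--", lw=1.0,
                label="no intervention")
        ax.axvline(configs[0].intervention_month, color="grey", lw=0.8)
    ax.set_xlabel("month")
    ax.set_ylabel("expected rate per 100,000")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
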