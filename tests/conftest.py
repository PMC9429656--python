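"""Shared fixtures: noiseless configs and cached Monte-Carlo cells.

The expensive Monte-Carlo cells are session-scoped so that the
reproduction and coverage tests can share one replicate set.
"""

import numpy as np
import pytest

from itsim import ModelSpec, scenario_config, simulate_series
from itsim.montecarlo import CellSpec, run_cell

MASTER_SEED = 20260101


@pytest.fixture(scope="session")
def noiseless_configs():
    return {
        s: scenario_config(s, 10.0, 5, sigma=0.0, ar_coef=0.0, ma_coef=0.0)
        for s in (1, 2, 3)
    }


@pytest.fixture(scope="session")
def default_series():
    """One default-calibration Scenario-1 series with a fixed seed."""
    return simulate_series(scenario_config(1, 10.0, 5, seed=7))


@pytest.fixture(scope="session")
def matched_scenario1_cells():
    """Matched Scenario-1 year-5 cells at desk scale, both approaches."""
    out = {}
    for effect in (5.0, 10.0, 15.0):
        cell = CellSpec(scenario=1, effect_size=effect, intervention_year=5,
                        fitting_model_id=1, n_replicates=500, master_seed=MASTER_SEED)
        out[effect] = run_cell(cell)
    return out


@pytest.fixture(scope="session")
def misspecified_cells():
    """Lagged-scenario data analysed with Model 1 (the misspecified fit)."""
    out = {}
    for effect, year, approaches in (
            (5.0, 5, ("estimated", "predicted")),
            (5.0, 13, ("estimated",)),
            (15.0, 13, ("estimated",))):
        cell = CellSpec(scenario=3, effect_size=effect, intervention_year=year,
                        fitting_model_id=1, n_replicates=150,
                        master_seed=MASTER_SEED, approaches=approaches)
        out[(effect, year)] = run_cell(cell)
    return out
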