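"""Shared fixtures: small simulated cohorts and their MLE fits.

Session-scoped so the expensive fitting runs once; every fixture is fully
seeded, so the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from driftlab.fitting import FitOptions, fit_dataset
from driftlab.model import CONTROL_FREE_PARAMS, LABELS_FREE_PARAMS
from driftlab.simulate import DesignSpec, PopulationSpec, simulate_dataset


@pytest.fixture(scope="session")
def labels_cohort():
    """Ten labels-variant participants at the 72-trial design."""
    design = DesignSpec(study="study1", n_participants=10, seed=101)
    population = PopulationSpec(variant="labels", seed=102)
    trials, truth = simulate_dataset(design, population)
    return trials, truth


@pytest.fixture(scope="session")
def labels_fits(labels_cohort):
    trials, _ = labels_cohort
    return fit_dataset(trials, FitOptions(n_starts=6, seed=103))


@pytest.fixture(scope="session")
def control_cohort():
    """Twelve control-variant participants at the 72-trial design."""
    design = DesignSpec(study="control", n_participants=12, seed=104)
    population = PopulationSpec(variant="control", seed=105)
    trials, truth = simulate_dataset(design, population)
    return trials, truth


@pytest.fixture(scope="session")
def control_fits(control_cohort):
    trials, _ = control_cohort
    return fit_dataset(trials, FitOptions(n_starts=6, seed=106))


def truth_as_fits(truth: pd.DataFrame) -> pd.DataFrame:
    """Dress a true-parameter table in the fit-table layout (used to test
    group analysis operations without paying for model fitting)."""
    out = truth.copy()
    variant = "control" if (out["study"] == "control").all() else "labels"
    out["variant"] = variant
    names = CONTROL_FREE_PARAMS if variant == "control" else LABELS_FREE_PARAMS
    for name in ("v_sl", "v_sol", "Tl"):
        if name not in out.columns:
            out[name] = 0.0
    out["error"] = ""
    return out


def draw_param_table(
    rng: np.random.Generator,
    n: int,
    study: str = "study1",
    shift: dict | None = None,
) -> pd.DataFrame:
    """Synthetic fit-table rows drawn from a simple population (no fitting)."""
    variant = "control" if study == "control" else "labels"
    names = CONTROL_FREE_PARAMS if variant == "control" else LABELS_FREE_PARAMS
    means = {
        "v_base": 0.0, "v_s": 0.8, "v_so": 0.2, "v_sl": 0.4, "v_sol": 0.4,
        "a": 0.8, "w": 0.5, "T0": 0.4, "Tl": -0.04,
    }
    sds = {
        "v_base": 0.2, "v_s": 0.4, "v_so": 0.4, "v_sl": 0.4, "v_sol": 0.4,
        "a": 0.1, "w": 0.04, "T0": 0.08, "Tl": 0.04,
    }
    if shift:
        means = {**means, **{k: means[k] + v for k, v in shift.items()}}
    rows = []
    for i in range(n):
        row = {"participant_id": f"{study}-{i:03d}", "study": study, "variant": variant}
        for name in names:
            row[name] = rng.normal(means[name], sds[name])
        row["a"] = max(row["a"], 0.2)
        row["w"] = min(max(row["w"], 0.1), 0.9)
        row["T0"] = max(row["T0"], 0.05)
        for name in ("v_sl", "v_sol", "Tl"):
            row.setdefault(name, 0.0)
        row["error"] = ""
        rows.append(row)
    return pd.DataFrame(rows)
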