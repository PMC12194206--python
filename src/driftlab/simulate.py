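"""Synthetic study designs and diffusion-process trial simulation.

The generator reproduces the structure of the object-detection studies the
model is built for: three arms (a no-labels ``control`` plus two
labels-present arms ``study1``/``study2``), 72 trials per participant
split 36 upright / 36 inverted, labels-present arms crossed 18-per-cell
with valid/invalid labels, the familiar side left/right balanced within
every cell, a 4000 ms response deadline, and per-participant parameter
heterogeneity drawn from a truncated-normal population.

Choices and RTs are simulated from the diffusion process itself
(Euler-Maruyama with within-step Brownian-bridge crossing detection; see
:mod:`driftlab._kernels`), so simulated data and the WFPT likelihood refer
to exactly the same generative model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import _kernels
from .io import TRIAL_COLUMNS, coerce_trials
from .model import CONTROL_FREE_PARAMS, LABELS_FREE_PARAMS, DDMParams, TrialParams

__all__ = [
    "DesignSpec",
    "PopulationSpec",
    "DEFAULT_N_PARTICIPANTS",
    "generate_design",
    "simulate_trial",
    "simulate_dataset",
    "inject_slow_contaminants",
]

logger = logging.getLogger(__name__)

#: Default group sizes per study arm (control / study1 / study2).
DEFAULT_N_PARTICIPANTS = {"control": 113, "study1": 105, "study2": 103}

#: Euler-Maruyama step (s).  With bridge-corrected crossing detection the
#: residual first-passage bias at this step is far below RT precision.
SIM_DT = 1e-4

# Population defaults: centred on group-level magnitudes typical of masked
# figure-ground detection (thresholds near 0.8 evidence units, non-decision
# time near 0.5 s, a slight rightward start bias) with the substantial
# between-participant drift heterogeneity such data show.
_LABELS_MEANS = {
    "v_base": 0.0,
    "v_s": 0.80,
    "v_so": 0.17,
    "v_sl": 0.45,
    "v_sol": 0.37,
    "a": 0.78,
    "w": 0.52,
    "T0": 0.50,
    "Tl": -0.04,
}
_LABELS_SDS = {
    "v_base": 0.20,
    "v_s": 0.50,
    "v_so": 0.45,
    "v_sl": 0.50,
    "v_sol": 0.60,
    "a": 0.15,
    "w": 0.05,
    "T0": 0.10,
    "Tl": 0.06,
}
_CONTROL_MEANS = {k: _LABELS_MEANS[k] for k in CONTROL_FREE_PARAMS}
_CONTROL_SDS = {k: _LABELS_SDS[k] for k in CONTROL_FREE_PARAMS}

#: Truncation bounds applied when sampling participants.
_PARAM_BOUNDS = {
    "v_base": (-8.0, 8.0),
    "v_s": (-8.0, 8.0),
    "v_so": (-8.0, 8.0),
    "v_sl": (-8.0, 8.0),
    "v_sol": (-8.0, 8.0),
    "a": (0.2, 3.0),
    "w": (0.15, 0.85),
    "T0": (0.08, 1.2),
    "Tl": (-0.3, 0.3),
}


@dataclass(frozen=True)
class DesignSpec:
    """Structure of one study arm.

    ``n_participants=None`` selects the arm's default group size
    (:data:`DEFAULT_N_PARTICIPANTS`).  ``trials_per_participant`` may
    deviate from 72 but must keep the design balanced: divisible by 4 for
    the control arm (orientation x side) and by 8 for labels arms
    (orientation x label x side).
    """

    study: str
    n_participants: Optional[int] = None
    trials_per_participant: int = 72
    deadline: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.study not in DEFAULT_N_PARTICIPANTS:
            raise ValueError(f"unknown study {self.study!r}")
        divisor = 4 if self.study == "control" else 8
        if self.trials_per_participant <= 0 or self.trials_per_participant % divisor:
            raise ValueError(
                f"trials_per_participant must be a positive multiple of {divisor} "
                f"for {self.study}, got {self.trials_per_participant}"
            )
        if self.deadline <= 0:
            raise ValueError("deadline must be positive")

    @property
    def n(self) -> int:
        return (
            DEFAULT_N_PARTICIPANTS[self.study]
            if self.n_participants is None
            else self.n_participants
        )

    @property
    def variant(self) -> str:
        return "control" if self.study == "control" else "labels"


@dataclass(frozen=True)
class PopulationSpec:
    """Truncated-normal population over per-participant parameters.

    Used for parameter-recovery experiments and end-to-end pipeline checks;
    the fitting itself is fixed-effects per participant and does not assume
    this population.
    """

    variant: str = "labels"
    means: Mapping[str, float] = field(default_factory=dict)
    sds: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("control", "labels"):
            raise ValueError(f"variant must be 'control' or 'labels', got {self.variant!r}")
        defaults_m = _CONTROL_MEANS if self.variant == "control" else _LABELS_MEANS
        defaults_s = _CONTROL_SDS if self.variant == "control" else _LABELS_SDS
        unknown = (set(self.means) | set(self.sds)) - set(defaults_m)
        if unknown:
            raise ValueError(f"unknown parameter names {sorted(unknown)} for {self.variant} variant")
        object.__setattr__(self, "means", {**defaults_m, **dict(self.means)})
        object.__setattr__(self, "sds", {**defaults_s, **dict(self.sds)})
        if any(s < 0 for s in self.sds.values()):
            raise ValueError("population SDs must be non-negative")
        for name, m in self.means.items():
            lo, hi = _PARAM_BOUNDS[name]
            if not (lo <= m <= hi):
                raise ValueError(f"population mean for {name} outside bounds ({lo}, {hi})")

    @property
    def free_names(self) -> tuple[str, ...]:
        return CONTROL_FREE_PARAMS if self.variant == "control" else LABELS_FREE_PARAMS

    def sample_participant(self, rng: np.random.Generator) -> DDMParams:
        """Draw one participant's true parameters (rejection-truncated)."""
        values: dict[str, float] = {}
        for name in self.free_names:
            lo, hi = _PARAM_BOUNDS[name]
            m, s = self.means[name], self.sds[name]
            x = m
            if s > 0:
                for _ in range(1000):
                    x = rng.normal(m, s)
                    if lo <= x <= hi:
                        break
                else:  # pragma: no cover - pathological spec
                    x = min(max(m, lo), hi)
            values[name] = x
        if self.variant == "labels" and values["T0"] + values["Tl"] < 0.05:
            values["Tl"] = 0.05 - values["T0"]
        return DDMParams(variant=self.variant, **values)


def _balanced_cells(study: str, n_trials: int) -> pd.DataFrame:
    """Fully crossed, exactly balanced covariate table for one participant."""
    if study == "control":
        per = n_trials // 4
        cells = [(o, None, s) for o in (1, 0) for s in (1, -1)]
    else:
        per = n_trials // 8
        cells = [(o, lab, s) for o in (1, 0) for lab in (1, 0) for s in (1, -1)]
    rows = [(o, lab, s) for (o, lab, s) in cells for _ in range(per)]
    df = pd.DataFrame(rows, columns=["orientation", "label", "side"])
    return df


def generate_design(spec: DesignSpec) -> pd.DataFrame:
    """Trial-skeleton table (covariates only) for every participant.

    Cell counts are exact for every seed; only the trial order within a
    participant is randomised.  Each participant sees each display slot
    once, mirroring the single-presentation design of the task.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    width = len(str(max(spec.n, 1)))
    for p in range(spec.n):
        cells = _balanced_cells(spec.study, spec.trials_per_participant)
        order = rng.permutation(len(cells))
        df = cells.iloc[order].reset_index(drop=True)
        df.insert(0, "participant_id", f"{spec.study}-{p + 1:0{width}d}")
        df.insert(1, "study", spec.study)
        df["trial"] = np.arange(len(df))
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["label"] = out["label"].astype("Int64")
    return out


def simulate_trial(
    tp: TrialParams, deadline: float, rng: np.random.Generator
) -> tuple[str, float, bool]:
    """Simulate a single trial; returns ``(choice, rt, responded)``.

    Reference-path implementation of the same Euler-Maruyama/bridge scheme
    as the batch kernel, driven by a numpy Generator.  ``rt`` is nan when
    the deadline lapses.
    """
    dt = SIM_DT
    sqrt_dt = np.sqrt(dt)
    y = tp.w * tp.a
    budget = deadline - tp.Ter
    t = 0.0
    while t < budget:
        y1 = y + tp.v * dt + sqrt_dt * rng.standard_normal()
        t += dt
        hit: Optional[int] = None
        if y1 >= tp.a:
            hit = 1
        elif y1 <= 0.0:
            hit = 0
        elif rng.random() < np.exp(-2.0 * (tp.a - y) * (tp.a - y1) / dt):
            hit = 1
        elif rng.random() < np.exp(-2.0 * y * y1 / dt):
            hit = 0
        if hit is not None:
            return ("right" if hit == 1 else "left", t + tp.Ter, True)
        y = y1
    return ("", float("nan"), False)


def _trial_diffusion_arrays(design_p: pd.DataFrame, params: DDMParams):
    S = design_p["side"].to_numpy(dtype=float)
    O = design_p["orientation"].to_numpy(dtype=float)
    L = design_p["label"].fillna(0).to_numpy(dtype=float)
    theta = params.to_full_vector()
    v = theta[0] + theta[1] * S + theta[2] * S * O + theta[3] * S * L + theta[4] * S * O * L
    ter = theta[7] + theta[8] * L
    a = np.full_like(v, params.a)
    w = np.full_like(v, params.w)
    return v, a, w, ter


def simulate_dataset(
    design: DesignSpec, population: PopulationSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; returns ``(trials, truth)``.

    ``trials`` follows the CSV trial dialect (:data:`TRIAL_COLUMNS`);
    ``truth`` holds one row of true generating parameters per participant
    for recovery scoring.  Fully determined by ``design.seed`` and
    ``population.seed``.
    """
    if population.variant != design.variant:
        raise ValueError(
            f"population variant {population.variant!r} does not match "
            f"design variant {design.variant!r}"
        )
    skeleton = generate_design(design)
    pop_rng = np.random.default_rng(population.seed)
    sim_seeds = np.random.SeedSequence(design.seed).spawn(design.n)

    frames, truth_rows = [], []
    for idx, (pid, design_p) in enumerate(skeleton.groupby("participant_id", sort=True)):
        params = population.sample_participant(pop_rng)
        v, a, w, ter = _trial_diffusion_arrays(design_p, params)
        kseed = int(sim_seeds[idx].generate_state(1)[0] % (2**31))
        choice_code, rt = _kernels.simulate_batch(v, a, w, ter, design.deadline, SIM_DT, kseed)
        df = design_p[["participant_id", "study", "side", "orientation", "label"]].copy()
        df["choice"] = np.where(choice_code == 1, "right", np.where(choice_code == 0, "left", None))
        df["rt_s"] = rt
        df["responded"] = choice_code >= 0
        frames.append(df)
        truth_rows.append({"participant_id": pid, "study": design.study, **{
            name: getattr(params, name) for name in params.free_names
        }})
    trials = coerce_trials(pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS])
    truth = pd.DataFrame(truth_rows)
    non_resp = 1.0 - trials["responded"].mean()
    if non_resp > 0.5:
        warnings.warn(
            f"population produced {non_resp:.0%} non-responses before the "
            f"{design.deadline:.1f} s deadline",
            stacklevel=2,
        )
    logger.info(
        "simulated %s: %d participants, %d trials, %.1f%% responded",
        design.study, design.n, len(trials), 100 * trials["responded"].mean(),
    )
    return trials, truth


def inject_slow_contaminants(
    trials: pd.DataFrame,
    fraction: float,
    rng: np.random.Generator,
    rt_range: tuple[float, float] = (2.0, 4.0),
) -> pd.DataFrame:
    """Replace a random fraction of responded RTs with slow uniform draws.

    A probe for fit diagnostics: contaminated trials keep their choice but
    get an RT uniform in ``rt_range``, emulating lapses / late deliberation
    that the single-stage diffusion model does not produce.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    out = trials.copy()
    idx = out.index[out["responded"]]
    n_bad = int(round(fraction * len(idx)))
    bad = rng.choice(idx, size=n_bad, replace=False)
    out.loc[bad, "rt_s"] = rng.uniform(rt_range[0], rt_range[1], size=n_bad)
    return out
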