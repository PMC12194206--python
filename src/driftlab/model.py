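"""Condition-to-parameter mapping and per-trial likelihood.

The behavioral task is a two-alternative figure-ground judgment: on each
trial a bipartite display sketches a familiar object on one side
(``S = +1`` right, ``-1`` left), upright or inverted (``O = 1`` / ``0``),
optionally preceded by a valid or invalid word label (``L = 1`` / ``0``;
absent in the control arm).  The diffusion's drift rate is a linear
function of these codes,

    v = v_base + v_s * S + v_so * S * O  [+ v_sl * S * L + v_sol * S * O * L]

and the non-decision time may shift with label validity,

    Ter = T0 + Tl * L.

Boundary separation ``a`` and relative start ``w`` are constant within a
participant: both are set before the stimulus appears.

The *control* variant has 6 free parameters (v_base, v_s, v_so, a, w, T0);
the *labels* variant has 9 (adding v_sl, v_sol, Tl).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .wfpt import DEFAULT_CONFIG, DiffusionSpec, WfptConfig, wfpt_density

__all__ = [
    "STUDIES",
    "CONTROL_FREE_PARAMS",
    "LABELS_FREE_PARAMS",
    "PARAM_ORDER",
    "DDMParams",
    "TrialParams",
    "TrialRecord",
    "effective_params",
    "trial_loglik",
    "variant_for_study",
]

STUDIES = ("control", "study1", "study2")

#: Free-parameter names per model variant, in optimisation order.
CONTROL_FREE_PARAMS = ("v_base", "v_s", "v_so", "a", "w", "T0")
LABELS_FREE_PARAMS = ("v_base", "v_s", "v_so", "v_sl", "v_sol", "a", "w", "T0", "Tl")

#: Canonical order of the full 9-parameter vector used by the kernels.
PARAM_ORDER = ("v_base", "v_s", "v_so", "v_sl", "v_sol", "a", "w", "T0", "Tl")


def variant_for_study(study: str) -> str:
    if study not in STUDIES:
        raise ValueError(f"unknown study {study!r}; expected one of {STUDIES}")
    return "control" if study == "control" else "labels"


@dataclass(frozen=True)
class DDMParams:
    """Per-participant diffusion parameters.

    Drift coefficients are in evidence/s per unit of the (coded) covariate;
    ``a`` in evidence units; ``w`` dimensionless in (0, 1); ``T0`` and
    ``Tl`` in seconds.  The reported starting-point *bias* is ``w - 0.5``
    (positive = toward the right side); the fitted free parameter is ``w``.
    """

    v_base: float
    v_s: float
    v_so: float
    a: float
    w: float
    T0: float
    v_sl: float = 0.0
    v_sol: float = 0.0
    Tl: float = 0.0
    variant: str = "labels"

    def __post_init__(self) -> None:
        if self.variant not in ("control", "labels"):
            raise ValueError(f"variant must be 'control' or 'labels', got {self.variant!r}")
        if not (self.a > 0.0):
            raise ValueError(f"boundary separation a must be positive, got {self.a}")
        if not (0.0 < self.w < 1.0):
            raise ValueError(f"relative start w must lie in (0, 1), got {self.w}")
        if self.T0 < 0.0:
            raise ValueError(f"baseline non-decision time T0 must be >= 0, got {self.T0}")
        if self.T0 + self.Tl < 0.0:
            raise ValueError("valid-label non-decision time T0 + Tl must be >= 0")
        if self.variant == "control" and (self.v_sl or self.v_sol or self.Tl):
            raise ValueError("control variant fixes v_sl, v_sol and Tl at 0")

    @classmethod
    def control(cls, v_base: float, v_s: float, v_so: float, a: float, w: float, T0: float) -> "DDMParams":
        return cls(v_base=v_base, v_s=v_s, v_so=v_so, a=a, w=w, T0=T0, variant="control")

    @property
    def free_names(self) -> tuple[str, ...]:
        return CONTROL_FREE_PARAMS if self.variant == "control" else LABELS_FREE_PARAMS

    @property
    def start_bias(self) -> float:
        """Starting-point bias ``w - 0.5``; positive = toward the right side."""
        return self.w - 0.5

    def to_full_vector(self) -> np.ndarray:
        """Full 9-vector in :data:`PARAM_ORDER` (zeros for fixed params)."""
        return np.array([getattr(self, name) for name in PARAM_ORDER], dtype=float)

    def with_variant(self, variant: str) -> "DDMParams":
        return replace(self, variant=variant)


@dataclass(frozen=True)
class TrialParams:
    """Effective diffusion parameters for one trial."""

    v: float
    a: float
    w: float
    Ter: float

    def __post_init__(self) -> None:
        if self.a <= 0.0 or not (0.0 < self.w < 1.0) or self.Ter < 0.0:
            raise ValueError(f"invalid trial parameters {self!r}")


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial: condition covariates plus the response."""

    participant_id: str
    study: str
    S: int
    O: int
    choice: str  # "left" | "right"
    rt: float  # seconds
    L: Optional[int] = None
    responded: bool = True

    def __post_init__(self) -> None:
        if self.study not in STUDIES:
            raise ValueError(f"unknown study {self.study!r}")
        if self.S not in (-1, 1):
            raise ValueError(f"side code S must be -1 or +1, got {self.S}")
        if self.O not in (0, 1):
            raise ValueError(f"orientation code O must be 0 or 1, got {self.O}")
        if self.L not in (None, 0, 1):
            raise ValueError(f"label code L must be 0, 1 or absent, got {self.L}")
        if self.study == "control" and self.L is not None:
            raise ValueError("control trials carry no label code")
        if self.study != "control" and self.L is None:
            raise ValueError(f"{self.study} trials require a label code")
        if self.responded:
            if self.choice not in ("left", "right"):
                raise ValueError(f"choice must be 'left' or 'right', got {self.choice!r}")
            if not (self.rt > 0.0 and math.isfinite(self.rt)):
                raise ValueError(f"responded trials need rt > 0, got {self.rt}")

    @property
    def correct(self) -> bool:
        """Response scored correct when it matches the familiar side."""
        return (self.choice == "right") == (self.S == 1)


def effective_params(params: DDMParams, S: int, O: int, L: Optional[int] = None) -> TrialParams:
    """Map condition codes to the trial's effective (v, a, w, Ter).

    Raises a validation error when a label code is supplied for the control
    variant, when it is missing for the labels variant, or when a code lies
    outside its domain.
    """
    if S not in (-1, 1):
        raise ValueError(f"side code S must be -1 or +1, got {S}")
    if O not in (0, 1):
        raise ValueError(f"orientation code O must be 0 or 1, got {O}")
    if params.variant == "control":
        if L is not None:
            raise ValueError("label code supplied for control-variant parameters")
        lab = 0
    else:
        if L not in (0, 1):
            raise ValueError(f"labels variant requires label code 0 or 1, got {L}")
        lab = L
    v = (
        params.v_base
        + params.v_s * S
        + params.v_so * S * O
        + params.v_sl * S * lab
        + params.v_sol * S * O * lab
    )
    ter = params.T0 + params.Tl * lab
    return TrialParams(v=v, a=params.a, w=params.w, Ter=ter)


def trial_loglik(trial: TrialRecord, params: DDMParams, cfg: Optional[WfptConfig] = None) -> float:
    """Log-likelihood (nats) of one responded trial under ``params``.

    The WFPT density is evaluated at ``t = rt - Ter`` at the boundary
    matching the choice (upper = right, lower = left) and floored at
    ``cfg.density_floor``; trials with ``rt - Ter`` at or below
    ``cfg.t_floor`` receive the floor directly.
    """
    if cfg is None:
        cfg = DEFAULT_CONFIG
    if not trial.responded:
        raise ValueError("non-responded trials do not enter the likelihood")
    tp = effective_params(params, trial.S, trial.O, trial.L)
    t = trial.rt - tp.Ter
    if t <= cfg.t_floor:
        return math.log(cfg.density_floor)
    boundary = "upper" if trial.choice == "right" else "lower"
    dens = wfpt_density(t, DiffusionSpec(v=tp.v, a=tp.a, w=tp.w), boundary=boundary, cfg=cfg)
    return math.log(max(dens, cfg.density_floor))
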