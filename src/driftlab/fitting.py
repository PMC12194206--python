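"""Per-participant maximum-likelihood estimation of the diffusion model.

Each participant is fit independently by minimising the negative total
log-likelihood of their responded trials (sum of per-trial WFPT log
densities) under box bounds, restarting a local optimizer (L-BFGS-B) from
several jittered initial points and keeping the best optimum.  The fits
are deterministic given the data and the seed; restart seeds come from a
nested seed stream, so the best likelihood over the first *k* starts is
non-decreasing in *k*.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _kernels
from .model import (
    CONTROL_FREE_PARAMS,
    LABELS_FREE_PARAMS,
    PARAM_ORDER,
    DDMParams,
    variant_for_study,
)
from .wfpt import DEFAULT_CONFIG, WfptConfig

__all__ = [
    "FitOptions",
    "FitResult",
    "default_bounds",
    "fit_participant",
    "fit_dataset",
    "participant_seed",
]

logger = logging.getLogger(__name__)

MIN_TRIALS = 20

#: Indices of each variant's free parameters within the full 9-vector.
_FULL_INDEX = {name: i for i, name in enumerate(PARAM_ORDER)}


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for per-participant MLE.

    ``bounds`` entries override the per-parameter defaults from
    :func:`default_bounds`; the T0 upper bound is always additionally
    capped at the participant's minimum observed RT (the density has no
    support at RT <= Ter).
    """

    n_starts: int = 10
    seed: int = 0
    tol: float = 1e-8
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    cfg: WfptConfig = DEFAULT_CONFIG

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        for name, (lo, hi) in self.bounds.items():
            if name not in _FULL_INDEX:
                raise ValueError(f"unknown parameter {name!r} in bounds")
            if not lo < hi:
                raise ValueError(f"bounds for {name} are not well-ordered: ({lo}, {hi})")


@dataclass(frozen=True)
class FitResult:
    """Point estimates and metadata for one participant."""

    params: DDMParams
    loglik: float
    n_trials: int
    converged: bool
    n_starts_used: int
    best_start_seed: int


def default_bounds(variant: str, min_rt: float) -> dict[str, tuple[float, float]]:
    """Default box bounds: drift coefficients in [-8, 8], a in [0.1, 5],
    w in [0.05, 0.95], T0 in [0, min observed RT], Tl in [-0.5, 0.5]."""
    b: dict[str, tuple[float, float]] = {
        "v_base": (-8.0, 8.0),
        "v_s": (-8.0, 8.0),
        "v_so": (-8.0, 8.0),
        "a": (0.1, 5.0),
        "w": (0.05, 0.95),
        "T0": (0.0, float(min_rt)),
    }
    if variant == "labels":
        b.update({"v_sl": (-8.0, 8.0), "v_sol": (-8.0, 8.0), "Tl": (-0.5, 0.5)})
    return b


def _trial_arrays(trials: pd.DataFrame):
    responded = trials[trials["responded"].astype(bool)]
    # canonical trial order: the likelihood is a float sum, so fits are
    # bit-identical only under a fixed summation order
    responded = responded.sort_values(
        ["side", "orientation", "label", "choice", "rt_s"], na_position="first"
    )
    S = np.ascontiguousarray(responded["side"].to_numpy(dtype=np.float64))
    O = np.ascontiguousarray(responded["orientation"].to_numpy(dtype=np.float64))
    L = np.ascontiguousarray(responded["label"].fillna(0).to_numpy(dtype=np.float64))
    upper = np.ascontiguousarray((responded["choice"] == "right").to_numpy())
    rt = np.ascontiguousarray(responded["rt_s"].to_numpy(dtype=np.float64))
    return S, O, L, upper, rt


def _expand(x: np.ndarray, free: tuple[str, ...]) -> np.ndarray:
    theta = np.zeros(len(PARAM_ORDER))
    for xi, name in zip(x, free):
        theta[_FULL_INDEX[name]] = xi
    return theta


def _draw_start(rng: np.random.Generator, free: tuple[str, ...], bounds: dict) -> np.ndarray:
    """Jittered initial point in a plausible interior region of the bounds."""
    windows = {
        "v_base": (-1.0, 1.0),
        "v_s": (-2.0, 2.0),
        "v_so": (-1.5, 1.5),
        "v_sl": (-1.5, 1.5),
        "v_sol": (-1.5, 1.5),
        "a": (0.3, 2.0),
        "w": (0.3, 0.7),
        "Tl": (-0.1, 0.1),
    }
    x = np.empty(len(free))
    for i, name in enumerate(free):
        lo, hi = bounds[name]
        if name == "T0":
            wlo, whi = 0.05 * hi, 0.9 * hi
        else:
            wlo, whi = windows[name]
        wlo, whi = max(wlo, lo), min(whi, hi)
        x[i] = rng.uniform(wlo, whi)
    return x


def fit_participant(trials: pd.DataFrame, variant: str, opts: Optional[FitOptions] = None) -> FitResult:
    """Maximum-likelihood fit of one participant's trials.

    Parameters
    ----------
    trials : DataFrame
        Trial table rows for a single participant (trial CSV dialect).
        Non-responded trials are excluded from the likelihood.
    variant : {"control", "labels"}
        Which parameterisation to fit (6 or 9 free parameters).
    opts : FitOptions
        Seeded multi-start settings; defaults to 10 starts.

    Raises
    ------
    ValueError
        On fewer than 20 responded trials, mixed participants, or a
        variant/covariate mismatch.
    """
    if opts is None:
        opts = FitOptions()
    if variant not in ("control", "labels"):
        raise ValueError(f"variant must be 'control' or 'labels', got {variant!r}")
    pids = trials["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError(f"fit_participant expects exactly one participant, got {list(pids)}")
    S, O, L, upper, rt = _trial_arrays(trials)
    if rt.size < MIN_TRIALS:
        raise ValueError(
            f"participant {pids[0]}: only {rt.size} responded trials; "
            f"at least {MIN_TRIALS} are required for a stable fit"
        )
    if variant == "control" and np.any(L != 0):
        raise ValueError("control variant but trial table carries label codes")

    free = CONTROL_FREE_PARAMS if variant == "control" else LABELS_FREE_PARAMS
    # T0 is supported only below the fastest RT at Ter = T0 (i.e. L = 0)
    # trials; valid-label trials constrain T0 + Tl instead, which the
    # density floor handles.
    rt_l0 = rt[L == 0]
    min_rt_l0 = float(rt_l0.min()) if rt_l0.size else float(rt.min())
    bounds = default_bounds(variant, min_rt=min_rt_l0)
    bounds.update(opts.bounds)
    t0_lo, t0_hi = bounds["T0"]
    bounds["T0"] = (t0_lo, min(t0_hi, min_rt_l0))
    box = [bounds[name] for name in free]

    cfg = opts.cfg
    log_floor = math.log(cfg.density_floor)
    i_T0, i_Tl = _FULL_INDEX["T0"], _FULL_INDEX["Tl"]

    def objective(x: np.ndarray) -> float:
        theta = _expand(x, free)
        nll = _kernels.neg_loglik(theta, S, O, L, upper, rt, cfg.err, cfg.t_floor, log_floor)
        viol = -(theta[i_T0] + theta[i_Tl])  # valid-label Ter must stay >= 0
        if viol > 0.0:
            nll += 1e6 * viol * viol
        return nll

    children = np.random.SeedSequence(opts.seed).spawn(opts.n_starts)
    best = None
    best_seed = -1
    any_success = False
    for child in children:
        rng = np.random.default_rng(child)
        x0 = _draw_start(rng, free, bounds)
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=box,
            options={"ftol": opts.tol, "gtol": 1e-6, "maxfun": 20000},
        )
        if not np.isfinite(res.fun):
            continue
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
            best_seed = int(child.generate_state(1)[0] % (2**31))
    if best is None:  # pragma: no cover - requires pathological data
        raise RuntimeError(f"participant {pids[0]}: all optimizer starts failed")

    values = dict(zip(free, best.x))
    params = DDMParams(variant=variant, **values)
    return FitResult(
        params=params,
        loglik=-float(best.fun),
        n_trials=int(rt.size),
        converged=any_success,
        n_starts_used=opts.n_starts,
        best_start_seed=best_seed,
    )


def participant_seed(seed: int, participant_id: str) -> int:
    """Stable per-participant seed, independent of table ordering."""
    return (seed * 1000003 + zlib.crc32(participant_id.encode())) % (2**31)


def fit_dataset(trials: pd.DataFrame, opts: Optional[FitOptions] = None) -> pd.DataFrame:
    """Fit every participant in a trial table; returns a tidy fit table.

    One row per participant (stable, sorted by participant id) with the
    estimates, total log-likelihood and convergence metadata.  Each
    participant gets a seed derived from ``opts.seed`` and their id, so the
    batch result equals per-participant fits run individually with
    :func:`participant_seed` seeds, in any table order.  Failures are
    logged and reported in the ``error`` column rather than raised.
    """
    if opts is None:
        opts = FitOptions()
    if len(trials) == 0:
        raise ValueError("empty trial table")
    rows = []
    for pid, sub in trials.groupby("participant_id", sort=True):
        study = sub["study"].iloc[0]
        variant = variant_for_study(study)
        p_opts = FitOptions(
            n_starts=opts.n_starts,
            seed=participant_seed(opts.seed, str(pid)),
            tol=opts.tol,
            bounds=opts.bounds,
            cfg=opts.cfg,
        )
        row = {"participant_id": str(pid), "study": study, "variant": variant}
        try:
            fit = fit_participant(sub, variant, p_opts)
        except ValueError as exc:
            logger.warning("skipping participant %s: %s", pid, exc)
            row["error"] = str(exc)
            rows.append(row)
            continue
        theta = fit.params.to_full_vector()
        row.update({name: theta[i] for i, name in enumerate(PARAM_ORDER)})
        row.update(
            loglik=fit.loglik,
            n_trials=fit.n_trials,
            converged=fit.converged,
            n_starts_used=fit.n_starts_used,
            error="",
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    n_failed = int((out.get("error", "") != "").sum())
    if n_failed:
        logger.warning("%d of %d participants could not be fit", n_failed, len(out))
    return out
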