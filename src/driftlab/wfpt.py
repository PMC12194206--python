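"""Wiener first-passage-time (WFPT) density and closed-form diffusion summaries.

This module is the numerical core of the package.  It implements the
first-passage-time density of a one-dimensional Wiener diffusion with
constant drift ``v``, absorbing boundaries at ``0`` and ``a``, relative
starting point ``w = z / a`` and unit noise (``s = 1``), using the
small-time / large-time series pair with per-call truncation bounds
(the standard fast evaluation scheme for this density).  On top of the
density it provides the analytic absorption probability, the
unconditional mean decision time (Wald identity), and model-predicted
accuracy / mean-RT summaries for a study condition.

Conventions
-----------
* Ratcliff parameterisation: boundaries at 0 and ``a``, start ``z = w a``,
  noise fixed at ``s = 1`` so the drift rate is a signal-to-noise ratio.
* The *upper* boundary corresponds to a "right" response in the
  behavioral task; the *lower* boundary to "left".
* Densities are in 1/s; times in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

__all__ = [
    "DiffusionSpec",
    "WfptConfig",
    "DEFAULT_CONFIG",
    "wfpt_density",
    "choice_probability",
    "mean_decision_time",
    "predicted_condition_summary",
    "ConditionSummary",
]


@dataclass(frozen=True)
class DiffusionSpec:
    """Parameters of a single Wiener diffusion decision process.

    Attributes
    ----------
    v : float
        Drift rate (evidence/s, signed; positive favors the upper boundary).
    a : float
        Boundary separation (evidence units, > 0).
    w : float
        Relative starting point ``z / a``, strictly between 0 and 1.
    s : float
        Noise scale; fixed at 1 (the model is identified only up to this
        scale, so it is not a free parameter).
    """

    v: float
    a: float
    w: float
    s: float = 1.0

    def __post_init__(self) -> None:
        if not (self.a > 0.0 and math.isfinite(self.a)):
            raise ValueError(f"boundary separation a must be positive, got {self.a}")
        if not (0.0 < self.w < 1.0):
            raise ValueError(f"relative start w must lie in (0, 1), got {self.w}")
        if not math.isfinite(self.v):
            raise ValueError(f"drift rate v must be finite, got {self.v}")
        if self.s != 1.0:
            raise ValueError("noise scale s is fixed at 1")

    @property
    def z(self) -> float:
        """Absolute starting point ``w * a``."""
        return self.w * self.a


@dataclass(frozen=True)
class WfptConfig:
    """Precision controls for the series evaluation of the WFPT density.

    Attributes
    ----------
    err : float
        Absolute truncation tolerance of the density series (default 1e-7).
    t_floor : float
        Smallest decision time evaluated, in seconds; below this the
        likelihood machinery substitutes ``density_floor``.
    density_floor : float
        Floor applied to per-trial likelihoods before taking logs, keeping
        optimizers finite on trials with RT at or below the non-decision
        time.
    """

    err: float = 1e-7
    t_floor: float = 1e-5
    density_floor: float = 1e-10

    def __post_init__(self) -> None:
        if not (0.0 < self.err < 1e-3):
            raise ValueError("err must be positive and below 1e-3")
        if self.t_floor <= 0.0 or self.density_floor <= 0.0:
            raise ValueError("t_floor and density_floor must be positive")


DEFAULT_CONFIG = WfptConfig()


def _f0_small_time(tau: float, w: float, n_terms: int) -> float:
    """Zero-drift unit-boundary density, small-time expansion with
    ``2 * n_terms + 1`` symmetric terms."""
    acc = 0.0
    for k in range(-n_terms, n_terms + 1):
        x = w + 2.0 * k
        acc += x * math.exp(-x * x / (2.0 * tau))
    return acc / math.sqrt(2.0 * math.pi * tau**3)


def _f0_large_time(tau: float, w: float, n_terms: int) -> float:
    """Zero-drift unit-boundary density, large-time (eigenfunction) expansion."""
    acc = 0.0
    for k in range(1, n_terms + 1):
        acc += k * math.exp(-(k * k) * math.pi * math.pi * tau / 2.0) * math.sin(
            k * math.pi * w
        )
    return math.pi * acc


def _series_term_counts(tau: float, err: float) -> tuple[float, float]:
    """Number of terms needed by each expansion for absolute tolerance ``err``.

    Returns ``(k_small, k_large)``; the cheaper branch is the one with the
    smaller count.
    """
    if 2.0 * math.sqrt(2.0 * math.pi * tau) * err < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tau * math.log(2.0 * err * math.sqrt(2.0 * math.pi * tau)))
        ks = max(ks, math.sqrt(tau) + 1.0)
    else:
        ks = 2.0
    if math.pi * tau * err < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tau * err) / (math.pi * math.pi * tau))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(tau)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tau))
    return ks, kl


def wfpt_density(
    t: float,
    spec: DiffusionSpec,
    boundary: str = "lower",
    cfg: Optional[WfptConfig] = None,
    branch: Optional[str] = None,
) -> float:
    """First-passage-time density at decision time ``t`` for one boundary.

    Parameters
    ----------
    t : float
        Decision time in seconds, strictly positive.
    spec : DiffusionSpec
        Diffusion parameters.
    boundary : {"lower", "upper"}
        Which absorbing boundary the density refers to.  The upper-boundary
        density is obtained from the lower one by the reflection
        ``w -> 1 - w``, ``v -> -v``.
    cfg : WfptConfig, optional
        Series precision controls; defaults to :data:`DEFAULT_CONFIG`.
    branch : {"small", "large"}, optional
        Force a specific series expansion (testing hook); by default the
        branch needing fewer terms for tolerance ``cfg.err`` is used.

    Returns
    -------
    float
        Non-negative density in 1/s.
    """
    if cfg is None:
        cfg = DEFAULT_CONFIG
    if not (t > 0.0 and math.isfinite(t)):
        raise ValueError(f"decision time must be positive and finite, got {t}")
    if boundary == "lower":
        v, w = spec.v, spec.w
    elif boundary == "upper":
        v, w = -spec.v, 1.0 - spec.w
    else:
        raise ValueError(f"boundary must be 'lower' or 'upper', got {boundary!r}")

    a = spec.a
    tau = t / (a * a)
    ks, kl = _series_term_counts(tau, cfg.err)
    if branch is None:
        branch = "small" if ks < kl else "large"
    if branch == "small":
        # ks counts total terms of the one-sided truncation; the symmetric
        # sum with ceil(ks/2) wings is at least as accurate.
        f0 = _f0_small_time(tau, w, int(math.ceil(ks / 2.0)) + 1)
    elif branch == "large":
        f0 = _f0_large_time(tau, w, int(math.ceil(kl)))
    else:
        raise ValueError(f"branch must be 'small' or 'large', got {branch!r}")

    log_scale = -v * a * w - v * v * t / 2.0 - 2.0 * math.log(a)
    density = f0 * math.exp(log_scale) if f0 > 0.0 else 0.0
    return max(density, 0.0)


def choice_probability(spec: DiffusionSpec) -> float:
    """Probability that the diffusion is absorbed at the *upper* boundary.

    Uses the closed form ``(1 - exp(-2 v z)) / (1 - exp(-2 v a))`` with
    ``z = w a``, continuous at ``v = 0`` where it equals ``w``.
    """
    v, a, w = spec.v, spec.a, spec.w
    if abs(v) < 1e-10:
        return w
    num = -math.expm1(-2.0 * v * w * a)
    den = -math.expm1(-2.0 * v * a)
    return min(max(num / den, 0.0), 1.0)


def mean_decision_time(spec: DiffusionSpec) -> float:
    """Expected first-passage time in seconds, unconditional on boundary.

    By the Wald identity ``E[DT] = (a P_upper - z) / v`` for nonzero drift;
    for zero drift ``E[DT] = z (a - z)`` (unit noise).
    """
    v, a = spec.v, spec.a
    z = spec.z
    if abs(v) < 1e-6:
        return z * (a - z)
    return (a * choice_probability(spec) - z) / v


class ConditionSummary(NamedTuple):
    """Model-predicted accuracy and mean RT for one study condition."""

    p_correct: float
    mean_rt: float


def predicted_condition_summary(params, S: int, O: int, L: Optional[int] = None) -> ConditionSummary:
    """Analytic accuracy and mean RT predicted for a condition cell.

    The familiar configuration lies on side ``S`` (+1 right, -1 left); a
    response is scored correct when the absorbed boundary matches that side
    (upper = right).  Mean RT is the unconditional mean decision time plus
    the condition's non-decision time, i.e. it pools correct and error
    responses.

    Parameters
    ----------
    params : DDMParams
        Per-participant model parameters (control or labels variant).
    S, O, L : condition codes
        Side (+1/-1), orientation (1 upright / 0 inverted), label validity
        (1 valid / 0 invalid; must be omitted for the control variant).
    """
    from .model import effective_params  # deferred: avoids a module cycle

    tp = effective_params(params, S, O, L)
    spec = DiffusionSpec(v=tp.v, a=tp.a, w=tp.w)
    p_upper = choice_probability(spec)
    p_correct = p_upper if S == 1 else 1.0 - p_upper
    mean_rt = mean_decision_time(spec) + tp.Ter
    return ConditionSummary(p_correct=p_correct, mean_rt=mean_rt)
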