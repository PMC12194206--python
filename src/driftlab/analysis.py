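"""Group-level contrasts and model-fit diagnostics.

Everything downstream of the per-participant fits lives here: condition
drift rates implied by the fitted coefficients, increments of the
labels-present arms over control with t-based confidence intervals, 2x2
mixed ANOVAs (between = study, within = orientation), the fastest-RT
contrast used to corroborate non-decision-time effects, quantile-based
observed-vs-model discrepancy checks, and the observed-vs-predicted
accuracy / mean-RT condition summary.

Condition drift rates toward the correct side follow directly from the
drift equation evaluated at S = +1:

    upright-valid    v_s + v_so + v_sl + v_sol
    inverted-valid   v_s + v_sl
    upright-invalid  v_s + v_so
    inverted-invalid v_s
    control upright  v_s + v_so
    control inverted v_s
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from . import _kernels
from .model import DDMParams, variant_for_study
from .simulate import SIM_DT
from .wfpt import predicted_condition_summary

__all__ = [
    "condition_drifts",
    "condition_increments",
    "mixed_anova_2x2",
    "fastest_rt_contrast",
    "quantile_check",
    "predicted_vs_observed_summary",
    "params_from_fit_row",
    "headline_summary",
]

logger = logging.getLogger(__name__)

_ORIENT_NAME = {1: "upright", 0: "inverted"}


def params_from_fit_row(row: Mapping) -> DDMParams:
    """Rebuild a :class:`DDMParams` from one fit-table row."""
    variant = row.get("variant") or variant_for_study(row["study"])
    kwargs = dict(
        v_base=row["v_base"], v_s=row["v_s"], v_so=row["v_so"],
        a=row["a"], w=row["w"], T0=row["T0"], variant=variant,
    )
    if variant == "labels":
        kwargs.update(v_sl=row["v_sl"], v_sol=row["v_sol"], Tl=row["Tl"])
    return DDMParams(**kwargs)


def _ok_fits(fits: pd.DataFrame) -> pd.DataFrame:
    if "error" in fits.columns:
        fits = fits[fits["error"].fillna("") == ""]
    return fits


def condition_drifts(fits: pd.DataFrame) -> pd.DataFrame:
    """Per-participant drift toward the correct side for each condition cell.

    Returns a long table (participant_id, study, orientation, label, drift);
    ``label`` is NA for control fits.
    """
    fits = _ok_fits(fits)
    rows = []
    for _, row in fits.iterrows():
        variant = row.get("variant") or variant_for_study(row["study"])
        base = {"participant_id": row["participant_id"], "study": row["study"]}
        v_s, v_so = row["v_s"], row["v_so"]
        if variant == "control":
            rows.append({**base, "orientation": 1, "label": pd.NA, "drift": v_s + v_so})
            rows.append({**base, "orientation": 0, "label": pd.NA, "drift": v_s})
        else:
            v_sl, v_sol = row["v_sl"], row["v_sol"]
            rows.append({**base, "orientation": 1, "label": 1, "drift": v_s + v_so + v_sl + v_sol})
            rows.append({**base, "orientation": 0, "label": 1, "drift": v_s + v_sl})
            rows.append({**base, "orientation": 1, "label": 0, "drift": v_s + v_so})
            rows.append({**base, "orientation": 0, "label": 0, "drift": v_s})
    out = pd.DataFrame(rows)
    out["label"] = out["label"].astype("Int64")
    return out


def _two_sample_contrast(x: np.ndarray, y: np.ndarray) -> dict:
    """Pooled-variance two-sample contrast of mean(x) - mean(y) with a
    t-based 95% CI and Cohen's d."""
    nx, ny = len(x), len(y)
    diff = float(np.mean(x) - np.mean(y))
    df = nx + ny - 2
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / df
    se = math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    half = stats.t.ppf(0.975, df) * se
    return {
        "increment": diff,
        "se": se,
        "ci_low": diff - half,
        "ci_high": diff + half,
        "t": t,
        "df": df,
        "p": p,
        "cohens_d": diff / math.sqrt(sp2),
    }


def condition_increments(
    fits_study: pd.DataFrame,
    fits_control: pd.DataFrame,
    label_condition: str = "valid",
) -> pd.DataFrame:
    """Mean condition-drift increment of a labels arm over control, per
    orientation, with a pooled-SE 95% CI and an independent-groups t-test.

    ``label_condition`` selects which label cells of the study arm are
    compared against control ("valid" or "invalid").
    """
    if label_condition not in ("valid", "invalid"):
        raise ValueError(f"label_condition must be 'valid' or 'invalid', got {label_condition!r}")
    fits_study, fits_control = _ok_fits(fits_study), _ok_fits(fits_control)
    if len(fits_study) < 2 or len(fits_control) < 2:
        raise ValueError("need at least 2 participants per group")
    sv = set(fits_study.get("variant", fits_study["study"].map(variant_for_study)))
    cv = set(fits_control.get("variant", fits_control["study"].map(variant_for_study)))
    if sv != {"labels"} or cv != {"control"}:
        raise ValueError(
            f"expected labels-variant study fits vs control-variant fits, got {sv} vs {cv}"
        )
    lab = 1 if label_condition == "valid" else 0
    d_study = condition_drifts(fits_study)
    d_ctrl = condition_drifts(fits_control)
    rows = []
    for orient in (1, 0):
        m_s = (d_study["orientation"] == orient) & (d_study["label"] == lab)
        x = d_study.loc[m_s, "drift"].to_numpy(float)
        y = d_ctrl.loc[d_ctrl["orientation"] == orient, "drift"].to_numpy(float)
        res = _two_sample_contrast(x, y)
        rows.append(
            {
                "orientation": _ORIENT_NAME[orient],
                "label_condition": label_condition,
                "mean_study": float(np.mean(x)),
                "mean_control": float(np.mean(y)),
                "sd_study": float(np.std(x, ddof=1)),
                "sd_control": float(np.std(y, ddof=1)),
                **res,
            }
        )
    return pd.DataFrame(rows)


def mixed_anova_2x2(
    data: pd.DataFrame,
    dv: str = "drift",
    within: str = "orientation",
    between: str = "study",
    subject: str = "participant_id",
) -> pd.DataFrame:
    """2x2 mixed ANOVA (one between factor, one within factor, 2 levels
    each) on a long table; returns F, df, p and partial eta-squared for the
    between main effect, within main effect and interaction.

    Sums of squares are the classical mixed-model partition; with two
    levels per factor and complete cells the usual SS types coincide.
    """
    for col in (dv, within, between, subject):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from ANOVA input")
    if data[within].nunique() != 2 or data[between].nunique() != 2:
        raise ValueError("mixed_anova_2x2 requires exactly 2 levels per factor")
    counts = data.groupby([between, within], observed=True)[dv].count()
    if len(counts) != 4 or counts.min() == 0:
        raise ValueError("missing cells in the 2x2 design")
    wide_check = data.groupby(subject, observed=True)[within].nunique()
    if (wide_check != 2).any():
        raise ValueError("every subject needs both within-factor levels exactly once")

    aov = pg.mixed_anova(
        data=data.astype({within: str}), dv=dv, within=within,
        between=between, subject=subject, correction=False, effsize="np2",
    )
    aov = aov.set_index("Source")
    rows = []
    for effect, source in (
        ("between", between), ("within", within), ("interaction", "Interaction"),
    ):
        r = aov.loc[source]
        rows.append(
            {
                "effect": effect,
                "F": float(r["F"]),
                "df1": int(r["DF1"]),
                "df2": int(r["DF2"]),
                "p": float(r["p_unc"]),
                "np2": float(r["np2"]),
            }
        )
    return pd.DataFrame(rows)


def fastest_rt_contrast(
    trials: pd.DataFrame, fraction: float = 0.20
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Valid-vs-invalid contrast of each participant's fastest RTs.

    For each participant and label condition, the mean of the fastest
    ``ceil(fraction * n)`` responded RTs is computed; the study-level
    summary reports the valid and invalid group means, their difference
    (valid - invalid), and a paired t-test across participants.

    Returns ``(per_participant, summary)``.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    resp = trials[trials["responded"].astype(bool)]
    if resp["label"].isna().any():
        raise ValueError("fastest_rt_contrast requires labels-present data")
    rows = []
    for (pid, study, lab), sub in resp.groupby(
        ["participant_id", "study", "label"], observed=True
    ):
        rts = np.sort(sub["rt_s"].to_numpy(dtype=float))
        k = int(math.ceil(fraction * len(rts)))
        rows.append(
            {
                "participant_id": pid,
                "study": study,
                "label": int(lab),
                "mean_fast_rt": float(rts[:k].mean()),
                "n_used": k,
            }
        )
    per_participant = pd.DataFrame(rows)
    summaries = []
    for study, sub in per_participant.groupby("study", observed=True):
        wide = sub.pivot(index="participant_id", columns="label", values="mean_fast_rt").dropna()
        valid, invalid = wide[1].to_numpy(), wide[0].to_numpy()
        t, p = stats.ttest_rel(valid, invalid)
        summaries.append(
            {
                "study": study,
                "mean_valid": float(valid.mean()),
                "mean_invalid": float(invalid.mean()),
                "difference": float(valid.mean() - invalid.mean()),
                "t": float(t),
                "df": len(wide) - 1,
                "p": float(p),
            }
        )
    return per_participant, pd.DataFrame(summaries)


def _simulate_cell(
    params: DDMParams,
    S_pool: np.ndarray,
    orientation: int,
    label,
    n_sim: int,
    deadline: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated (rt, correct) draws for one condition cell."""
    rng = np.random.default_rng(seed)
    S = rng.choice(S_pool, size=n_sim, replace=True).astype(float)
    L = float(label) if label is not None else 0.0
    theta = params.to_full_vector()
    v = theta[0] + theta[1] * S + theta[2] * S * orientation + theta[3] * S * L + theta[4] * S * orientation * L
    a = np.full(n_sim, params.a)
    w = np.full(n_sim, params.w)
    ter = np.full(n_sim, params.T0 + params.Tl * L)
    choice, rt = _kernels.simulate_batch(v, a, w, ter, deadline, SIM_DT, seed % (2**31))
    ok = choice >= 0
    correct = (choice[ok] == 1) == (S[ok] > 0)
    return rt[ok], correct.astype(float)


def _bin_means(rt: np.ndarray, correct: np.ndarray, n_bins: int):
    """Per-quantile-bin (mean rt, mean accuracy) using rt's own quantiles."""
    edges = np.quantile(rt, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    idx = np.searchsorted(edges, rt, side="right") - 1
    out = []
    for b in range(n_bins):
        m = idx == b
        out.append((float(rt[m].mean()), float(correct[m].mean())) if m.any() else (np.nan, np.nan))
    return out


def quantile_check(
    trials: pd.DataFrame,
    fits: pd.DataFrame,
    n_quantiles: int = 4,
    n_sim: int = 10_000,
    seed: int = 0,
    deadline: float = 4.0,
    flag_z: float = 3.0,
) -> pd.DataFrame:
    """Observed-vs-model RT and accuracy discrepancies per RT quantile bin.

    For every participant and condition cell (orientation, and label where
    present), the participant's observed responded RTs are split at their
    own quantiles, as are trials simulated at that participant's fitted
    parameters (about ``n_sim`` simulated draws per condition across the
    cohort).  Per cell and bin, the participant-level observed bin means
    are compared with the simulated ones by Welch t-tests across
    participants — mirroring how such quantile fit checks are scored on
    real cohorts, with between-participant variability in the denominator.
    A bin is *flagged* when |t| exceeds ``flag_z`` (3 by default, a 3-SE
    criterion).  Participants lacking a cell, or cells with fewer trials
    than ``n_quantiles``, are skipped with a log entry.
    """
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    fits = _ok_fits(fits)
    if len(fits) < 3:
        raise ValueError("quantile_check needs at least 3 fitted participants")
    resp = trials[trials["responded"].astype(bool)]
    has_labels = resp["label"].notna().any()
    group_cols = ["orientation", "label"] if has_labels else ["orientation"]
    n_draws = max(4 * n_quantiles, int(math.ceil(n_sim / len(fits))))

    seeds = np.random.SeedSequence(seed)
    obs_rows, sim_rows = [], []
    for (pid_seed, (_, fit_row)) in zip(seeds.spawn(len(fits)), fits.iterrows()):
        pid = str(fit_row["participant_id"])
        params = params_from_fit_row(fit_row)
        sub_p = resp[resp["participant_id"] == pid]
        if sub_p.empty:
            logger.info("quantile_check: no trials for fitted participant %s", pid)
            continue
        cell_seeds = pid_seed.spawn(8)
        for ci, (key, sub) in enumerate(
            sub_p.groupby(group_cols, observed=True, dropna=False)
        ):
            key = key if isinstance(key, tuple) else (key,)
            orient = int(key[0])
            label = int(key[1]) if has_labels else None
            if len(sub) < n_quantiles:
                logger.info(
                    "quantile_check: participant %s cell %s has only %d trials; skipped",
                    pid, key, len(sub),
                )
                continue
            rt_o = sub["rt_s"].to_numpy(dtype=float)
            cor_o = ((sub["choice"] == "right") == (sub["side"] == 1)).to_numpy(dtype=float)
            cseed = int(cell_seeds[ci].generate_state(1)[0] % (2**31))
            rt_s, cor_s = _simulate_cell(
                params, sub["side"].to_numpy(dtype=float), orient, label,
                n_draws, deadline, cseed,
            )
            if rt_s.size < n_quantiles:
                continue
            for b, (m_rt, m_acc) in enumerate(_bin_means(rt_o, cor_o, n_quantiles)):
                obs_rows.append((orient, label, b, m_rt, m_acc))
            for b, (m_rt, m_acc) in enumerate(_bin_means(rt_s, cor_s, n_quantiles)):
                sim_rows.append((orient, label, b, m_rt, m_acc))

    cols = ["orientation", "label", "bin", "rt", "acc"]
    obs = pd.DataFrame(obs_rows, columns=cols)
    sim = pd.DataFrame(sim_rows, columns=cols)
    rows = []
    for (orient, label, b), obs_cell in obs.groupby(
        ["orientation", "label", "bin"], observed=True, dropna=False
    ):
        sim_cell = sim[
            (sim["orientation"] == orient)
            & (sim["label"].isna() if pd.isna(label) else sim["label"] == label)
            & (sim["bin"] == b)
        ]
        rt_o, rt_s = obs_cell["rt"].dropna(), sim_cell["rt"].dropna()
        ac_o, ac_s = obs_cell["acc"].dropna(), sim_cell["acc"].dropna()
        t_rt, p_rt = stats.ttest_ind(rt_o, rt_s, equal_var=False)
        t_ac, p_ac = stats.ttest_ind(ac_o, ac_s, equal_var=False)
        if not np.isfinite(t_ac):  # e.g. accuracy saturated in both groups
            t_ac, p_ac = 0.0, 1.0
        rows.append(
            {
                "orientation": int(orient),
                "label": label if pd.notna(label) else pd.NA,
                "bin": int(b),
                "n_participants": len(obs_cell),
                "obs_rt": float(rt_o.mean()),
                "sim_rt": float(rt_s.mean()),
                "rt_diff": float(rt_o.mean() - rt_s.mean()),
                "rt_t": float(t_rt),
                "rt_p": float(p_rt),
                "rt_flag": bool(abs(t_rt) > flag_z),
                "obs_acc": float(ac_o.mean()),
                "sim_acc": float(ac_s.mean()),
                "acc_t": float(t_ac),
                "acc_p": float(p_ac),
                "acc_flag": bool(abs(t_ac) > flag_z),
            }
        )
    out = pd.DataFrame(rows).sort_values(["orientation", "label", "bin"]).reset_index(drop=True)
    if not out.empty:
        out["label"] = out["label"].astype("Int64")
    return out


def predicted_vs_observed_summary(
    fits: pd.DataFrame, trials: pd.DataFrame
) -> pd.DataFrame:
    """Observed vs model-predicted accuracy and mean RT per condition cell.

    Observed values are per-participant means over responded trials
    (pooling correct and error RTs), averaged across participants;
    predictions come from the analytic absorption probability and mean
    decision time at each participant's fitted parameters, averaged over
    the left/right side mix.
    """
    fits = _ok_fits(fits)
    resp = trials[trials["responded"].astype(bool)].copy()
    resp["correct"] = (resp["choice"] == "right") == (resp["side"] == 1)
    has_labels = resp["label"].notna().any()
    cell_cols = ["study", "orientation"] + (["label"] if has_labels else [])

    obs = (
        resp.groupby(cell_cols + ["participant_id"], observed=True)
        .agg(acc=("correct", "mean"), rt=("rt_s", "mean"))
        .groupby(cell_cols, observed=True)
        .mean()
        .rename(columns={"acc": "obs_acc", "rt": "obs_rt"})
    )

    pred_rows = []
    for _, row in fits.iterrows():
        params = params_from_fit_row(row)
        orients = (1, 0)
        labels = (1, 0) if params.variant == "labels" else (None,)
        for o in orients:
            for lab in labels:
                acc, rt = 0.0, 0.0
                for S in (1, -1):
                    s = predicted_condition_summary(params, S, o, lab)
                    acc += s.p_correct / 2.0
                    rt += s.mean_rt / 2.0
                rec = {"study": row["study"], "orientation": o, "pred_acc": acc, "pred_rt": rt}
                if has_labels:
                    rec["label"] = lab
                pred_rows.append(rec)
    pred = pd.DataFrame(pred_rows).groupby(cell_cols, observed=True).mean()

    out = obs.join(pred, how="inner").reset_index()
    n_per_cell = resp.groupby(cell_cols, observed=True)["participant_id"].nunique()
    out = out.merge(
        n_per_cell.rename("n_participants").reset_index(), on=cell_cols, how="left"
    )
    return out


def headline_summary(
    fits_by_study: Mapping[str, pd.DataFrame],
    trials_by_study: Optional[Mapping[str, pd.DataFrame]] = None,
) -> dict[str, float]:
    """Group-level summary quantities of a full three-arm analysis.

    Returns mean control condition drifts, valid-label increments over
    control per orientation and study, mean valid-label drifts per study,
    mean thresholds per arm, and (when trial tables are supplied) the
    fastest-20% valid-invalid RT differences.
    """
    out: dict[str, float] = {}
    ctrl = _ok_fits(fits_by_study["control"])
    d_ctrl = condition_drifts(ctrl)
    out["control_drift_upright"] = float(d_ctrl.query("orientation == 1")["drift"].mean())
    out["control_drift_inverted"] = float(d_ctrl.query("orientation == 0")["drift"].mean())
    out["threshold_control"] = float(ctrl["a"].mean())
    for study in ("study1", "study2"):
        if study not in fits_by_study:
            continue
        fits = _ok_fits(fits_by_study[study])
        inc = condition_increments(fits, ctrl, "valid").set_index("orientation")
        out[f"increment_{study}_upright_valid"] = float(inc.loc["upright", "increment"])
        out[f"increment_{study}_inverted_valid"] = float(inc.loc["inverted", "increment"])
        d = condition_drifts(fits)
        valid = d[d["label"] == 1].groupby("participant_id", observed=True)["drift"].mean()
        out[f"valid_drift_{study}"] = float(valid.mean())
        out[f"threshold_{study}"] = float(fits["a"].mean())
        if trials_by_study and study in trials_by_study:
            _, summary = fastest_rt_contrast(trials_by_study[study], 0.20)
            out[f"fastest20_diff_{study}"] = float(
                summary.set_index("study").loc[study, "difference"]
            )
    return out
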