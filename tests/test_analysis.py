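"""Group-level contrasts, ANOVA, fastest-RT and quantile diagnostics."""

import numpy as np
import pandas as pd
import pytest

from conftest import draw_param_table, truth_as_fits
from driftlab.analysis import (
    condition_drifts,
    condition_increments,
    fastest_rt_contrast,
    headline_summary,
    mixed_anova_2x2,
    predicted_vs_observed_summary,
    quantile_check,
)
from driftlab.model import DDMParams
from driftlab.wfpt import predicted_condition_summary


class TestConditionDrifts:
    def test_algebra_is_exact(self):
        rng = np.random.default_rng(0)
        fits = draw_param_table(rng, 5, "study1")
        drifts = condition_drifts(fits).set_index(
            ["participant_id", "orientation", "label"]
        )["drift"]
        for _, row in fits.iterrows():
            pid = row["participant_id"]
            assert drifts[pid, 1, 1] == pytest.approx(
                row["v_s"] + row["v_so"] + row["v_sl"] + row["v_sol"]
            )
            assert drifts[pid, 0, 1] == pytest.approx(row["v_s"] + row["v_sl"])
            assert drifts[pid, 1, 0] == pytest.approx(row["v_s"] + row["v_so"])
            assert drifts[pid, 0, 0] == pytest.approx(row["v_s"])

    def test_control_cells(self):
        rng = np.random.default_rng(1)
        fits = draw_param_table(rng, 3, "control")
        drifts = condition_drifts(fits)
        assert drifts["label"].isna().all()
        up = drifts[drifts["orientation"] == 1].set_index("participant_id")["drift"]
        for _, row in fits.iterrows():
            assert up[row["participant_id"]] == pytest.approx(row["v_s"] + row["v_so"])


class TestConditionIncrements:
    def test_null_increment_near_zero(self):
        """Two groups drawn from the same population differ by ~0."""
        rng = np.random.default_rng(2)
        study = draw_param_table(rng, 60, "study1")
        control = draw_param_table(rng, 60, "control")
        inc = condition_increments(study, control, "invalid")
        # invalid cells share the control drift structure exactly
        assert inc["increment"].abs().max() < 0.3
        assert (inc["p"] > 0.01).all()

    def test_known_shift_recovered_within_ci(self):
        rng = np.random.default_rng(3)
        study = draw_param_table(rng, 80, "study1", shift={"v_sol": 0.1})  # 0.4+0.1
        control = draw_param_table(rng, 80, "control")
        inc = condition_increments(study, control, "valid").set_index("orientation")
        true_up = 0.4 + 0.5  # v_sl + shifted v_sol means
        assert inc.loc["upright", "ci_low"] < true_up < inc.loc["upright", "ci_high"]
        assert inc.loc["inverted", "ci_low"] < 0.4 < inc.loc["inverted", "ci_high"]

    def test_p_value_matches_permutation_oracle(self):
        """The pooled-t p-value agrees with a permutation test."""
        rng = np.random.default_rng(4)
        study = draw_param_table(rng, 12, "study1", shift={"v_sl": 0.2})
        control = draw_param_table(rng, 12, "control")
        inc = condition_increments(study, control, "valid").set_index("orientation")
        x = (study["v_s"] + study["v_so"] + study["v_sl"] + study["v_sol"]).to_numpy()
        y = (control["v_s"] + control["v_so"]).to_numpy()
        obs = x.mean() - y.mean()
        pooled = np.concatenate([x, y])
        count = 0
        n_perm = 20_000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            if abs(pooled[: len(x)].mean() - pooled[len(x):].mean()) >= abs(obs):
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
        p_t = inc.loc["upright", "p"]
        mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p_t - p_perm) < mc_err + 0.01

    def test_ci_width_matches_bootstrap_oracle(self):
        rng = np.random.default_rng(5)
        study = draw_param_table(rng, 40, "study1")
        control = draw_param_table(rng, 40, "control")
        inc = condition_increments(study, control, "valid").set_index("orientation")
        x = (study["v_s"] + study["v_so"] + study["v_sl"] + study["v_sol"]).to_numpy()
        y = (control["v_s"] + control["v_so"]).to_numpy()
        boots = np.array([
            rng.choice(x, len(x)).mean() - rng.choice(y, len(y)).mean()
            for _ in range(5000)
        ])
        width_boot = np.quantile(boots, 0.975) - np.quantile(boots, 0.025)
        width_t = inc.loc["upright", "ci_high"] - inc.loc["upright", "ci_low"]
        assert width_t == pytest.approx(width_boot, rel=0.10)

    def test_refuses_variant_mismatch_and_tiny_groups(self):
        rng = np.random.default_rng(6)
        study = draw_param_table(rng, 5, "study1")
        control = draw_param_table(rng, 5, "control")
        with pytest.raises(ValueError, match="label_condition"):
            condition_increments(study, control, "sometimes")
        with pytest.raises(ValueError, match="variant"):
            condition_increments(control, control)
        with pytest.raises(ValueError, match="2 participants"):
            condition_increments(study.head(1), control)


def drift_long_table(rng, n_per_group, effects):
    """Long-format 2x2 drift table with additive true effects."""
    rows = []
    for g, study in enumerate(["control", "study1"]):
        for i in range(n_per_group):
            pid = f"{study}-{i}"
            subj = rng.normal(0, 0.3)
            for o in (0, 1):
                mu = (
                    effects.get("between", 0) * g
                    + effects.get("within", 0) * o
                    + effects.get("interaction", 0) * g * o
                )
                rows.append({
                    "participant_id": pid, "study": study, "orientation": o,
                    "drift": 0.8 + subj + mu + rng.normal(0, 0.2),
                })
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_matches_hand_computed_sums_of_squares(self):
        """Toy table checked against the classical mixed-model partition
        computed from scratch."""
        data = pd.DataFrame({
            "participant_id": ["a", "a", "b", "b", "c", "c", "d", "d"],
            "study": ["g1", "g1", "g1", "g1", "g2", "g2", "g2", "g2"],
            "orientation": [0, 1] * 4,
            "drift": [1.0, 2.0, 1.5, 2.1, 0.8, 1.1, 1.2, 1.4],
        })
        aov = mixed_anova_2x2(data).set_index("effect")

        y = data.pivot_table(index=["study", "participant_id"],
                             columns="orientation", values="drift")
        groups = y.index.get_level_values("study")
        grand = y.to_numpy().mean()
        n, k = 2, 2  # participants per group, within levels
        subj_mean = y.mean(axis=1)
        group_mean = subj_mean.groupby("study").mean()
        col_mean = y.mean(axis=0)
        cell_mean = y.groupby("study").mean()

        ss_between = k * n * ((group_mean - grand) ** 2).sum()
        ss_subj = k * ((subj_mean - groups.map(group_mean)) ** 2).sum()
        ss_within = 2 * n * ((col_mean - grand) ** 2).sum()
        ss_inter = n * (
            (cell_mean.sub(group_mean, axis=0).sub(col_mean, axis=1) + grand) ** 2
        ).to_numpy().sum()
        # residual: data minus subject and cell structure
        resid = (
            y.sub(subj_mean, axis=0)
            - (cell_mean.loc[groups].to_numpy() - group_mean.loc[groups].to_numpy()[:, None])
        )
        ss_err = (resid.to_numpy() ** 2).sum()

        df_group = 2 * (n - 1)
        assert aov.loc["between", "F"] == pytest.approx(
            ss_between / (ss_subj / df_group), rel=1e-6
        )
        assert aov.loc["between", "df1"] == 1
        assert aov.loc["between", "df2"] == df_group
        assert aov.loc["within", "F"] == pytest.approx(
            ss_within / (ss_err / df_group), rel=1e-6
        )
        assert aov.loc["interaction", "F"] == pytest.approx(
            ss_inter / (ss_err / df_group), rel=1e-6
        )

    def test_partial_eta_squared_relation(self):
        rng = np.random.default_rng(7)
        data = drift_long_table(rng, 20, {"within": 0.3})
        aov = mixed_anova_2x2(data)
        for _, row in aov.iterrows():
            expected = row["F"] * row["df1"] / (row["F"] * row["df1"] + row["df2"])
            assert row["np2"] == pytest.approx(expected, rel=1e-6)

    def test_null_data_rarely_significant(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            aov = mixed_anova_2x2(drift_long_table(rng, 15, {}))
            hits += int((aov["p"] < 0.05).any())
        assert hits <= 3

    def test_injected_within_effect_detected_specifically(self):
        """An orientation-only effect shows up as a within main effect and
        nothing else in the vast majority of seeded runs."""
        within_hits = study_hits = inter_hits = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            aov = mixed_anova_2x2(
                drift_long_table(rng, 30, {"within": 0.4})
            ).set_index("effect")
            within_hits += int(aov.loc["within", "p"] < 0.05)
            study_hits += int(aov.loc["between", "p"] < 0.05)
            inter_hits += int(aov.loc["interaction", "p"] < 0.05)
        assert within_hits >= 9
        assert study_hits <= 2 and inter_hits <= 2

    def test_refuses_bad_designs(self):
        rng = np.random.default_rng(8)
        data = drift_long_table(rng, 5, {})
        with pytest.raises(ValueError, match="column"):
            mixed_anova_2x2(data.drop(columns="drift"))
        with pytest.raises(ValueError, match="2 levels"):
            three = data.copy()
            three.loc[three.index[:2], "study"] = "study2"
            mixed_anova_2x2(three)
        with pytest.raises(ValueError, match="both within-factor levels"):
            mixed_anova_2x2(data.drop(data.index[0]))


class TestFastestRt:
    def test_full_fraction_equals_condition_means(self, labels_cohort):
        trials, _ = labels_cohort
        per_part, _ = fastest_rt_contrast(trials, fraction=1.0)
        resp = trials[trials["responded"]]
        expected = resp.groupby(["participant_id", "label"])["rt_s"].mean()
        for _, row in per_part.iterrows():
            assert row["mean_fast_rt"] == pytest.approx(
                expected[row["participant_id"], row["label"]]
            )

    def test_negative_tl_shows_in_fastest_rts(self):
        from driftlab.simulate import DesignSpec, PopulationSpec, simulate_dataset

        pop = PopulationSpec(
            variant="labels",
            means={"v_sl": 0.0, "v_sol": 0.0, "Tl": -0.05},
            sds={k: 0.0 for k in ("v_base", "v_s", "v_so", "v_sl", "v_sol",
                                  "a", "w", "T0", "Tl")},
            seed=9,
        )
        design = DesignSpec(study="study2", n_participants=6, seed=10)
        trials, _ = simulate_dataset(design, pop)
        _, summary = fastest_rt_contrast(trials, 0.20)
        assert summary["difference"].iloc[0] < 0

    def test_label_permutation_kills_contrast(self, labels_cohort):
        trials, _ = labels_cohort
        rng = np.random.default_rng(11)
        permuted = trials.copy()
        permuted["label"] = (
            permuted.groupby("participant_id")["label"]
            .transform(lambda s: rng.permutation(s.to_numpy()))
        )
        _, summary = fastest_rt_contrast(permuted, 0.20)
        assert abs(summary["t"].iloc[0]) < 3

    def test_domain_checks(self, labels_cohort, control_cohort):
        trials, _ = labels_cohort
        with pytest.raises(ValueError, match="fraction"):
            fastest_rt_contrast(trials, 0.0)
        control_trials, _ = control_cohort
        with pytest.raises(ValueError, match="labels"):
            fastest_rt_contrast(control_trials)


class TestQuantileCheck:
    def test_self_consistency_no_flags(self, control_cohort):
        """Data diagnosed against the parameters that generated them show
        no systematic per-bin discrepancies."""
        trials, truth = control_cohort
        qc = quantile_check(trials, truth_as_fits(truth), seed=12)
        assert len(qc) == 2 * 4
        assert not qc["rt_flag"].any()
        assert not qc["acc_flag"].any()

    def test_median_split_degenerates_gracefully(self, control_cohort):
        trials, truth = control_cohort
        qc = quantile_check(trials, truth_as_fits(truth), n_quantiles=2, seed=13)
        assert sorted(qc["bin"].unique()) == [0, 1]
        assert np.isfinite(qc["rt_t"]).all()

    def test_requires_cohort(self, control_cohort):
        trials, truth = control_cohort
        with pytest.raises(ValueError, match="participants"):
            quantile_check(trials, truth_as_fits(truth).head(2))
        with pytest.raises(ValueError, match="n_quantiles"):
            quantile_check(trials, truth_as_fits(truth), n_quantiles=1)


class TestPredictedVsObserved:
    def test_self_consistency_on_simulated_data(self, labels_cohort):
        trials, truth = labels_cohort
        table = predicted_vs_observed_summary(truth_as_fits(truth), trials)
        assert len(table) == 4
        assert (table["n_participants"] == 10).all()
        # 10 participants x 18 trials per cell: 3-SE bounds on the cell means
        assert (table["obs_acc"] - table["pred_acc"]).abs().max() < 0.12
        assert (table["obs_rt"] - table["pred_rt"]).abs().max() < 0.06

    def test_valid_label_drift_raises_valid_accuracy_only(self):
        base = DDMParams(v_base=0, v_s=0.8, v_so=0.2, a=0.8, w=0.5, T0=0.4,
                         v_sl=0.0, v_sol=0.0, Tl=0.0)
        boosted = DDMParams(v_base=0, v_s=0.8, v_so=0.2, a=0.8, w=0.5, T0=0.4,
                            v_sl=0.5, v_sol=0.0, Tl=0.0)
        for o in (0, 1):
            assert (
                predicted_condition_summary(boosted, 1, o, 1).p_correct
                > predicted_condition_summary(base, 1, o, 1).p_correct
            )
            assert predicted_condition_summary(boosted, 1, o, 0).p_correct == (
                pytest.approx(predicted_condition_summary(base, 1, o, 0).p_correct)
            )

    def test_gaps_shrink_with_more_trials(self):
        """Observed condition means converge on the analytic predictions as
        trials per participant grow."""
        from driftlab.simulate import DesignSpec, PopulationSpec, simulate_dataset

        pop = PopulationSpec(variant="labels", seed=14)
        gaps = []
        for n_trials in (72, 1152):
            design = DesignSpec(study="study1", n_participants=6,
                                trials_per_participant=n_trials, seed=15)
            trials, truth = simulate_dataset(design, pop)
            table = predicted_vs_observed_summary(truth_as_fits(truth), trials)
            gaps.append((table["obs_rt"] - table["pred_rt"]).abs().mean())
        assert gaps[1] < gaps[0]


class TestHeadlineSummary:
    def test_reports_full_set_of_quantities(self, labels_cohort, control_cohort):
        trials_l, truth_l = labels_cohort
        trials_c, truth_c = control_cohort
        out = headline_summary(
            {"control": truth_as_fits(truth_c), "study1": truth_as_fits(truth_l)},
            {"study1": trials_l},
        )
        for key in (
            "control_drift_upright", "control_drift_inverted", "threshold_control",
            "increment_study1_upright_valid", "increment_study1_inverted_valid",
            "valid_drift_study1", "threshold_study1", "fastest20_diff_study1",
        ):
            assert key in out and np.isfinite(out[key])
        assert out["control_drift_upright"] == pytest.approx(
            (truth_c["v_s"] + truth_c["v_so"]).mean()
        )
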