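import numpy as np
import pandas as pd
import pytest

from tempomem import (
    assumption_checks,
    correct_counts,
    fit_response_line,
    mixed_anova_2x2,
    score_trials,
    summarize_groups,
)


def _all_correct_cohort(scale):
    rows = []
    for group in ("musician", "non_musician"):
        for i in range(3):
            pid = f"{group}_{i}"
            for lab in range(1, 8):
                rows.append(dict(participant_id=pid, group=group,
                                 task="identification", trial_index=lab,
                                 target_label=lab, response_label=lab))
                rows.append(dict(participant_id=pid, group=group,
                                 task="production", trial_index=lab,
                                 target_label=lab,
                                 response_bpm=scale.label_to_bpm(lab)))
    return pd.DataFrame(rows)


class TestSummarizeGroups:
    def test_all_correct_cohort_is_100_percent_sd_zero(self, scale):
        scored = score_trials(_all_correct_cohort(scale), scale)
        table = summarize_groups(scored).table
        assert np.allclose(table["pct_correct_mean"], 100.0)
        assert np.allclose(table["pct_correct_sd"], 0.0)
        assert np.allclose(table["error_mean"], 0.0)

    def test_percentages_equal_mean_count_over_trials(self, scored_cohort):
        table = summarize_groups(scored_cohort).table
        counts = correct_counts(scored_cohort)
        for _, row in table.iterrows():
            col = f"n_correct_{row['task']}"
            cell = counts[counts["group"] == row["group"]][col]
            assert row["pct_correct_mean"] == pytest.approx(
                100.0 * cell.mean() / 7, rel=1e-12
            )

    def test_cell_shape_for_reference_design(self, scored_cohort):
        table = summarize_groups(scored_cohort).table
        assert len(table) == 4
        assert set(table["n_participants"]) == {15}
        assert ((table["pct_correct_mean"] >= 0) & (table["pct_correct_mean"] <= 100)).all()


class TestFitResponseLine:
    def test_perfect_identity_data(self, scale):
        scored = score_trials(_all_correct_cohort(scale), scale)
        fit = fit_response_line(scored, task="production")
        assert fit.slope == pytest.approx(1.0, abs=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-6)
        assert fit.pearson_r == pytest.approx(1.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        # six points; oracle written out from the closed-form normal equations
        x = np.array([71.0, 80.0, 90.0, 101.0, 113.0, 127.0])
        y = np.array([75.0, 78.0, 95.0, 99.0, 120.0, 121.0])
        n = len(x)
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - (intercept + slope * x)
        s2 = np.sum(resid**2) / (n - 2)
        slope_se = np.sqrt(s2 / sxx)
        intercept_se = np.sqrt(s2 * (1 / n + x.mean() ** 2 / sxx))
        r = sxy / np.sqrt(sxx * np.sum((y - y.mean()) ** 2))

        df = pd.DataFrame(dict(participant_id="p", group="g", task="production",
                               target_bpm=x, response_bpm=y))
        fit = fit_response_line(df)
        assert fit.slope == pytest.approx(slope, rel=1e-12)
        assert fit.intercept == pytest.approx(intercept, rel=1e-12)
        assert fit.slope_se == pytest.approx(slope_se, rel=1e-12)
        assert fit.intercept_se == pytest.approx(intercept_se, rel=1e-12)
        assert fit.pearson_r == pytest.approx(r, rel=1e-12)
        assert fit.n == 6

    def test_degenerate_inputs_rejected(self):
        df = pd.DataFrame(dict(participant_id="p", group="g", task="production",
                               target_bpm=[101.0] * 5, response_bpm=np.arange(5) + 90.0))
        with pytest.raises(ValueError, match="constant target"):
            fit_response_line(df)
        with pytest.raises(ValueError, match=">= 3 points"):
            fit_response_line(df.iloc[:2])


def _long_scores(scores_by_subject):
    rows = []
    for (pid, group), (s_id, s_prod) in scores_by_subject.items():
        rows.append(dict(participant_id=pid, group=group, task="identification",
                         score=s_id))
        rows.append(dict(participant_id=pid, group=group, task="production",
                         score=s_prod))
    return pd.DataFrame(rows)


class TestMixedAnova:
    # hand-computed split-plot decomposition for 2 subjects per group:
    # scores (task1, task2): A1 (4,2), A2 (6,2), B1 (3,1), B2 (5,3)
    FIXTURE = {
        ("A1", "A"): (4.0, 2.0),
        ("A2", "A"): (6.0, 2.0),
        ("B1", "B"): (3.0, 1.0),
        ("B2", "B"): (5.0, 3.0),
    }

    def test_fixture_matches_hand_computed_ss(self):
        res = mixed_anova_2x2(_long_scores(self.FIXTURE))
        assert res.ss["total"] == pytest.approx(19.5, abs=1e-12)
        assert res.ss["training"] == pytest.approx(0.5, abs=1e-12)
        assert res.ss["subjects_within_groups"] == pytest.approx(5.0, abs=1e-12)
        assert res.ss["task"] == pytest.approx(12.5, abs=1e-12)
        assert res.ss["interaction"] == pytest.approx(0.5, abs=1e-12)
        assert res.ss["task_x_subjects"] == pytest.approx(1.0, abs=1e-12)
        assert res.F["training"] == pytest.approx(0.2, abs=1e-12)
        assert res.F["task"] == pytest.approx(25.0, abs=1e-12)
        assert res.F["interaction"] == pytest.approx(1.0, abs=1e-12)
        assert res.df["task_x_subjects"] == 2

    def test_matches_pingouin_on_simulated_cohort(self, scored_cohort):
        pingouin = pytest.importorskip("pingouin")
        counts = correct_counts(scored_cohort)
        long = counts.melt(
            id_vars=["participant_id", "group"],
            value_vars=["n_correct_identification", "n_correct_production"],
            var_name="task", value_name="score",
        )
        long["task"] = long["task"].str.replace("n_correct_", "", regex=False)
        res = mixed_anova_2x2(long)
        pg = pingouin.mixed_anova(
            data=long, dv="score", within="task", between="group",
            subject="participant_id",
        ).set_index("Source")
        assert res.F["training"] == pytest.approx(pg.loc["group", "F"], rel=1e-9)
        assert res.F["task"] == pytest.approx(pg.loc["task", "F"], rel=1e-9)
        assert res.F["interaction"] == pytest.approx(pg.loc["Interaction", "F"], rel=1e-9)
        assert res.p["task"] == pytest.approx(pg.loc["task", "p_unc"], rel=1e-9)

    def test_all_equal_scores_give_zero_f(self):
        scores = {(f"s{i}", "A" if i < 3 else "B"): (5.0, 5.0) for i in range(6)}
        res = mixed_anova_2x2(_long_scores(scores))
        assert res.F["training"] == 0.0
        assert res.F["task"] == 0.0
        assert res.F["interaction"] == 0.0

    def test_ss_decomposition_sums_to_total(self, scored_cohort):
        counts = correct_counts(scored_cohort)
        long = counts.melt(
            id_vars=["participant_id", "group"],
            value_vars=["n_correct_identification", "n_correct_production"],
            var_name="task", value_name="score",
        )
        long["task"] = long["task"].str.replace("n_correct_", "", regex=False)
        res = mixed_anova_2x2(long)
        parts = (
            res.ss["training"] + res.ss["subjects_within_groups"]
            + res.ss["task"] + res.ss["interaction"] + res.ss["task_x_subjects"]
        )
        assert parts == pytest.approx(res.ss["total"], rel=1e-9)
        assert res.df["subjects_within_groups"] == 28

    def test_permuting_rows_leaves_statistics_unchanged(self):
        df = _long_scores(self.FIXTURE)
        shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert mixed_anova_2x2(df) == mixed_anova_2x2(shuffled)

    def test_unbalanced_design_refused(self):
        df = _long_scores(self.FIXTURE).iloc[:-1]  # drop one task score
        with pytest.raises(ValueError, match="unbalanced"):
            mixed_anova_2x2(df)

    def test_unequal_group_sizes_refused(self):
        scores = dict(self.FIXTURE)
        scores[("A3", "A")] = (4.0, 4.0)
        with pytest.raises(ValueError, match="unbalanced"):
            mixed_anova_2x2(_long_scores(scores))


def test_assumption_checks_report_scipy_diagnostics():
    rng = np.random.default_rng(4)
    rows = []
    for g in ("A", "B"):
        for i in range(10):
            for task in ("identification", "production"):
                rows.append(dict(participant_id=f"{g}{i}", group=g, task=task,
                                 score=float(rng.normal(3, 1))))
    out = assumption_checks(pd.DataFrame(rows))
    assert set(out) == {"shapiro_W", "shapiro_p", "bartlett_chi_sq", "bartlett_p"}
    assert 0 <= out["shapiro_p"] <= 1
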