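"""Group-level summaries: accuracy tables, response-target fits, mixed ANOVA.

The design is a balanced 2x2 split plot: training group (e.g. musicians vs
non-musicians) between participants, task (identification vs production)
within participants, with the per-participant number of correct responses
per task as the dependent variable. The between factor is tested against
the subjects-within-groups mean square, the within factor and the
interaction against the task-by-subjects mean square, each on (1, N-2)
degrees of freedom for two groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "RegressionFit",
    "MixedAnovaResult",
    "summarize_groups",
    "fit_response_line",
    "mixed_anova_2x2",
    "assumption_checks",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-cell (group x task) accuracy and error summaries.

    ``table`` has one row per (group, task) with the mean and SD, across
    participants, of the percent of correct responses and of the mean
    signed error in semitempi.
    """

    table: pd.DataFrame
    trials_per_task: int


def summarize_groups(scored: pd.DataFrame, trials_per_task: int = 7) -> GroupSummary:
    """Percent-correct and mean-error table by group and task.

    Each participant contributes one percent-correct value
    (100 * correct count / trials) and one mean signed error per task; the
    table reports the mean and SD of those values across the participants
    in each cell. Empty cells are absent from the table.
    """
    ok = scored.dropna(subset=["correct"])
    per_part = (
        ok.groupby(["group", "task", "participant_id"], sort=False)
        .agg(
            n_correct=("correct", "sum"),
            mean_error=("error_semitempi", "mean"),
        )
        .reset_index()
    )
    per_part["pct_correct"] = 100.0 * per_part["n_correct"] / trials_per_task
    table = (
        per_part.groupby(["group", "task"], sort=True)
        .agg(
            pct_correct_mean=("pct_correct", "mean"),
            pct_correct_sd=("pct_correct", lambda s: s.std(ddof=1)),
            error_mean=("mean_error", "mean"),
            error_sd=("mean_error", lambda s: s.std(ddof=1)),
            n_participants=("participant_id", "nunique"),
        )
        .reset_index()
    )
    return GroupSummary(table=table, trials_per_task=trials_per_task)


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of response bpm on target bpm, with Pearson r."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    pearson_r: float
    n: int


def fit_response_line(
    scored: pd.DataFrame,
    group: str | None = None,
    task: str | None = None,
) -> RegressionFit:
    """Ordinary least squares of response bpm on target bpm.

    Standard errors use the usual residual-variance formula (n - 2 df).
    Raises on fewer than 3 usable points or a constant target.
    """
    df = scored
    if group is not None:
        df = df[df["group"] == group]
    if task is not None:
        df = df[df["task"] == task]
    df = df.dropna(subset=["target_bpm", "response_bpm"])
    if len(df) < 3:
        raise ValueError(f"need >= 3 points, got {len(df)}")
    x = df["target_bpm"].to_numpy(dtype=float)
    y = df["response_bpm"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant target bpm: slope undefined")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        pearson_r=float(res.rvalue),
        n=len(df),
    )


@dataclass(frozen=True)
class MixedAnovaResult:
    """Split-plot ANOVA table for the 2 (group) x 2 (task) design."""

    ss: dict[str, float]
    df: dict[str, int]
    F: dict[str, float]
    p: dict[str, float]
    partial_eta_sq: dict[str, float]


def mixed_anova_2x2(scores: pd.DataFrame) -> MixedAnovaResult:
    """Balanced split-plot ANOVA with one between and one within factor.

    Parameters
    ----------
    scores:
        Long table with columns ``participant_id``, ``group``, ``task`` and
        ``score`` (one row per participant per task). Exactly two groups of
        equal size and two tasks; every participant must have one score per
        task, otherwise the input is refused.

    Effects are keyed ``'training'`` (between), ``'task'`` (within) and
    ``'interaction'``; error strata are ``'subjects_within_groups'`` and
    ``'task_x_subjects'``. Partial eta squared divides each effect's SS by
    itself plus its own error SS.
    """
    required = {"participant_id", "group", "task", "score"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    groups = sorted(scores["group"].unique())
    tasks = sorted(scores["task"].unique())
    if len(groups) != 2 or len(tasks) != 2:
        raise ValueError("design must have exactly 2 groups and 2 tasks")
    wide = scores.pivot_table(
        index=["group", "participant_id"], columns="task", values="score",
        aggfunc="first",
    )
    if wide.isna().any().any():
        raise ValueError("unbalanced design: every participant needs one score per task")
    sizes = wide.groupby(level="group").size()
    if sizes.nunique() != 1:
        raise ValueError("unbalanced design: groups must have equal size")

    y = wide.to_numpy(dtype=float)          # (subjects, tasks)
    n_subj, n_task = y.shape
    n_per_group = n_subj // 2
    grand = y.mean()

    subj_means = y.mean(axis=1)
    group_of = wide.index.get_level_values("group").to_numpy()
    group_means = np.array([y[group_of == g].mean() for g in groups])
    task_means = y.mean(axis=0)
    cell_means = np.array([[y[group_of == g][:, t].mean() for t in range(n_task)]
                           for g in groups])

    ss_total = float(((y - grand) ** 2).sum())
    ss_between_subj = float(n_task * ((subj_means - grand) ** 2).sum())
    ss_training = float(n_per_group * n_task * ((group_means - grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_training
    ss_task = float(n_subj * ((task_means - grand) ** 2).sum())
    ss_cells = float(n_per_group * ((cell_means - grand) ** 2).sum())
    ss_interaction = ss_cells - ss_training - ss_task
    ss_task_x_subj = ss_total - ss_between_subj - ss_task - ss_interaction

    df_effect = 1
    df_subj_within = n_subj - 2
    df_task_x_subj = n_subj - 2

    ms_subj_within = ss_subj_within / df_subj_within
    ms_task_x_subj = ss_task_x_subj / df_task_x_subj

    def f_and_p(ss_eff: float, ms_err: float, df_err: int) -> tuple[float, float]:
        f = (ss_eff / df_effect) / ms_err if ms_err > 0 else (
            0.0 if ss_eff == 0 else float("inf"))
        p = float(stats.f.sf(f, df_effect, df_err)) if np.isfinite(f) else 0.0
        return float(f), p

    F_training, p_training = f_and_p(ss_training, ms_subj_within, df_subj_within)
    F_task, p_task = f_and_p(ss_task, ms_task_x_subj, df_task_x_subj)
    F_inter, p_inter = f_and_p(ss_interaction, ms_task_x_subj, df_task_x_subj)

    def peta(ss_eff: float, ss_err: float) -> float:
        denom = ss_eff + ss_err
        return float(ss_eff / denom) if denom > 0 else 0.0

    return MixedAnovaResult(
        ss={
            "training": ss_training,
            "subjects_within_groups": ss_subj_within,
            "task": ss_task,
            "interaction": ss_interaction,
            "task_x_subjects": ss_task_x_subj,
            "total": ss_total,
        },
        df={
            "training": df_effect,
            "subjects_within_groups": df_subj_within,
            "task": df_effect,
            "interaction": df_effect,
            "task_x_subjects": df_task_x_subj,
        },
        F={"training": F_training, "task": F_task, "interaction": F_inter},
        p={"training": p_training, "task": p_task, "interaction": p_inter},
        partial_eta_sq={
            "training": peta(ss_training, ss_subj_within),
            "task": peta(ss_task, ss_task_x_subj),
            "interaction": peta(ss_interaction, ss_task_x_subj),
        },
    )


def assumption_checks(scores: pd.DataFrame) -> dict[str, float]:
    """Descriptive normality and homoskedasticity diagnostics.

    Shapiro-Wilk on cell-centred residuals and Bartlett's test across the
    two groups' per-participant mean scores, via the standard scipy
    implementations. Reported descriptively alongside the ANOVA.
    """
    resid = (
        scores["score"]
        - scores.groupby(["group", "task"])["score"].transform("mean")
    ).to_numpy(dtype=float)
    w, p_shapiro = stats.shapiro(resid)
    by_group = [
        g["score"].groupby(g["participant_id"]).mean().to_numpy()
        for _, g in scores.groupby("group")
    ]
    chi, p_bartlett = stats.bartlett(*by_group)
    return {
        "shapiro_W": float(w),
        "shapiro_p": float(p_shapiro),
        "bartlett_chi_sq": float(chi),
        "bartlett_p": float(p_bartlett),
    }
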