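"""Trial-table I/O, pipeline configuration and the end-to-end run.

Trial tables are delimited text (comma or tab) with columns
``participant_id, group, task, trial_index, target_label`` plus a response:
``response_label`` (identification), ``response_bpm`` or ``onsets_file``
(production). Tap trains are one CSV (single ``onset_s`` column) or JSON
(flat list of seconds) file per trial. Spreadsheet input (.xlsx) is
supported through a user-supplied column map, since deposited sheets vary
in layout.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .tempo_scale import (
    ExperimentalScale,
    build_semitempo_series,
    select_experimental_scale,
)
from .tap_metrics import score_trials, correct_counts
from .chance_models import (
    binomial_tail,
    select_threshold,
    permutation_null,
    uniform_range_null,
    classify_cohort,
    IDENTIFICATION_GUESS_P,
)
from .serial_position import counts_by_position, central_contrast, bow_index
from .group_stats import summarize_groups, fit_response_line, mixed_anova_2x2

__all__ = [
    "REQUIRED_COLUMNS",
    "PipelineConfig",
    "read_trials",
    "write_trials",
    "read_tap_train",
    "run_pipeline",
    "write_report",
]

REQUIRED_COLUMNS = ("participant_id", "group", "task", "trial_index", "target_label")
OPTIONAL_COLUMNS = ("response_label", "response_bpm", "onsets_file")

REPORT_SCHEMA_VERSION = "1"


def _validate_row(row: pd.Series, n_labels: int) -> str | None:
    """Return a diagnostic string for a bad row, or None if the row is valid."""
    task = row.get("task")
    if task not in ("identification", "production"):
        return f"unknown task {task!r}"
    try:
        lab = int(row["target_label"])
    except (TypeError, ValueError):
        return f"non-integer target_label {row['target_label']!r}"
    if not 1 <= lab <= n_labels:
        return f"target_label {lab} outside 1..{n_labels}"
    resp_lab = row.get("response_label")
    has_resp_lab = resp_lab is not None and not (
        isinstance(resp_lab, float) and math.isnan(resp_lab)
    )
    if has_resp_lab and not 1 <= int(resp_lab) <= n_labels:
        return f"response_label {resp_lab} outside 1..{n_labels}"
    resp_bpm = row.get("response_bpm")
    has_resp_bpm = resp_bpm is not None and not (
        isinstance(resp_bpm, float) and math.isnan(resp_bpm)
    )
    if has_resp_bpm and float(resp_bpm) <= 0:
        return f"non-positive response_bpm {resp_bpm}"
    onsets_file = row.get("onsets_file")
    has_onsets = isinstance(onsets_file, str) and onsets_file.strip() != ""
    if task == "identification" and not has_resp_lab:
        return "identification row without response_label"
    if task == "production" and not (has_resp_bpm or has_onsets):
        return "production row without response_bpm or onsets_file"
    return None


def read_trials(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    n_labels: int = 7,
    load_onsets: bool = True,
) -> pd.DataFrame:
    """Read and validate a trial table from delimited text (or .xlsx).

    ``column_map`` maps file column names to the canonical names; it is
    mandatory when the file does not already use the canonical header.
    Rows failing validation are dropped and reported, with the reason, in
    ``result.attrs['row_errors']``. When ``load_onsets`` is true, rows with
    an ``onsets_file`` get an ``onsets`` column loaded from the referenced
    file (relative to the table's directory).
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep=None, engine="python")
    if column_map:
        df = df.rename(columns=column_map)
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing mandatory columns: {sorted(missing)}")

    row_errors: list[dict] = []
    keep = np.ones(len(df), dtype=bool)
    for pos, (idx, row) in enumerate(df.iterrows()):
        reason = _validate_row(row, n_labels)
        if reason is not None:
            row_errors.append({"index": idx, "reason": reason})
            keep[pos] = False
    out = df[keep].copy()
    out["target_label"] = out["target_label"].astype(int)
    if load_onsets and "onsets_file" in out.columns:
        onsets = []
        for f in out["onsets_file"]:
            if isinstance(f, str) and f.strip():
                onsets.append(read_tap_train(path.parent / f))
            else:
                onsets.append(None)
        out["onsets"] = onsets
    out.attrs["row_errors"] = row_errors
    return out


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as CSV (bpm at full double precision)."""
    cols = [c for c in trials.columns if c != "onsets"]
    trials[cols].to_csv(path, index=False, float_format="%.15g")


def read_tap_train(path: str | Path) -> list[float]:
    """Load tap onsets (seconds) from a one-column CSV or a JSON list."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return [float(x) for x in data]
    df = pd.read_csv(path)
    col = "onset_s" if "onset_s" in df.columns else df.columns[0]
    return [float(x) for x in df[col]]


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration echoed into every report."""

    seed: int
    scale_base_bpm: float = 40.0
    scale_n_steps: int = 37
    scale_start_index: int = 10
    scale_stride: int = 2
    scale_count: int = 7
    clip_duration_s: float = 10.0
    band_semitempi: float = 1.0
    alpha: float = 0.05
    permutation_cycles: int = 100
    # adopted classification thresholds (both null models' raw thresholds
    # are reported alongside)
    t_identification: int = 4
    t_production: int = 3
    uniform_range_bpm: tuple[float, float] = (23.0, 233.0)
    uniform_band_bpm: tuple[float, float] = (67.0, 150.4)

    def scale(self) -> ExperimentalScale:
        series = build_semitempo_series(self.scale_base_bpm, self.scale_n_steps)
        return select_experimental_scale(
            series,
            self.scale_start_index,
            self.scale_stride,
            self.scale_count,
            self.clip_duration_s,
        )


def _positions_section(scored: pd.DataFrame, task: str) -> dict[str, Any]:
    sub = scored[scored["task"] == task]
    if sub.empty:
        return {"available": False}
    pc = counts_by_position(sub, task=task)
    section: dict[str, Any] = {
        "available": True,
        "correct_by_position": list(pc.correct),
        "n_per_position": pc.n_per_position,
        "bow_index": bow_index(pc),
    }
    try:
        cc = central_contrast(pc)
        section["central_contrast"] = {
            "table": [list(r) for r in cc.table],
            "chi_sq": cc.chi_sq,
            "df": cc.df,
            "p_value": cc.p_value,
            "phi": cc.phi,
        }
    except ValueError as exc:
        section["central_contrast"] = {"undefined": str(exc)}
    return section


def run_pipeline(trials: pd.DataFrame, config: PipelineConfig) -> dict[str, Any]:
    """Score trials and run every analysis stage; return the report bundle.

    Stages: scoring -> chance thresholds (binomial, permutation, analytic)
    -> participant classification -> serial-position contrasts -> group
    summaries, regression fits and the mixed ANOVA. Stage timings and all
    seeds are recorded in the report.
    """
    t0 = time.perf_counter()
    timings: dict[str, float] = {}
    scale = config.scale()

    scored = score_trials(trials, scale, band_semitempi=config.band_semitempi)
    timings["score"] = time.perf_counter() - t0

    n_trials = config.scale_count
    id_tail = binomial_tail(n_trials, IDENTIFICATION_GUESS_P)
    id_thr = select_threshold(n_trials, IDENTIFICATION_GUESS_P, config.alpha)

    prod = scored[scored["task"] == "production"]
    thresholds: dict[str, Any] = {
        "identification": {
            "p_chance": IDENTIFICATION_GUESS_P,
            "tail": list(id_tail.tail),
            "T": id_thr.T,
        },
    }
    if not prod.dropna(subset=["response_bpm"]).empty:
        t1 = time.perf_counter()
        perm = permutation_null(
            prod,
            n_cycles=config.permutation_cycles,
            seed=config.seed,
            band_semitempi=config.band_semitempi,
        )
        timings["permutation_null"] = time.perf_counter() - t1
        perm_thr = select_threshold(n_trials, perm.p_hat, config.alpha)
        analytic = uniform_range_null(
            *config.uniform_range_bpm, *config.uniform_band_bpm, n_trials
        )
        analytic_thr = select_threshold(n_trials, analytic.p, config.alpha)
        thresholds["production"] = {
            "permutation": {
                "n_cycles": perm.n_cycles,
                "seed": perm.seed,
                "n_assignments": perm.n_assignments,
                "n_correct": perm.n_correct,
                "p_hat": perm.p_hat,
                "T": perm_thr.T,
                "tail": list(binomial_tail(n_trials, perm.p_hat).tail),
            },
            "uniform_range": {
                "range_bpm": list(config.uniform_range_bpm),
                "band_bpm": list(config.uniform_band_bpm),
                "p1": analytic.p1,
                "p2": analytic.p2,
                "p": analytic.p,
                "T": analytic_thr.T,
                "tail": list(binomial_tail(n_trials, analytic.p).tail),
            },
        }
    thresholds["adopted"] = {
        "T_identification": config.t_identification,
        "T_production": config.t_production,
    }

    classes = classify_cohort(
        scored, T_id=config.t_identification, T_prod=config.t_production
    )
    quadrants = classes["participant_class"].value_counts().to_dict()

    serial = {
        task: _positions_section(scored, task)
        for task in ("identification", "production")
    }

    summary = summarize_groups(scored, trials_per_task=n_trials)
    fits = {}
    for group in sorted(scored["group"].dropna().unique()):
        for task in ("identification", "production"):
            try:
                fit = fit_response_line(scored, group=group, task=task)
                fits[f"{group}/{task}"] = asdict(fit)
            except ValueError as exc:
                fits[f"{group}/{task}"] = {"undefined": str(exc)}

    counts = correct_counts(scored)
    anova_section: dict[str, Any]
    try:
        long = counts.melt(
            id_vars=["participant_id", "group"],
            value_vars=["n_correct_identification", "n_correct_production"],
            var_name="task",
            value_name="score",
        )
        long["task"] = long["task"].str.replace("n_correct_", "", regex=False)
        res = mixed_anova_2x2(long)
        anova_section = {
            "ss": res.ss,
            "df": res.df,
            "F": res.F,
            "p": res.p,
            "partial_eta_sq": res.partial_eta_sq,
        }
    except ValueError as exc:
        anova_section = {"undefined": str(exc)}

    timings["total"] = time.perf_counter() - t0
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "config": asdict(config),
        "scale": scale.to_dict(),
        "n_trials_scored": int(scored["correct"].notna().sum()),
        "row_errors": scored.attrs.get("row_errors", []),
        "thresholds": thresholds,
        "classification": {
            "per_participant": classes.to_dict(orient="records"),
            "quadrant_counts": {k: int(v) for k, v in quadrants.items()},
        },
        "serial_position": serial,
        "group_summary": summary.table.to_dict(orient="records"),
        "regression_fits": fits,
        "mixed_anova": anova_section,
        "timings_s": timings,
    }


def _json_default(o: Any):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def write_report(report: dict[str, Any], path: str | Path) -> None:
    """Write a report bundle as JSON."""
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default) + "\n")
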