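"""Tap-train tempo estimation and semitempo error scoring.

Produced tempo is estimated from tap onsets by discarding the first and
last tap (attack and release artefacts) and counting inter-onset intervals
in the remaining window: ``bpm = 60 * (k - 1) / window`` for ``k`` retained
onsets. Errors are expressed in semitempo units, the signed log-ratio
``12 * log2(response / target)``; a response within +/- 1 semitempo
(a +/- ~6% bpm shift) counts as a correct production, the band matching the
one-semitone criterion of absolute-pitch studies. Identification responses
are correct only on an exact label match; their error in semitempo units is
twice the label distance, since adjacent scale tempi sit two semitempi apart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .tempo_scale import ExperimentalScale

__all__ = [
    "TapTrain",
    "InsufficientDataError",
    "produced_bpm",
    "semitempo_error",
    "identification_error",
    "is_correct_production",
    "score_trials",
    "DEFAULT_BAND_SEMITEMPI",
    "BAND_TOL",
]

#: half-width of the production correctness band, in semitempi
DEFAULT_BAND_SEMITEMPI: float = 1.0
#: absolute tolerance on the band comparison, so boundary trials do not
#: flip on floating-point representation noise
BAND_TOL: float = 1e-9

#: trials per task per participant in the reference design
TRIALS_PER_TASK: int = 7


class InsufficientDataError(ValueError):
    """A tap train too short for tempo estimation (fewer than 4 onsets)."""


@dataclass(frozen=True)
class TapTrain:
    """One production trial's tap onsets, in seconds, strictly increasing."""

    onsets_s: tuple[float, ...]
    participant_id: str | None = None
    trial_index: int | None = None
    target_label: int | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.onsets_s, dtype=float)
        if arr.ndim != 1:
            raise ValueError("onsets_s must be a flat sequence")
        if arr.size >= 2 and not np.all(np.diff(arr) > 0):
            raise ValueError("onsets_s must be strictly increasing")

    @property
    def bpm(self) -> float:
        return produced_bpm(self.onsets_s)


def produced_bpm(onsets_s: Sequence[float]) -> float:
    """Estimate the produced tempo (bpm) from a train of tap onsets.

    The first and last onsets are discarded; the tempo is the number of
    inter-onset intervals between the remaining onsets divided by the time
    window they span, scaled to beats per minute. A perfectly periodic train
    of IOI ``d`` seconds therefore returns exactly ``60 / d``.

    Raises
    ------
    InsufficientDataError
        if fewer than 4 onsets are supplied (trimming must leave at least
        one interval).
    ValueError
        if the onsets are not strictly increasing.
    """
    arr = np.asarray(onsets_s, dtype=float)
    if arr.size < 4:
        raise InsufficientDataError(
            f"need >= 4 onsets to estimate tempo, got {arr.size}"
        )
    if not np.all(np.diff(arr) > 0):
        raise ValueError("onsets must be strictly increasing")
    trimmed = arr[1:-1]
    window = trimmed[-1] - trimmed[0]
    n_intervals = trimmed.size - 1
    return 60.0 * n_intervals / window


def semitempo_error(response_bpm: float, target_bpm: float) -> float:
    """Signed tempo error in semitempo units: ``12 * log2(response/target)``.

    Positive when the response is faster than the target; one octave
    (a doubling) is 12 semitempi. E.g. a 118 bpm response to a 101 bpm
    target is an error of 2.7 semitempi.
    """
    if response_bpm <= 0 or target_bpm <= 0:
        raise ValueError("bpm values must be positive")
    return 12.0 * math.log2(response_bpm / target_bpm)


def identification_error(response_label: int, target_label: int) -> float:
    """Identification error in semitempo units (labels are 2 semitempi apart)."""
    return 2.0 * (int(response_label) - int(target_label))


def is_correct_production(
    response_bpm: float,
    target_bpm: float,
    band_semitempi: float = DEFAULT_BAND_SEMITEMPI,
    tol: float = BAND_TOL,
) -> bool:
    """True iff the response lies within +/- ``band_semitempi`` of the target.

    The band is inclusive; comparison uses an absolute tolerance on the
    semitempo value so exact-boundary responses count as correct.
    """
    return abs(semitempo_error(response_bpm, target_bpm)) <= band_semitempi + tol


def _resolve_response_bpm(row: pd.Series) -> float | None:
    bpm = row.get("response_bpm")
    if bpm is not None and not (isinstance(bpm, float) and math.isnan(bpm)):
        return float(bpm)
    onsets = row.get("onsets")
    if onsets is not None and not (
        isinstance(onsets, float) and math.isnan(onsets)
    ):
        return produced_bpm(onsets)
    return None


def score_trials(
    trials: pd.DataFrame,
    scale: ExperimentalScale,
    band_semitempi: float = DEFAULT_BAND_SEMITEMPI,
) -> pd.DataFrame:
    """Score a trial table against the experimental scale.

    Parameters
    ----------
    trials:
        One row per trial with columns ``participant_id``, ``group``,
        ``task`` ({'identification', 'production'}), ``trial_index``,
        ``target_label`` and a response: ``response_label`` for
        identification, ``response_bpm`` or ``onsets`` (a sequence of onset
        times in seconds) for production.
    scale:
        Experimental scale mapping labels to target bpm (unrounded values
        are used throughout).
    band_semitempi:
        Half-width of the production correctness band.

    Returns
    -------
    DataFrame with ``target_bpm``, ``response_bpm``, ``error_semitempi``
    and ``correct`` appended. Rows that cannot be scored (no usable
    response) get ``correct = NaN`` and are listed, with the reason, in
    ``result.attrs['row_errors']``; they never abort the run.
    """
    out = trials.copy()
    n = len(out)
    target_bpm = np.full(n, np.nan)
    response_bpm = np.full(n, np.nan)
    error = np.full(n, np.nan)
    correct = np.full(n, np.nan)
    row_errors: list[dict] = []

    for pos, (idx, row) in enumerate(out.iterrows()):
        try:
            t_bpm = scale.label_to_bpm(int(row["target_label"]))
        except (KeyError, ValueError, TypeError) as exc:
            row_errors.append({"index": idx, "reason": f"bad target_label: {exc}"})
            continue
        target_bpm[pos] = t_bpm
        task = str(row["task"])
        if task == "identification":
            lab = row.get("response_label")
            if lab is None or (isinstance(lab, float) and math.isnan(lab)):
                row_errors.append({"index": idx, "reason": "missing response_label"})
                continue
            lab = int(lab)
            error[pos] = identification_error(lab, int(row["target_label"]))
            correct[pos] = float(lab == int(row["target_label"]))
            try:
                response_bpm[pos] = scale.label_to_bpm(lab)
            except KeyError:
                response_bpm[pos] = np.nan
        elif task == "production":
            try:
                r_bpm = _resolve_response_bpm(row)
            except (InsufficientDataError, ValueError) as exc:
                row_errors.append({"index": idx, "reason": str(exc)})
                continue
            if r_bpm is None:
                row_errors.append(
                    {"index": idx, "reason": "no response_bpm and no onsets"}
                )
                continue
            response_bpm[pos] = r_bpm
            err = semitempo_error(r_bpm, t_bpm)
            error[pos] = err
            correct[pos] = float(abs(err) <= band_semitempi + BAND_TOL)
        else:
            row_errors.append({"index": idx, "reason": f"unknown task {task!r}"})

    out["target_bpm"] = target_bpm
    out["response_bpm"] = response_bpm
    out["error_semitempi"] = error
    out["correct"] = correct
    out.attrs["row_errors"] = row_errors
    return out


def correct_counts(scored: pd.DataFrame) -> pd.DataFrame:
    """Per-participant correct-response counts, one column per task.

    Returns a DataFrame with ``participant_id``, ``group``,
    ``n_correct_identification`` and ``n_correct_production`` (tasks a
    participant did not perform count as 0).
    """
    ok = scored.dropna(subset=["correct"])
    counts = (
        ok.groupby(["participant_id", "group", "task"], sort=False)["correct"]
        .sum()
        .unstack("task", fill_value=0.0)
    )
    counts = counts.rename(
        columns={
            "identification": "n_correct_identification",
            "production": "n_correct_production",
        }
    ).reset_index()
    for col in ("n_correct_identification", "n_correct_production"):
        if col not in counts:
            counts[col] = 0
        counts[col] = counts[col].astype(int)
    return counts
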