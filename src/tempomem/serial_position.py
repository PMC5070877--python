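"""Serial-position analysis of correct responses (bow-effect statistics).

Absolute-identification tasks typically show a *bow effect*: stimuli at the
edges of the ordered range are identified better than those in the middle.
This module counts correct responses per ordinal position of the target in
the learning set, contrasts the central position against the pooled other
positions with an (uncorrected) Pearson chi-square on the 2x2 table, and
summarises curvature with an orthogonal quadratic contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PositionCounts",
    "CentralContrast",
    "counts_by_position",
    "central_contrast",
    "bow_index",
]


@dataclass(frozen=True)
class PositionCounts:
    """Correct-response counts by target position, slowest to fastest."""

    task: str
    correct: tuple[int, ...]
    n_per_position: int

    @property
    def n_positions(self) -> int:
        return len(self.correct)


def counts_by_position(
    scored: pd.DataFrame,
    task: str | None = None,
    n_labels: int = 7,
) -> PositionCounts:
    """Count correct responses per target label in a scored trial table.

    ``n_per_position`` is taken as the number of scored responses per label
    (the cohort size when each participant sees every target once). Labels
    absent from the table contribute zero counts.
    """
    df = scored
    if task is not None:
        df = df[df["task"] == task]
    else:
        tasks = df["task"].unique()
        if len(tasks) != 1:
            raise ValueError("table mixes tasks; pass task= explicitly")
        task = str(tasks[0])
    df = df.dropna(subset=["correct"])
    per_label_n = df.groupby("target_label").size()
    per_label_correct = df.groupby("target_label")["correct"].sum()
    correct = tuple(
        int(per_label_correct.get(lab, 0)) for lab in range(1, n_labels + 1)
    )
    n_per = int(per_label_n.max()) if len(per_label_n) else 0
    return PositionCounts(task=str(task), correct=correct, n_per_position=n_per)


@dataclass(frozen=True)
class CentralContrast:
    """Central-vs-other 2x2 contingency result."""

    table: tuple[tuple[int, int], tuple[int, int]]
    chi_sq: float
    df: int
    p_value: float
    phi: float
    n_total: int


def central_contrast(counts: PositionCounts) -> CentralContrast:
    """Chi-square contrast of the central position against the other positions.

    Builds the 2x2 table {central, other-pooled} x {correct, incorrect} and
    computes the Pearson chi-square *without* continuity correction (df = 1)
    and the phi effect size ``sqrt(chi_sq / N)`` with N the total number of
    responses in the table.
    """
    k = counts.n_positions
    if k < 3 or k % 2 == 0:
        raise ValueError("need an odd number (>= 3) of positions")
    if counts.n_per_position <= 0:
        raise ValueError("n_per_position must be positive")
    c = k // 2
    central_ok = counts.correct[c]
    central_no = counts.n_per_position - central_ok
    other_ok = sum(counts.correct) - central_ok
    other_no = (k - 1) * counts.n_per_position - other_ok
    table = np.array([[central_ok, central_no], [other_ok, other_no]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin: chi-square statistic undefined")
    chi_sq, p_value, df, _ = stats.chi2_contingency(table, correction=False)
    n_total = int(table.sum())
    return CentralContrast(
        table=((int(central_ok), int(central_no)), (int(other_ok), int(other_no))),
        chi_sq=float(chi_sq),
        df=int(df),
        p_value=float(p_value),
        phi=math.sqrt(chi_sq / n_total),
        n_total=n_total,
    )


def bow_index(counts: PositionCounts) -> float:
    """Signed curvature of the serial-position curve.

    The orthogonal quadratic contrast over positions, normalised by the sum
    of squared contrast coefficients: positive for a U shape (edges better
    than the centre), negative for an inverted U, zero for a flat curve.
    """
    k = counts.n_positions
    i = np.arange(k, dtype=float)
    c = (i - (k - 1) / 2.0) ** 2
    c -= c.mean()
    x = np.asarray(counts.correct, dtype=float)
    return float(np.dot(c, x) / np.dot(c, c))
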