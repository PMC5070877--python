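"""Logarithmic tempo scales.

A *semitempo* is one step of a geometric tempo series with ratio
``2**(1/12)`` (about +6% per step), the tempo analogue of the equal-tempered
semitone: twelve semitempi double the beat frequency (one tempo "octave").
The experimental scale used for identification/production tasks picks every
second semitempo — seven tempi spanning one octave, roughly centred on the
spontaneous motor tempo (~100 bpm) — and labels them 1 (slowest) to 7
(fastest).

All computation is carried out on unrounded bpm; integer bpm values are a
display convention (half-up rounding), and the inter-onset intervals and
per-clip beat counts quoted for the experimental tempi follow the rounded
display values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

__all__ = [
    "SEMITEMPO_RATIO",
    "SemitempoSeries",
    "ExperimentalScale",
    "round_half_up",
    "build_semitempo_series",
    "select_experimental_scale",
    "bpm_to_ioi_ms",
    "ioi_ms_to_bpm",
    "beats_in_clip",
    "default_scale",
]

#: per-step frequency ratio of the semitempo series (12 steps = one doubling)
SEMITEMPO_RATIO: float = 2.0 ** (1.0 / 12.0)


def round_half_up(x: float) -> int:
    """Round a non-negative value to the nearest integer, halves upward.

    This is the rounding convention that reproduces the printed integer bpm
    series (e.g. 63.496 -> 63, 100.79 -> 101) from the unrounded values.
    """
    if x < 0:
        raise ValueError("round_half_up is defined for non-negative values")
    return int(math.floor(x + 0.5))


def bpm_to_ioi_ms(bpm: float) -> float:
    """Inter-onset interval in milliseconds for a tempo in beats per minute.

    120 bpm corresponds to an IOI of 500 ms.
    """
    if bpm <= 0:
        raise ValueError(f"bpm must be positive, got {bpm}")
    return 60_000.0 / bpm


def ioi_ms_to_bpm(ioi_ms: float) -> float:
    """Tempo in bpm for an inter-onset interval in milliseconds."""
    if ioi_ms <= 0:
        raise ValueError(f"ioi_ms must be positive, got {ioi_ms}")
    return 60_000.0 / ioi_ms


def beats_in_clip(bpm: float, duration_s: float = 10.0) -> int:
    """Number of beats in a clip of the given duration, rounded half-up."""
    if bpm <= 0:
        raise ValueError(f"bpm must be positive, got {bpm}")
    if duration_s <= 0:
        raise ValueError(f"duration_s must be positive, got {duration_s}")
    return round_half_up(bpm * duration_s / 60.0)


@dataclass(frozen=True)
class SemitempoSeries:
    """Geometric tempo series: ``values[k] = base_bpm * multiplier**k``."""

    base_bpm: float
    n_steps: int
    multiplier: float
    values_unrounded: tuple[float, ...]
    values_rounded: tuple[int, ...]

    def __len__(self) -> int:
        return self.n_steps

    def __getitem__(self, k: int) -> float:
        return self.values_unrounded[k]


def build_semitempo_series(
    base_bpm: float = 40.0,
    n_steps: int = 37,
    multiplier: float = SEMITEMPO_RATIO,
) -> SemitempoSeries:
    """Build a semitempo series of ``n_steps`` values starting at ``base_bpm``.

    The default (base 40 bpm, 37 steps) spans three tempo octaves, 40-320 bpm.

    Parameters
    ----------
    base_bpm:
        Tempo of the first element, bpm; must be positive.
    n_steps:
        Number of series elements (``n_steps = 1`` is the base alone).
    multiplier:
        Per-step frequency ratio; defaults to ``2**(1/12)``.
    """
    if base_bpm <= 0:
        raise ValueError(f"base_bpm must be positive, got {base_bpm}")
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    if multiplier <= 0:
        raise ValueError(f"multiplier must be positive, got {multiplier}")
    values = tuple(base_bpm * multiplier**k for k in range(n_steps))
    return SemitempoSeries(
        base_bpm=float(base_bpm),
        n_steps=int(n_steps),
        multiplier=float(multiplier),
        values_unrounded=values,
        values_rounded=tuple(round_half_up(v) for v in values),
    )


@dataclass(frozen=True)
class ExperimentalScale:
    """The labelled tempo scale presented to participants.

    ``labels[i]`` is the user-facing ordinal (1 = slowest). ``bpm_unrounded``
    carries the exact geometric values used in every computation;
    ``bpm_rounded``, ``ioi_ms`` and ``clip_beats`` are the display values
    (IOI and beat counts are derived from the rounded bpm, matching how the
    stimulus clips are described).
    """

    labels: tuple[int, ...]
    bpm_unrounded: tuple[float, ...]
    bpm_rounded: tuple[int, ...]
    ioi_ms: tuple[float, ...]
    clip_beats: tuple[int, ...]
    clip_duration_s: float = 10.0
    base_bpm: float = 40.0
    start_index: int = 10
    stride: int = 2

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.bpm_unrounded):
            raise ValueError("labels and bpm_unrounded must have equal length")

    @property
    def n_tempi(self) -> int:
        return len(self.labels)

    def label_to_bpm(self, label: int, rounded: bool = False) -> float:
        """Tempo for a label; unrounded by default (rounded for display)."""
        try:
            i = self.labels.index(int(label))
        except ValueError:
            raise KeyError(f"label {label} not on the scale") from None
        return self.bpm_rounded[i] if rounded else self.bpm_unrounded[i]

    def nearest_label(self, bpm: float) -> int:
        """Label of the scale tempo nearest to ``bpm`` in log-frequency.

        Ties go to the slower tempo (probability zero under continuous
        noise, but the convention is fixed).
        """
        if bpm <= 0:
            raise ValueError(f"bpm must be positive, got {bpm}")
        log_b = math.log2(bpm)
        best_i = min(
            range(self.n_tempi),
            key=lambda i: (abs(math.log2(self.bpm_unrounded[i]) - log_b), i),
        )
        return self.labels[best_i]

    def to_dict(self) -> dict:
        return {
            "base_bpm": self.base_bpm,
            "multiplier_exponent_denominator": 12,
            "start_index": self.start_index,
            "stride": self.stride,
            "clip_duration_s": self.clip_duration_s,
            "labels": list(self.labels),
            "bpm_unrounded": list(self.bpm_unrounded),
            "bpm_rounded": list(self.bpm_rounded),
            "ioi_ms": list(self.ioi_ms),
            "clip_beats": list(self.clip_beats),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(doc + "\n")
        return doc

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentalScale":
        return cls(
            labels=tuple(int(x) for x in d["labels"]),
            bpm_unrounded=tuple(float(x) for x in d["bpm_unrounded"]),
            bpm_rounded=tuple(int(x) for x in d["bpm_rounded"]),
            ioi_ms=tuple(float(x) for x in d["ioi_ms"]),
            clip_beats=tuple(int(x) for x in d["clip_beats"]),
            clip_duration_s=float(d.get("clip_duration_s", 10.0)),
            base_bpm=float(d.get("base_bpm", 40.0)),
            start_index=int(d.get("start_index", 10)),
            stride=int(d.get("stride", 2)),
        )

    @classmethod
    def from_json(cls, source: str | Path) -> "ExperimentalScale":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


def select_experimental_scale(
    series: SemitempoSeries,
    start_index: int = 10,
    stride: int = 2,
    count: int = 7,
    clip_duration_s: float = 10.0,
) -> ExperimentalScale:
    """Pick ``count`` tempi from a semitempo series, every ``stride`` steps.

    The default selection (start index 10, stride 2, count 7 on the 40-bpm
    series) yields the experimental octave 71-80-90-101-113-127-143 bpm
    (rounded); adjacent scale tempi are two semitempi (+12%) apart.
    """
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    if start_index < 0:
        raise ValueError(f"start_index must be >= 0, got {start_index}")
    last = start_index + stride * (count - 1)
    if last >= series.n_steps:
        raise IndexError(
            f"selection needs series index {last} but series has "
            f"{series.n_steps} steps"
        )
    idx = range(start_index, last + 1, stride)
    unrounded = tuple(series.values_unrounded[i] for i in idx)
    rounded = tuple(series.values_rounded[i] for i in idx)
    return ExperimentalScale(
        labels=tuple(range(1, count + 1)),
        bpm_unrounded=unrounded,
        bpm_rounded=rounded,
        ioi_ms=tuple(round(bpm_to_ioi_ms(b), 1) for b in rounded),
        clip_beats=tuple(beats_in_clip(b, clip_duration_s) for b in rounded),
        clip_duration_s=float(clip_duration_s),
        base_bpm=series.base_bpm,
        start_index=int(start_index),
        stride=int(stride),
    )


def default_scale() -> ExperimentalScale:
    """The seven-tempo experimental scale (71..143 bpm rounded, 10 s clips)."""
    return select_experimental_scale(build_semitempo_series(40.0, 37))
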