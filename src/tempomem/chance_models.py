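"""Chance-performance null models and above-chance classification.

A participant is called "above chance" in a task when their number of
correct responses k out of n trials satisfies P(X >= k) < alpha under a
binomial null with per-trial success probability p. For identification,
p = 1/7 (uniform guessing over seven labels). For production two null
models estimate p:

* a **permutation null** — pool every produced tempo across the cohort,
  repeatedly permute the pool over the trial slots, and count how often a
  permuted production falls within the +/- 1 semitempo correctness band of
  the slot's target;
* an **analytic log-uniform null** — guesses drawn uniformly in
  log-tempo over the empirical production range land in the correct band
  with probability p1 = (band width in semitempi) / (range width in
  semitempi), and are the *right* one of the n alternatives with
  probability p2 = 1/n, so p = p1 * p2.

Crossing thresholds (T_id, T_prod) partition a cohort into four classes
(above chance in both tasks, in one, or in neither).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .tap_metrics import DEFAULT_BAND_SEMITEMPI, BAND_TOL, correct_counts

__all__ = [
    "BinomialTail",
    "ThresholdResult",
    "PermutationEstimate",
    "UniformRangeNull",
    "ParticipantClass",
    "binomial_tail",
    "select_threshold",
    "permutation_null",
    "uniform_range_null",
    "classify_participant",
    "classify_cohort",
]

IDENTIFICATION_GUESS_P = 1.0 / 7.0


@dataclass(frozen=True)
class BinomialTail:
    """Upper-tail probabilities P(X >= k), k = 0..n, X ~ Binomial(n, p)."""

    n_trials: int
    p_success: float
    tail: tuple[float, ...]

    def __getitem__(self, k: int) -> float:
        return self.tail[k]


def binomial_tail(n: int, p: float) -> BinomialTail:
    """Exact upper-tail vector of a Binomial(n, p): P(X >= k) for k = 0..n."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    k = np.arange(n + 1)
    # sf(k-1) = P(X > k-1) = P(X >= k); exact for k = 0 as well
    tail = stats.binom.sf(k - 1, n, p)
    tail[0] = 1.0
    return BinomialTail(n_trials=n, p_success=float(p), tail=tuple(float(t) for t in tail))


@dataclass(frozen=True)
class ThresholdResult:
    """Smallest correct-response count T with P(X >= T) < alpha."""

    T: int | None
    alpha: float
    tail_at_T: float | None
    n_trials: int
    p_success: float

    @property
    def attainable(self) -> bool:
        return self.T is not None


def select_threshold(n: int, p: float, alpha: float = 0.05) -> ThresholdResult:
    """Smallest T in 1..n whose binomial upper tail is strictly below alpha.

    Returns ``T = None`` when even a perfect score is not improbable enough
    (p too large for the trial count).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    bt = binomial_tail(n, p)
    for k in range(1, n + 1):
        if bt.tail[k] < alpha:
            return ThresholdResult(
                T=k, alpha=alpha, tail_at_T=bt.tail[k], n_trials=n, p_success=p
            )
    return ThresholdResult(T=None, alpha=alpha, tail_at_T=None, n_trials=n, p_success=p)


@dataclass(frozen=True)
class PermutationEstimate:
    """Chance-correct probability estimated by permuting pooled productions."""

    n_cycles: int
    seed: int
    n_assignments: int
    n_correct: int
    p_hat: float
    per_cycle_correct: tuple[int, ...] = field(repr=False, default=())

    @property
    def se_hat(self) -> float:
        """Monte-Carlo standard error from the spread of per-cycle rates."""
        n_slots = self.n_assignments // self.n_cycles
        rates = np.asarray(self.per_cycle_correct, dtype=float) / n_slots
        if rates.size < 2:
            return float("nan")
        return float(rates.std(ddof=1) / math.sqrt(self.n_cycles))


def permutation_null(
    scored_production: pd.DataFrame,
    n_cycles: int = 100,
    seed: int | None = None,
    band_semitempi: float = DEFAULT_BAND_SEMITEMPI,
) -> PermutationEstimate:
    """Estimate the per-trial chance-correct probability by permutation.

    Each cycle draws one uniform random permutation of the pooled produced
    bpm values (fixed points allowed), assigns them to the trial slots, and
    counts assignments within +/- ``band_semitempi`` of the slot's target;
    ``p_hat`` pools the correct counts over all cycles. Deterministic given
    ``seed``.

    Parameters
    ----------
    scored_production:
        Scored production trials with ``target_bpm`` and ``response_bpm``
        columns (rows with either missing are dropped).
    """
    if seed is None:
        raise ValueError("seed is required for a reproducible permutation null")
    if n_cycles < 1:
        raise ValueError(f"n_cycles must be >= 1, got {n_cycles}")
    ok = scored_production.dropna(subset=["target_bpm", "response_bpm"])
    targets = ok["target_bpm"].to_numpy(dtype=float)
    pool = ok["response_bpm"].to_numpy(dtype=float)
    n = targets.size
    if n == 0:
        raise ValueError("empty production pool")
    rng = np.random.default_rng(seed)
    log_t = 12.0 * np.log2(targets)
    log_r = 12.0 * np.log2(pool)
    per_cycle = np.empty(n_cycles, dtype=int)
    for c in range(n_cycles):
        perm = rng.permutation(n)
        per_cycle[c] = int(
            np.sum(np.abs(log_r[perm] - log_t) <= band_semitempi + BAND_TOL)
        )
    n_correct = int(per_cycle.sum())
    return PermutationEstimate(
        n_cycles=n_cycles,
        seed=int(seed),
        n_assignments=n_cycles * n,
        n_correct=n_correct,
        p_hat=n_correct / (n_cycles * n),
        per_cycle_correct=tuple(int(x) for x in per_cycle),
    )


@dataclass(frozen=True)
class UniformRangeNull:
    """Analytic chance-correct probability under a log-uniform guess model."""

    range_lo: float
    range_hi: float
    band_lo: float
    band_hi: float
    n_alternatives: int
    band_semitempi: float
    range_semitempi: float
    p1: float
    p2: float
    p: float


def uniform_range_null(
    range_lo: float = 23.0,
    range_hi: float = 233.0,
    band_lo: float = 67.0,
    band_hi: float = 150.4,
    n_alternatives: int = 7,
) -> UniformRangeNull:
    """Chance probability for guesses log-uniform on [range_lo, range_hi].

    ``p1`` is the fraction of the range (measured in semitempi, i.e. in log
    tempo) covered by the correct-response band; ``p2 = 1/n_alternatives``
    is the probability a guess inside the band matches the right target.
    The defaults are the study values: an empirical production range of
    23-233 bpm (40.1 semitempi) and a correct band of 67-150.4 bpm
    (14 semitempi), giving p = 0.35 / 7 = 0.05.
    """
    if not 0 < range_lo < range_hi:
        raise ValueError("need 0 < range_lo < range_hi")
    if not (range_lo <= band_lo < band_hi <= range_hi):
        raise ValueError("band must lie inside the range")
    if n_alternatives < 1:
        raise ValueError("n_alternatives must be >= 1")
    band_w = 12.0 * math.log2(band_hi / band_lo)
    range_w = 12.0 * math.log2(range_hi / range_lo)
    p1 = band_w / range_w
    p2 = 1.0 / n_alternatives
    return UniformRangeNull(
        range_lo=range_lo,
        range_hi=range_hi,
        band_lo=band_lo,
        band_hi=band_hi,
        n_alternatives=n_alternatives,
        band_semitempi=band_w,
        range_semitempi=range_w,
        p1=p1,
        p2=p2,
        p=p1 * p2,
    )


class ParticipantClass(str, Enum):
    """Quadrant of the (identification, production) above-chance plane."""

    BOTH_ABOVE = "both_above"
    IDENTIFICATION_ONLY = "identification_only"
    PRODUCTION_ONLY = "production_only"
    CHANCE = "chance"


def classify_participant(
    n_correct_id: int,
    n_correct_prod: int,
    T_id: int = 4,
    T_prod: int = 3,
) -> ParticipantClass:
    """Assign a participant to one of the four above-chance quadrants.

    Thresholds are inclusive: a count equal to T counts as above chance.
    """
    above_id = n_correct_id >= T_id
    above_prod = n_correct_prod >= T_prod
    if above_id and above_prod:
        return ParticipantClass.BOTH_ABOVE
    if above_id:
        return ParticipantClass.IDENTIFICATION_ONLY
    if above_prod:
        return ParticipantClass.PRODUCTION_ONLY
    return ParticipantClass.CHANCE


def classify_cohort(
    scored: pd.DataFrame,
    T_id: int = 4,
    T_prod: int = 3,
) -> pd.DataFrame:
    """Per-participant correct counts and quadrant class for a scored table."""
    counts = correct_counts(scored)
    counts["participant_class"] = [
        classify_participant(i, p, T_id, T_prod).value
        for i, p in zip(
            counts["n_correct_identification"], counts["n_correct_production"]
        )
    ]
    return counts
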