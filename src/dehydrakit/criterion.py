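"""Criterion standard for dehydration severity from serial daily weights.

A rehydrated child gains weight until reaching the pre-illness weight, then
plateaus as the kidneys diurese excess fluid. The stable weight is the mean
of the highest two consecutive daily weights that differ by less than 2%;
percent weight change with rehydration, (stable - admission)/stable * 100,
is the proxy for percent volume deficit. Children who kept gaining, kept
losing, or had a single weight have no stable weight and are indeterminate
for the criterion standard unless they died (death is part of the composite
severe-disease outcome).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Literal, Optional, Sequence


class WeightStatus(str, Enum):
    STABLE = "stable"
    GAINING = "gaining"
    LOSING = "losing"
    SINGLE = "single"


class DehydrationCategory(str, Enum):
    NONE = "none"
    SOME = "some"
    SEVERE = "severe"


class SevereDisease(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class WeightSeries:
    """Ordered (day_index, weight_kg) pairs; day 0 is the admission weight."""

    days: tuple[int, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.days) != len(self.weights) or not self.days:
            raise ValueError("weight series needs >= 1 (day, weight) pair")
        if any(d2 <= d1 for d1, d2 in zip(self.days, self.days[1:])):
            raise ValueError("day indices must be strictly increasing")
        if any(not math.isfinite(w) or w <= 0 for w in self.weights):
            raise ValueError("weights must be finite and positive")

    @classmethod
    def from_weights(cls, weights: Sequence[float]) -> "WeightSeries":
        return cls(tuple(range(len(weights))), tuple(float(w) for w in weights))

    @property
    def admission_weight(self) -> float:
        return self.weights[0]


@dataclass(frozen=True)
class StableWeightResult:
    status: WeightStatus
    stable_weight: Optional[float] = None
    pair_indices: Optional[tuple[int, int]] = None


def find_stable_weight(
    series: WeightSeries,
    *,
    rel_tol: float = 0.02,
    denominator: Literal["mean", "larger"] = "mean",
) -> StableWeightResult:
    """Locate the stable weight in a daily weight series.

    Candidate pairs are consecutive measurements whose relative difference
    (|w2 - w1| over the pair mean, or the larger weight if ``denominator`` is
    "larger") is below ``rel_tol``. Among candidates the pair with the
    greatest mean wins ("highest two consecutive weights"); ties go to the
    later pair. With no candidate the series is classified ``single`` (one
    measurement), ``gaining`` (last weight >= first) or ``losing``.
    """
    w = series.weights
    if len(w) == 1:
        return StableWeightResult(WeightStatus.SINGLE)
    best_mean, best_pair = None, None
    for i in range(len(w) - 1):
        a, b = w[i], w[i + 1]
        denom = (a + b) / 2.0 if denominator == "mean" else max(a, b)
        if abs(b - a) / denom < rel_tol:
            pair_mean = (a + b) / 2.0
            if best_mean is None or pair_mean >= best_mean:
                best_mean, best_pair = pair_mean, (i, i + 1)
    if best_pair is not None:
        return StableWeightResult(WeightStatus.STABLE, best_mean, best_pair)
    # No qualifying pair: equal first/last weights would require some consecutive
    # step < rel_tol somewhere along a path returning to its start, which is not
    # guaranteed, so >= breaks toward "gaining".
    status = WeightStatus.GAINING if w[-1] >= w[0] else WeightStatus.LOSING
    return StableWeightResult(status)


def percent_weight_change(admission_kg: float, stable_kg: float) -> float:
    """Percent weight change with rehydration: (stable - admission)/stable * 100."""
    if admission_kg <= 0 or stable_kg <= 0:
        raise ValueError("weights must be positive")
    return (stable_kg - admission_kg) / stable_kg * 100.0


def classify_dehydration(pct: float, *, severe_inclusive: bool = True) -> DehydrationCategory:
    """Band percent weight change: <2% none, 2-10% some, >=10% severe.

    ``severe_inclusive`` keeps exactly 10% in the severe band (10% or more);
    unset, 10.0 falls in "some" (strictly greater than 10%).
    """
    if not math.isfinite(pct):
        raise ValueError("percent weight change must be finite")
    if pct < 2.0:
        return DehydrationCategory.NONE
    severe = pct >= 10.0 if severe_inclusive else pct > 10.0
    return DehydrationCategory.SEVERE if severe else DehydrationCategory.SOME


@dataclass(frozen=True)
class DehydrationOutcome:
    """Criterion-standard outcome for one child."""

    status: WeightStatus
    died: bool
    percent_weight_change: Optional[float] = None
    category: Optional[DehydrationCategory] = None
    severe_disease: SevereDisease = SevereDisease.INDETERMINATE


def severe_disease_outcome(
    series: WeightSeries,
    died: bool,
    *,
    rel_tol: float = 0.02,
    denominator: Literal["mean", "larger"] = "mean",
    severe_inclusive: bool = True,
) -> DehydrationOutcome:
    """Composite severe-disease outcome: severe dehydration (>=10% weight
    change) or in-hospital death.

    Children who died are outcome-positive regardless of weights (they rarely
    survive to a stable weight). Children with a stable weight are positive in
    the severe band, negative otherwise. Survivors without a stable weight are
    indeterminate and excluded from accuracy analyses.
    """
    res = find_stable_weight(series, rel_tol=rel_tol, denominator=denominator)
    if died:
        return DehydrationOutcome(res.status, True, severe_disease=SevereDisease.POSITIVE)
    if res.status is not WeightStatus.STABLE:
        return DehydrationOutcome(res.status, False, severe_disease=SevereDisease.INDETERMINATE)
    pct = percent_weight_change(series.admission_weight, res.stable_weight)
    cat = classify_dehydration(pct, severe_inclusive=severe_inclusive)
    sd = SevereDisease.POSITIVE if cat is DehydrationCategory.SEVERE else SevereDisease.NEGATIVE
    return DehydrationOutcome(res.status, False, pct, cat, sd)
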