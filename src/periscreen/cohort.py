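"""Estimation of model inputs from longitudinal EPDS screening data.

A cohort file holds one row per woman with EPDS scores at up to seven
visits (13, 17, 24, 31, 37 gestational weeks; days 3 and 42 postpartum).
Visits collapse to the four model periods (the paired visits by averaging),
scores categorize against the screening cutoffs (>= 9 suspicious, >= 13
high risk), and the categorized trajectories yield the baseline
distribution, baseline-anchored (or chained) transition tables, per-period
detection rates, and trajectory-pattern statistics.

Anchored estimation conditions each period's state on the *baseline* state,
which is how longitudinal follow-up tables are usually tabulated; women
missing a period contribute to the denominator but to no numerator, so row
masses fall short of 1 exactly where follow-up was lost.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .states import (
    LIVING_STATES,
    TRANSITION_PERIODS,
    HealthState,
    PerinatalPeriod,
    PeriodTransitionMatrix,
    Semantics,
    StateDistribution,
    TransitionSchedule,
)

__all__ = [
    "CategoryThresholds",
    "Trajectory",
    "CohortSummary",
    "EstimationResult",
    "VISIT_LABELS",
    "categorize_epds",
    "collapse_to_periods",
    "baseline_distribution",
    "estimate_anchored_transitions",
    "estimate_chained_transitions",
    "detection_rates",
    "outcome_statistics",
]

#: Visit labels and the period each belongs to.  Paired visits are averaged.
VISIT_LABELS: dict[str, PerinatalPeriod] = {
    "13w": PerinatalPeriod.FIRST_TRIMESTER,
    "17w": PerinatalPeriod.SECOND_TRIMESTER,
    "24w": PerinatalPeriod.SECOND_TRIMESTER,
    "31w": PerinatalPeriod.THIRD_TRIMESTER,
    "37w": PerinatalPeriod.THIRD_TRIMESTER,
    "d3": PerinatalPeriod.POSTPARTUM,
    "d42": PerinatalPeriod.POSTPARTUM,
}

ALL_PERIODS = tuple(PerinatalPeriod)


@dataclass(frozen=True)
class CategoryThresholds:
    """EPDS cutoffs: scores in [0, suspicious_min) are normal,
    [suspicious_min, high_min) suspicious, and >= high_min high risk."""

    suspicious_min: float = 9.0
    high_min: float = 13.0

    def __post_init__(self) -> None:
        if not 0 < self.suspicious_min < self.high_min:
            raise ValueError("need 0 < suspicious_min < high_min")


@dataclass(frozen=True)
class Trajectory:
    """One woman's screening category (and optionally score) per period.

    ``states`` maps each of the four periods to a living state or ``None``
    (missing).  ``scores`` optionally carries the period-collapsed raw EPDS
    scores the categories came from.
    """

    subject_id: str
    states: Mapping[PerinatalPeriod, HealthState | None]
    scores: Mapping[PerinatalPeriod, float | None] | None = None

    def state(self, period: PerinatalPeriod) -> HealthState | None:
        return self.states.get(period)

    @property
    def complete(self) -> bool:
        return all(self.states.get(p) is not None for p in ALL_PERIODS)

    @classmethod
    def from_scores(
        cls,
        subject_id: str,
        period_scores: Mapping[PerinatalPeriod, float | None],
        thresholds: CategoryThresholds = CategoryThresholds(),
    ) -> "Trajectory":
        states = {
            p: None if s is None else categorize_epds(s, thresholds)
            for p, s in period_scores.items()
        }
        return cls(subject_id, states, dict(period_scores))


@dataclass(frozen=True)
class CohortSummary:
    """Trajectory-pattern statistics over complete trajectories."""

    n_complete: int
    detection_rates: dict[PerinatalPeriod, float]
    always_normal: float
    ever_positive: float
    persistent_positive: float  # positive in all four periods, of complete
    persistent_positive_of_ever: float  # same numerator, of ever-positive
    first_positive_postpartum: float


@dataclass(frozen=True)
class EstimationResult:
    """Estimated schedule plus the count tables behind it."""

    schedule: TransitionSchedule
    counts: pd.DataFrame  # columns: period, from_state, to_state, count
    denominators: dict[HealthState, int]
    flags: list[str] = field(default_factory=list)


def categorize_epds(
    score: float, thresholds: CategoryThresholds = CategoryThresholds()
) -> HealthState:
    """Map an EPDS score (possibly a visit-pair average) to a living state."""
    if score < 0:
        raise ValueError(f"negative EPDS score: {score}")
    if score < thresholds.suspicious_min:
        return HealthState.NORMAL
    if score < thresholds.high_min:
        return HealthState.SUSPICIOUS
    return HealthState.HIGH_RISK


def collapse_to_periods(
    visit_scores: Mapping[str, float | None],
) -> dict[PerinatalPeriod, float | None]:
    """Average paired visit scores into the four model periods.

    A pair with one missing member uses the available score; a fully
    missing pair yields a missing period.
    """
    for label in visit_scores:
        if label.lower() not in VISIT_LABELS:
            raise ValueError(
                f"unknown visit label {label!r}; expected one of {sorted(VISIT_LABELS)}"
            )
    by_period: dict[PerinatalPeriod, list[float]] = {p: [] for p in ALL_PERIODS}
    for label, score in visit_scores.items():
        if score is not None and not (isinstance(score, float) and np.isnan(score)):
            by_period[VISIT_LABELS[label.lower()]].append(float(score))
    return {
        p: (float(np.mean(v)) if v else None) for p, v in by_period.items()
    }


def baseline_distribution(
    trajectories: Sequence[Trajectory],
) -> tuple[StateDistribution, dict[HealthState, int]]:
    """First-trimester state shares among women with a baseline observation."""
    counts = Counter(
        t.state(PerinatalPeriod.FIRST_TRIMESTER)
        for t in trajectories
        if t.state(PerinatalPeriod.FIRST_TRIMESTER) is not None
    )
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("no trajectory has a baseline (first trimester) observation")
    by_state = {s: counts.get(s, 0) for s in LIVING_STATES}
    dist = StateDistribution(
        by_state[HealthState.NORMAL] / denom,
        by_state[HealthState.SUSPICIOUS] / denom,
        by_state[HealthState.HIGH_RISK] / denom,
    )
    return dist, by_state


def _counts_frame(
    counts: dict[tuple[PerinatalPeriod, HealthState, HealthState], int],
) -> pd.DataFrame:
    rows = [
        {
            "period": p.value,
            "from_state": o.value,
            "to_state": d.value,
            "count": counts.get((p, o, d), 0),
        }
        for p in TRANSITION_PERIODS
        for o in LIVING_STATES
        for d in LIVING_STATES
    ]
    return pd.DataFrame(rows)


def estimate_anchored_transitions(
    trajectories: Sequence[Trajectory],
    thresholds: CategoryThresholds = CategoryThresholds(),
) -> EstimationResult:
    """Baseline-anchored transition tables: P(state at period | baseline state).

    Denominators are the baseline group sizes; subjects missing a period
    contribute no numerator there, so the estimated row mass equals the
    retention in that period.  A baseline state with no subjects yields an
    all-zero row and a flag.
    """
    del thresholds  # trajectories are already categorized
    with_base = [
        t for t in trajectories if t.state(PerinatalPeriod.FIRST_TRIMESTER) is not None
    ]
    if not with_base:
        raise ValueError("no trajectory has a baseline observation")
    denominators = {
        s: sum(1 for t in with_base if t.state(PerinatalPeriod.FIRST_TRIMESTER) is s)
        for s in LIVING_STATES
    }
    counts: dict[tuple[PerinatalPeriod, HealthState, HealthState], int] = {}
    for t in with_base:
        b = t.state(PerinatalPeriod.FIRST_TRIMESTER)
        assert b is not None
        for p in TRANSITION_PERIODS:
            s = t.state(p)
            if s is not None:
                counts[(p, b, s)] = counts.get((p, b, s), 0) + 1

    flags = [
        f"no subjects with baseline state {s.value}; row undefined"
        for s in LIVING_STATES
        if denominators[s] == 0
    ]
    matrices = []
    for p in TRANSITION_PERIODS:
        rows = np.zeros((3, 3))
        for i, origin in enumerate(LIVING_STATES):
            if denominators[origin] == 0:
                continue
            for j, dest in enumerate(LIVING_STATES):
                rows[i, j] = counts.get((p, origin, dest), 0) / denominators[origin]
        matrices.append(PeriodTransitionMatrix(p, rows))
    return EstimationResult(
        schedule=TransitionSchedule(tuple(matrices), Semantics.ANCHORED),
        counts=_counts_frame(counts),
        denominators=denominators,
        flags=flags,
    )


def estimate_chained_transitions(
    trajectories: Sequence[Trajectory],
    thresholds: CategoryThresholds = CategoryThresholds(),
) -> EstimationResult:
    """Period-to-period transition tables: P(state at period | previous state).

    Uses subject-period pairs where both the period and its predecessor are
    observed.  This is the estimator matching a subject-level Markov chain.
    """
    del thresholds
    pair_counts: dict[tuple[PerinatalPeriod, HealthState, HealthState], int] = {}
    pair_denoms: dict[tuple[PerinatalPeriod, HealthState], int] = {}
    for t in trajectories:
        for prev_p, p in zip(ALL_PERIODS[:-1], ALL_PERIODS[1:]):
            o, d = t.state(prev_p), t.state(p)
            if o is not None and d is not None:
                pair_counts[(p, o, d)] = pair_counts.get((p, o, d), 0) + 1
                pair_denoms[(p, o)] = pair_denoms.get((p, o), 0) + 1
    if not pair_counts:
        raise ValueError("no observed consecutive-period pairs")

    flags = []
    matrices = []
    for p in TRANSITION_PERIODS:
        rows = np.zeros((3, 3))
        for i, origin in enumerate(LIVING_STATES):
            denom = pair_denoms.get((p, origin), 0)
            if denom == 0:
                flags.append(f"{p.value}: no subjects observed in origin {origin.value}")
                continue
            for j, dest in enumerate(LIVING_STATES):
                rows[i, j] = pair_counts.get((p, origin, dest), 0) / denom
        matrices.append(PeriodTransitionMatrix(p, rows))
    # chained denominators vary by period; report baseline-period origins
    denominators = {
        s: pair_denoms.get((PerinatalPeriod.SECOND_TRIMESTER, s), 0)
        for s in LIVING_STATES
    }
    return EstimationResult(
        schedule=TransitionSchedule(tuple(matrices), Semantics.CHAINED),
        counts=_counts_frame(pair_counts),
        denominators=denominators,
        flags=flags,
    )


def detection_rates(
    trajectories: Sequence[Trajectory],
    thresholds: CategoryThresholds = CategoryThresholds(),
) -> tuple[dict[PerinatalPeriod, float], dict[PerinatalPeriod, int]]:
    """Per-period positive fraction (state above cutoff) among the observed.

    Returns (rates, per-period denominators).
    """
    del thresholds
    if not trajectories:
        raise ValueError("empty cohort")
    rates: dict[PerinatalPeriod, float] = {}
    denoms: dict[PerinatalPeriod, int] = {}
    for p in ALL_PERIODS:
        observed = [t.state(p) for t in trajectories if t.state(p) is not None]
        denoms[p] = len(observed)
        rates[p] = (
            sum(1 for s in observed if s is not HealthState.NORMAL) / len(observed)
            if observed
            else float("nan")
        )
    return rates, denoms


def outcome_statistics(
    trajectories: Sequence[Trajectory],
    thresholds: CategoryThresholds = CategoryThresholds(),
) -> CohortSummary:
    """Trajectory-pattern statistics over complete (all-period) trajectories.

    * always-normal: normal at every period;
    * ever-positive: its complement;
    * persistent-positive: positive at every period (reported both against
      all complete trajectories and against the ever-positive subgroup,
      since either denominator is defensible);
    * first-positive-postpartum: normal throughout pregnancy, positive
      only at the postpartum period.
    """
    complete = [t for t in trajectories if t.complete]
    if not complete:
        raise ValueError("no complete trajectories (all four periods observed)")
    n = len(complete)

    def positive(t: Trajectory, p: PerinatalPeriod) -> bool:
        return t.state(p) is not HealthState.NORMAL

    always_normal = sum(
        1 for t in complete if not any(positive(t, p) for p in ALL_PERIODS)
    )
    ever_positive = n - always_normal
    persistent = sum(1 for t in complete if all(positive(t, p) for p in ALL_PERIODS))
    first_pp = sum(
        1
        for t in complete
        if positive(t, PerinatalPeriod.POSTPARTUM)
        and not any(positive(t, p) for p in ALL_PERIODS[:3])
    )
    rates, _ = detection_rates(complete, thresholds)
    return CohortSummary(
        n_complete=n,
        detection_rates=rates,
        always_normal=always_normal / n,
        ever_positive=ever_positive / n,
        persistent_positive=persistent / n,
        persistent_positive_of_ever=(persistent / ever_positive if ever_positive else 0.0),
        first_positive_postpartum=first_pp / n,
    )
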