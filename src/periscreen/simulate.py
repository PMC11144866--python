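"""Synthetic longitudinal screening cohorts with known ground truth.

Subjects are generated as individual Markov chains: a baseline state drawn
from the configured distribution, then one state per post-baseline period
drawn from the (row-normalized) period matrix conditional on the previous
period's state.  Generation is therefore CHAINED at the subject level —
baseline-anchored tables cannot produce coherent individual trajectories —
and the anchored estimator applied to such data recovers the *implied*
anchored table (the product structure), not the generating rows; the
chained estimator recovers the generating rows themselves.

Optional per-period missingness (independent Bernoulli) emulates loss to
follow-up; optional integer scores are drawn uniformly within each state's
score band so that re-categorization always returns the generating state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import ALL_PERIODS, CategoryThresholds, Trajectory
from .states import (
    LIVING_STATES,
    TRANSITION_PERIODS,
    HealthState,
    PerinatalPeriod,
    StateDistribution,
    TransitionSchedule,
)

__all__ = ["SimulationConfig", "GroundTruth", "simulate_trajectories", "DEFAULT_SCORE_BANDS"]

#: Inclusive integer score bands per state; consistent with cutoffs 9 and 13.
DEFAULT_SCORE_BANDS: dict[HealthState, tuple[int, int]] = {
    HealthState.NORMAL: (0, 8),
    HealthState.SUSPICIOUS: (9, 12),
    HealthState.HIGH_RISK: (13, 30),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings.

    ``missing_rate`` applies independently per period (including baseline);
    ``score_bands`` must agree with the thresholds any downstream
    categorization will use.
    """

    baseline: StateDistribution
    schedule: TransitionSchedule
    n_subjects: int
    seed: int
    missing_rate: float = 0.0
    emit_scores: bool = False
    score_bands: dict[HealthState, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_BANDS)
    )
    thresholds: CategoryThresholds = CategoryThresholds()

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if abs(self.baseline.living.sum() - 1.0) > 1e-9:
            raise ValueError("baseline shares must sum to 1")
        for s, (lo, hi) in self.score_bands.items():
            if lo > hi:
                raise ValueError(f"empty score band for {s.value}")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually used: baseline and row-normalized rows."""

    baseline: StateDistribution
    normalized_schedule: TransitionSchedule
    seed: int
    n_subjects: int
    missing_rate: float


def simulate_trajectories(
    config: SimulationConfig,
) -> tuple[list[Trajectory], GroundTruth]:
    """Generate a cohort of categorized trajectories plus the ground truth.

    Identical configuration (including seed) yields identical output.
    """
    normalized = config.schedule.normalized()
    rng = np.random.default_rng(config.seed)

    baseline_p = config.baseline.living
    rows = {m.period: m.rows for m in normalized.matrices}

    n = config.n_subjects
    # state indices per period, generated chained at the subject level
    states = np.empty((n, 4), dtype=np.int64)
    states[:, 0] = rng.choice(3, size=n, p=baseline_p)
    for k, period in enumerate(TRANSITION_PERIODS, start=1):
        r = rows[period]
        u = rng.random(n)
        cum = r.cumsum(axis=1)
        states[:, k] = (u[:, None] > cum[states[:, k - 1]]).sum(axis=1)

    missing = (
        rng.random((n, 4)) < config.missing_rate
        if config.missing_rate > 0
        else np.zeros((n, 4), dtype=bool)
    )

    scores: np.ndarray | None = None
    if config.emit_scores:
        scores = np.empty((n, 4), dtype=np.int64)
        for idx, state in enumerate(LIVING_STATES):
            lo, hi = config.score_bands[state]
            mask = states == idx
            scores[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))

    trajectories: list[Trajectory] = []
    width = len(str(n))
    for i in range(n):
        st: dict[PerinatalPeriod, HealthState | None] = {}
        sc: dict[PerinatalPeriod, float | None] = {}
        for k, period in enumerate(ALL_PERIODS):
            if missing[i, k]:
                st[period] = None
                sc[period] = None
            else:
                st[period] = LIVING_STATES[states[i, k]]
                sc[period] = float(scores[i, k]) if scores is not None else None
        trajectories.append(
            Trajectory(
                subject_id=f"S{i + 1:0{width}d}",
                states=st,
                scores=sc if config.emit_scores else None,
            )
        )
    truth = GroundTruth(
        baseline=config.baseline,
        normalized_schedule=normalized,
        seed=config.seed,
        n_subjects=n,
        missing_rate=config.missing_rate,
    )
    return trajectories, truth
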