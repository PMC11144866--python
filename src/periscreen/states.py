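"""Health states, occupancy distributions, and period transition matrices.

The model tracks a cohort of pregnant women through four perinatal periods
(first, second, third trimester, postpartum) across four discrete health
states: *normal*, *suspicious* (above the screening cutoff but below the
high-risk cutoff), *high risk*, and *death*.  Death is absorbing.

Transition matrices are period-specific and cover the three post-baseline
periods.  Row masses may legitimately fall short of 1 when loss to follow-up
is represented as unattributed mass; validation warns below 0.95 and errors
above 1.01.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HealthState",
    "LIVING_STATES",
    "PerinatalPeriod",
    "TRANSITION_PERIODS",
    "Semantics",
    "StateDistribution",
    "PeriodTransitionMatrix",
    "TransitionSchedule",
    "ValidationIssue",
    "validate_transition_matrix",
]


class HealthState(enum.Enum):
    """The four health states of the perinatal depression model."""

    NORMAL = "normal"
    SUSPICIOUS = "suspicious"
    HIGH_RISK = "high_risk"
    DEAD = "dead"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Living states, in the canonical row/column order of transition matrices.
LIVING_STATES: tuple[HealthState, ...] = (
    HealthState.NORMAL,
    HealthState.SUSPICIOUS,
    HealthState.HIGH_RISK,
)


class PerinatalPeriod(enum.Enum):
    """The four screening periods, one model cycle (3 months) each."""

    FIRST_TRIMESTER = "first_trimester"
    SECOND_TRIMESTER = "second_trimester"
    THIRD_TRIMESTER = "third_trimester"
    POSTPARTUM = "postpartum"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Post-baseline periods, i.e. the periods a transition matrix targets.
TRANSITION_PERIODS: tuple[PerinatalPeriod, ...] = (
    PerinatalPeriod.SECOND_TRIMESTER,
    PerinatalPeriod.THIRD_TRIMESTER,
    PerinatalPeriod.POSTPARTUM,
)


class Semantics(enum.Enum):
    """How a transition schedule is applied during cohort roll-forward.

    ANCHORED
        Each period matrix maps the *baseline* distribution to that period's
        occupancy (period-state probabilities conditional on the baseline
        state, as longitudinal follow-up tables report them).
    CHAINED
        Each matrix maps the *previous* cycle's distribution forward — the
        textbook Markov reading.
    """

    ANCHORED = "anchored"
    CHAINED = "chained"


@dataclass(frozen=True)
class StateDistribution:
    """Cohort occupancy shares at one cycle.

    Shares are fractions; the total may be below 1 when loss to follow-up is
    carried as unattributed mass rather than renormalized away.
    """

    normal: float
    suspicious: float
    high_risk: float
    dead: float = 0.0

    def __post_init__(self) -> None:
        for name in ("normal", "suspicious", "high_risk", "dead"):
            v = getattr(self, name)
            if v < -1e-12:
                raise ValueError(f"negative share for {name}: {v}")
        if self.total > 1.0 + 1e-9:
            raise ValueError(f"total mass {self.total} exceeds 1")

    @property
    def living(self) -> np.ndarray:
        """Living-state shares as a vector in ``LIVING_STATES`` order."""
        return np.array([self.normal, self.suspicious, self.high_risk])

    @property
    def total(self) -> float:
        return self.normal + self.suspicious + self.high_risk + self.dead

    def share(self, state: HealthState) -> float:
        return {
            HealthState.NORMAL: self.normal,
            HealthState.SUSPICIOUS: self.suspicious,
            HealthState.HIGH_RISK: self.high_risk,
            HealthState.DEAD: self.dead,
        }[state]

    @classmethod
    def from_living(cls, living: np.ndarray, dead: float = 0.0) -> "StateDistribution":
        n, s, h = (float(x) for x in living)
        return cls(n, s, h, dead)


@dataclass(frozen=True)
class PeriodTransitionMatrix:
    """Transition probabilities into one post-baseline period.

    ``rows`` is a 3x3 array: origin living state (baseline or previous
    period) by destination living state, both in ``LIVING_STATES`` order.
    Entries are fractions.  Deficient row mass (sum < 1) represents subjects
    lost to follow-up in that period.
    """

    period: PerinatalPeriod
    rows: np.ndarray

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=float)
        if rows.shape != (3, 3):
            raise ValueError(f"transition matrix must be 3x3, got {rows.shape}")
        object.__setattr__(self, "rows", rows)
        if self.period not in TRANSITION_PERIODS:
            raise ValueError(f"{self.period} is not a post-baseline period")

    def row(self, origin: HealthState) -> np.ndarray:
        return self.rows[LIVING_STATES.index(origin)]

    def normalized(self) -> "PeriodTransitionMatrix":
        """Row-normalized copy (redistributes lost-to-follow-up mass)."""
        sums = self.rows.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValueError("cannot normalize a zero row")
        return PeriodTransitionMatrix(self.period, self.rows / sums)


@dataclass(frozen=True)
class TransitionSchedule:
    """The three period matrices, chronologically ordered, plus semantics."""

    matrices: tuple[PeriodTransitionMatrix, ...]
    semantics: Semantics = Semantics.ANCHORED

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrices", tuple(self.matrices))
        periods = tuple(m.period for m in self.matrices)
        if periods != TRANSITION_PERIODS:
            raise ValueError(
                f"schedule must hold one matrix per period in order "
                f"{[p.value for p in TRANSITION_PERIODS]}, got {[p.value for p in periods]}"
            )

    def matrix(self, period: PerinatalPeriod) -> PeriodTransitionMatrix:
        for m in self.matrices:
            if m.period == period:
                return m
        raise KeyError(period)

    def with_semantics(self, semantics: Semantics) -> "TransitionSchedule":
        return TransitionSchedule(self.matrices, semantics)

    def normalized(self) -> "TransitionSchedule":
        return TransitionSchedule(
            tuple(m.normalized() for m in self.matrices), self.semantics
        )


@dataclass(frozen=True)
class ValidationIssue:
    level: str  # "error" | "warning"
    message: str


def validate_transition_matrix(matrix: PeriodTransitionMatrix) -> list[ValidationIssue]:
    """Check a period matrix for structural problems.

    Errors: negative entries, entries above 1, or row sums above 1.01.
    Warnings: row sums below 0.95 (heavy loss to follow-up).
    """
    issues: list[ValidationIssue] = []
    for origin, row in zip(LIVING_STATES, matrix.rows):
        if np.any(row < 0):
            issues.append(
                ValidationIssue("error", f"{origin.value}: negative transition probability")
            )
        if np.any(row > 1):
            issues.append(
                ValidationIssue("error", f"{origin.value}: entry above 1")
            )
        total = float(row.sum())
        if total > 1.01:
            issues.append(
                ValidationIssue("error", f"{origin.value}: row sum {total:.4g} > 1.01")
            )
        elif total < 0.95:
            issues.append(
                ValidationIssue(
                    "warning",
                    f"{origin.value}: row mass {total:.4g} < 0.95 (loss to follow-up)",
                )
            )
    return issues
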