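"""Markov cohort engine: four-cycle roll-forward with cost and QALY accrual.

Each cycle is 3 months (0.25 years).  Utility accrues as the share-weighted
utility of the living states (plus 0 for death) times the cycle length; cost
accrues as the share-weighted per-state cycle cost.  There is no discounting
and no half-cycle correction over this short horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .states import (
    LIVING_STATES,
    HealthState,
    PeriodTransitionMatrix,
    Semantics,
    StateDistribution,
    TransitionSchedule,
    validate_transition_matrix,
)

__all__ = [
    "StrategyDefinition",
    "MarkovTrace",
    "apply_transition",
    "apply_mortality",
    "roll_forward",
    "accrue_costs",
]

#: Number of model cycles (first trimester through postpartum).
N_CYCLES = 4


@dataclass(frozen=True)
class StrategyDefinition:
    """One model arm: initial occupancy, schedule, per-state costs/utilities.

    Parameters
    ----------
    state_cycle_costs
        Money (yuan) accrued per cycle by a woman occupying each living
        state.  Death accrues no cost.
    state_utilities
        Utility weights in [0, 1] per living state; death has utility 0.
    high_risk_mortality
        Per-cycle probability that a high-risk woman dies (depression
        suicide risk); 0 in the base case.
    cycle_years
        Years per cycle; 0.25 for the 3-month perinatal cycles.
    """

    name: str
    initial: StateDistribution
    schedule: TransitionSchedule
    state_cycle_costs: dict[HealthState, float]
    state_utilities: dict[HealthState, float]
    high_risk_mortality: float = 0.0
    cycle_years: float = 0.25

    def __post_init__(self) -> None:
        for s in LIVING_STATES:
            if s not in self.state_cycle_costs:
                raise ValueError(f"missing cycle cost for state {s.value}")
            if s not in self.state_utilities:
                raise ValueError(f"missing utility for state {s.value}")
            if self.state_cycle_costs[s] < 0:
                raise ValueError(f"negative cost for state {s.value}")
            if not 0.0 <= self.state_utilities[s] <= 1.0:
                raise ValueError(f"utility for {s.value} outside [0, 1]")
        if self.state_cycle_costs.get(HealthState.DEAD, 0.0) != 0.0:
            raise ValueError("death must have zero cost")
        if self.state_utilities.get(HealthState.DEAD, 0.0) != 0.0:
            raise ValueError("death must have zero utility")
        if not 0.0 <= self.high_risk_mortality <= 1.0:
            raise ValueError("high_risk_mortality outside [0, 1]")
        if self.cycle_years <= 0:
            raise ValueError("cycle_years must be positive")

    @property
    def cost_vector(self) -> np.ndarray:
        return np.array([self.state_cycle_costs[s] for s in LIVING_STATES])

    @property
    def utility_vector(self) -> np.ndarray:
        return np.array([self.state_utilities[s] for s in LIVING_STATES])


@dataclass(frozen=True)
class MarkovTrace:
    """Per-cycle occupancy, cost and QALY contributions, plus totals."""

    distributions: tuple[StateDistribution, ...]
    cycle_costs: tuple[float, ...]
    cycle_qalys: tuple[float, ...]
    total_cost: float
    total_qalys: float


def apply_transition(
    dist: StateDistribution, matrix: PeriodTransitionMatrix
) -> StateDistribution:
    """One matrix-vector step; the dead share is carried forward unchanged."""
    new_living = dist.living @ matrix.rows
    return StateDistribution.from_living(new_living, dead=dist.dead)


def apply_mortality(dist: StateDistribution, rate: float) -> StateDistribution:
    """Move ``rate`` of the high-risk share to death; mass is conserved."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"mortality rate {rate} outside [0, 1]")
    moved = rate * dist.high_risk
    return StateDistribution(
        dist.normal, dist.suspicious, dist.high_risk - moved, dist.dead + moved
    )


def accrue_costs(
    trace: MarkovTrace, state_cycle_costs: dict[HealthState, float]
) -> tuple[tuple[float, ...], float]:
    """Re-cost an existing trace with a different per-state cost table.

    Returns (per-cycle costs, total).  Death contributes nothing.
    """
    for s, c in state_cycle_costs.items():
        if c < 0:
            raise ValueError(f"negative cost for state {s.value}")
    cost_vec = np.array([state_cycle_costs[s] for s in LIVING_STATES])
    per_cycle = tuple(float(d.living @ cost_vec) for d in trace.distributions)
    return per_cycle, float(sum(per_cycle))


def roll_forward(
    strategy: StrategyDefinition,
    *,
    renormalize: bool = False,
    validate: bool = True,
) -> MarkovTrace:
    """Roll the cohort through the four cycles and accrue costs and QALYs.

    Under ANCHORED semantics each period matrix is applied to the *initial*
    distribution; under CHAINED it is applied to the previous cycle's.  Both
    agree at cycle 2.  Mortality, if nonzero, removes a fraction of each
    post-baseline cycle's high-risk share.  With ``renormalize`` the period
    matrices are row-normalized first (redistributing loss to follow-up);
    the default uses row masses as given.
    """
    schedule = strategy.schedule.normalized() if renormalize else strategy.schedule
    if validate:
        for m in schedule.matrices:
            errors = [i for i in validate_transition_matrix(m) if i.level == "error"]
            if errors:
                raise ValueError(
                    f"invalid {m.period.value} matrix: "
                    + "; ".join(i.message for i in errors)
                )

    dists = [strategy.initial]
    for matrix in schedule.matrices:
        origin = dists[0] if schedule.semantics is Semantics.ANCHORED else dists[-1]
        d = apply_transition(origin, matrix)
        if strategy.high_risk_mortality > 0:
            d = apply_mortality(d, strategy.high_risk_mortality)
        dists.append(d)

    u, c = strategy.utility_vector, strategy.cost_vector
    cycle_qalys = tuple(float(d.living @ u) * strategy.cycle_years for d in dists)
    cycle_costs = tuple(float(d.living @ c) for d in dists)
    return MarkovTrace(
        distributions=tuple(dists),
        cycle_costs=cycle_costs,
        cycle_qalys=cycle_qalys,
        total_cost=float(sum(cycle_costs)),
        total_qalys=float(sum(cycle_qalys)),
    )
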