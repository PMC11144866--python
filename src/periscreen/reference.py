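"""Built-in base-case parameter set for the Chinese perinatal screening model.

Everything needed to run the two-arm comparison without external files:
baseline distributions and period transition tables for the screened and
routine-care cohorts (from national longitudinal screening follow-up),
state utilities, component costs, the positive predictive value of the
EPDS, the willingness-to-pay threshold (1x China's 2021 per-capita GDP),
and the uncertain-parameter table driving the sensitivity analyses.

Also included are the raw follow-up count tables the transition estimates
derive from, so the estimation stage can be exercised end to end on the
same inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .costing import DEFAULT_SCREENING_POSITIVE_OVERRIDE, CostInputs
from .sensitivity import DistKind, ParamSpec
from .states import (
    HealthState,
    PerinatalPeriod,
    PeriodTransitionMatrix,
    Semantics,
    StateDistribution,
    TransitionSchedule,
)

__all__ = [
    "ModelParameters",
    "reference_parameters",
    "reference_param_specs",
    "reference_transition_counts",
    "reference_cohort_counts",
    "trajectories_from_anchored_counts",
    "reference_trajectories",
    "WTP_CHINA_2021",
]

#: Willingness-to-pay threshold: 1x China's 2021 per-capita GDP (yuan/QALY).
WTP_CHINA_2021 = 80_976.0


@dataclass(frozen=True)
class ModelParameters:
    """The full two-arm model configuration."""

    screening_initial: StateDistribution
    routine_initial: StateDistribution
    screening_schedule: TransitionSchedule
    routine_schedule: TransitionSchedule
    utilities: dict[HealthState, float]
    cost_inputs: CostInputs
    screening_positive_override: float | None
    wtp: float
    mortality: float = 0.0
    semantics: Semantics = Semantics.ANCHORED
    cycle_years: float = 0.25
    renormalize: bool = False

    def with_semantics(self, semantics: Semantics) -> "ModelParameters":
        return replace(
            self,
            semantics=semantics,
            screening_schedule=self.screening_schedule.with_semantics(semantics),
            routine_schedule=self.routine_schedule.with_semantics(semantics),
        )


def _schedule(rows_by_period: dict[PerinatalPeriod, list[list[float]]]) -> TransitionSchedule:
    return TransitionSchedule(
        tuple(
            PeriodTransitionMatrix(p, np.array(rows_by_period[p]))
            for p in (
                PerinatalPeriod.SECOND_TRIMESTER,
                PerinatalPeriod.THIRD_TRIMESTER,
                PerinatalPeriod.POSTPARTUM,
            )
        )
    )


# Routine-care (unscreened) cohort: baseline-anchored period tables from the
# national longitudinal cohort (fractions; deficient row mass = follow-up loss).
_ROUTINE_INITIAL = StateDistribution(0.728, 0.195, 0.077)
_ROUTINE_ROWS = {
    PerinatalPeriod.SECOND_TRIMESTER: [
        [0.934, 0.021, 0.003],
        [0.669, 0.314, 0.017],
        [0.516, 0.333, 0.151],
    ],
    PerinatalPeriod.THIRD_TRIMESTER: [
        [0.959, 0.034, 0.003],
        [0.746, 0.225, 0.030],
        [0.570, 0.290, 0.140],
    ],
    PerinatalPeriod.POSTPARTUM: [
        [0.931, 0.052, 0.012],
        [0.733, 0.220, 0.047],
        [0.559, 0.312, 0.129],
    ],
}

# Screened cohort: same structure, from the hospital screening programme.
_SCREENING_INITIAL = StateDistribution(0.715, 0.265, 0.020)
_SCREENING_ROWS = {
    PerinatalPeriod.SECOND_TRIMESTER: [
        [0.971, 0.026, 0.002],
        [0.910, 0.071, 0.019],
        [0.833, 0.083, 0.083],
    ],
    PerinatalPeriod.THIRD_TRIMESTER: [
        [0.964, 0.031, 0.005],
        [0.949, 0.051, 0.000],
        [1.000, 0.000, 0.000],
    ],
    PerinatalPeriod.POSTPARTUM: [
        [0.969, 0.014, 0.017],
        [0.955, 0.026, 0.019],
        [1.000, 0.000, 0.000],
    ],
}

#: State utility weights (QALY weights per year in state).
_UTILITIES = {
    HealthState.NORMAL: 0.86,
    HealthState.SUSPICIOUS: 0.80,
    HealthState.HIGH_RISK: 0.63,
    HealthState.DEAD: 0.0,
}


def reference_parameters() -> ModelParameters:
    """The base-case two-arm model, ready to roll forward."""
    return ModelParameters(
        screening_initial=_SCREENING_INITIAL,
        routine_initial=_ROUTINE_INITIAL,
        screening_schedule=_schedule(_SCREENING_ROWS),
        routine_schedule=_schedule(_ROUTINE_ROWS),
        utilities=dict(_UTILITIES),
        cost_inputs=CostInputs(),
        screening_positive_override=DEFAULT_SCREENING_POSITIVE_OVERRIDE,
        wtp=WTP_CHINA_2021,
    )


def reference_param_specs() -> list[ParamSpec]:
    """Uncertain parameters for DSA and PSA.

    Utilities carry Beta distributions and the surveyed cost/frequency
    parameters Gamma distributions (method-of-moments from the reported
    mean/SD); the remaining parameters — drug cost, specialist cost,
    baseline state shares, mortality and the discount rate — have
    deterministic ranges only and enter the one-way analysis alone.
    Treatment sessions: base 3 with range 2-12; the Monte Carlo mean is
    3.33 (SD 0.84) as surveyed.
    """
    B, G, N = DistKind.BETA, DistKind.GAMMA, DistKind.NONE
    return [
        ParamSpec("utility_normal", 0.86, 0.77, 0.95, B, 0.86, 0.09),
        ParamSpec("utility_suspicious", 0.80, 0.72, 0.83, B, 0.80, 0.08),
        ParamSpec("utility_high_risk", 0.63, 0.30, 0.73, B, 0.63, 0.15),
        ParamSpec("screening_fee", 19.0, 5.0, 51.0, G, 19.0, 21.83),
        ParamSpec("registration_fee", 22.5, 15.0, 30.0, G, 22.5, 8.66),
        ParamSpec("first_visit_fee", 42.5, 30.0, 49.5, G, 42.5, 10.85),
        ParamSpec("treatment_cost", 229.0, 79.0, 495.0, G, 229.0, 209.41),
        ParamSpec("treatment_sessions", 3.0, 2.0, 12.0, G, 3.33, 0.84),
        ParamSpec("drug_cost", 479.7, 97.2, 1106.1, N),
        ParamSpec("specialist_cost", 1405.9, 846.8, 1702.0, N),
        ParamSpec("mortality", 0.0, 0.0, 0.04, N),
        ParamSpec("discount_rate", 0.03, 0.0, 0.07, N),
        ParamSpec("screening_baseline_normal", 0.715, 0.678, 0.725, N),
        ParamSpec("screening_baseline_suspicious", 0.265, 0.229, 0.275, N),
        ParamSpec("routine_baseline_normal", 0.728, 0.703, 0.753, N),
        ParamSpec("routine_baseline_suspicious", 0.195, 0.173, 0.217, N),
    ]


def reference_transition_counts() -> pd.DataFrame:
    """Follow-up counts behind the routine-care transition tables.

    One row per (baseline group, period, destination category); baseline
    group sizes were 884 normal, 236 suspicious, 93 high risk (n = 1,213
    with a baseline observation).  Period row sums below the group size are
    women lost to follow-up in that period.
    """
    data = {
        ("normal", 884): {
            "second_trimester": (826, 19, 3),
            "third_trimester": (848, 30, 3),
            "postpartum": (823, 46, 11),
        },
        ("suspicious", 236): {
            "second_trimester": (158, 74, 4),
            "third_trimester": (176, 53, 7),
            "postpartum": (173, 52, 11),
        },
        ("high_risk", 93): {
            "second_trimester": (48, 31, 14),
            "third_trimester": (53, 27, 13),
            "postpartum": (52, 29, 12),
        },
    }
    rows = []
    for (origin, size), periods in data.items():
        for period, (n, s, h) in periods.items():
            for dest, count in zip(("normal", "suspicious", "high_risk"), (n, s, h)):
                rows.append(
                    {
                        "from_state": origin,
                        "baseline_n": size,
                        "period": period,
                        "to_state": dest,
                        "count": count,
                    }
                )
    return pd.DataFrame(rows)


def trajectories_from_anchored_counts(counts: pd.DataFrame):
    """Reconstruct a categorized cohort realizing an anchored count table.

    Anchored counts constrain only the per-period destination marginals
    within each baseline group, so any assignment matching those marginals
    is a valid realization; destinations are assigned deterministically by
    subject index within each group.  Subjects beyond a period's row sum
    (loss to follow-up) get a missing period.  Running the anchored
    estimator on the result reproduces the table exactly.

    ``counts`` uses the ``reference_transition_counts`` layout
    (from_state, baseline_n, period, to_state, count).
    """
    from .cohort import Trajectory  # local import to avoid a cycle
    from .states import LIVING_STATES, TRANSITION_PERIODS

    state_by_name = {s.value: s for s in LIVING_STATES}
    trajectories = []
    for origin_name, group in counts.groupby("from_state", sort=False):
        origin = state_by_name[str(origin_name)]
        size = int(group["baseline_n"].iloc[0])
        # per period, expand destination counts into a subject-indexed list
        period_states: dict[PerinatalPeriod, list[HealthState | None]] = {}
        for period in TRANSITION_PERIODS:
            block = group[group["period"] == period.value]
            assigned: list[HealthState | None] = []
            for _, r in block.iterrows():
                assigned.extend([state_by_name[r["to_state"]]] * int(r["count"]))
            if len(assigned) > size:
                raise ValueError(
                    f"{origin.value}/{period.value}: counts exceed baseline size {size}"
                )
            assigned.extend([None] * (size - len(assigned)))
            period_states[period] = assigned
        for i in range(size):
            states: dict[PerinatalPeriod, HealthState | None] = {
                PerinatalPeriod.FIRST_TRIMESTER: origin
            }
            for period in TRANSITION_PERIODS:
                states[period] = period_states[period][i]
            trajectories.append(Trajectory(f"{origin.value}_{i + 1}", states))
    return trajectories


def reference_trajectories():
    """The routine-care cohort reconstructed from its follow-up counts."""
    return trajectories_from_anchored_counts(reference_transition_counts())


def reference_cohort_counts() -> dict[str, int]:
    """Headline cohort counts from the longitudinal study.

    enrolled/analyzed give the follow-up retention; among the 329
    ever-positive women, 101 screened positive postpartum and 55 were
    positive in the second and third trimesters and postpartum.
    """
    return {
        "enrolled": 1284,
        "analyzed": 1210,
        "ever_positive": 329,
        "postpartum_positive": 101,
        "positive_all_followup_periods": 55,
    }
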