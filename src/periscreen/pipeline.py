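"""Glue from a parameter set to strategies, comparisons and analyses.

``build_comparison`` is the single path from a ``ModelParameters`` bundle
(plus named scalar overrides) to the two-arm incremental comparison; the
deterministic base case, the one-way DSA and the PSA all go through it, so
a parameter perturbs the model the same way everywhere.

Override semantics worth knowing:

* Overriding a baseline state share rescales that arm's other two shares
  proportionally so the baseline still sums to 1.
* ``discount_rate`` re-converts the specialist-hospital cost from its raw
  literature value (back-derived from the base-case 3 %/yr conversion), so
  the base rate reproduces the base-case cost exactly.
* When the screening high-risk state cost is pinned to its base-case
  override, component overrides (treatment cost, sessions, drug cost, PPV,
  fees) shift it additively by the change they induce in the component
  formula — the base case stays at the override while sensitivity analyses
  still see every component.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping

import pandas as pd

from .costing import (
    CostInputs,
    build_state_cost_tables,
    inflate_cost,
    screening_positive_cost,
)
from .cua import (
    CUAComparison,
    StrategyOutcome,
    cost_utility_ratio,
    decide,
    incremental_analysis,
)
from .markov import MarkovTrace, StrategyDefinition, roll_forward
from .reference import ModelParameters
from .states import HealthState, StateDistribution

__all__ = [
    "OVERRIDABLE",
    "build_strategies",
    "build_comparison",
    "model_builder_for",
    "base_case_report",
]

#: Names accepted as overrides by ``build_comparison``.
OVERRIDABLE = frozenset(
    {
        "utility_normal",
        "utility_suspicious",
        "utility_high_risk",
        "screening_fee",
        "registration_fee",
        "first_visit_fee",
        "treatment_cost",
        "treatment_sessions",
        "drug_cost",
        "medication_proportion",
        "specialist_cost",
        "ppv",
        "mortality",
        "discount_rate",
        "cycle_years",
        "screening_baseline_normal",
        "screening_baseline_suspicious",
        "screening_baseline_high_risk",
        "routine_baseline_normal",
        "routine_baseline_suspicious",
        "routine_baseline_high_risk",
    }
)

_COST_FIELD = {
    "screening_fee": "screening_fee",
    "registration_fee": "registration_fee",
    "first_visit_fee": "first_visit_fee",
    "treatment_cost": "treatment_cost_per_session",
    "treatment_sessions": "treatment_sessions",
    "drug_cost": "drug_cost_3mo",
    "medication_proportion": "medication_proportion",
    "specialist_cost": "specialist_cost",
    "ppv": "ppv",
}


def _override_share(dist: StateDistribution, which: str, value: float) -> StateDistribution:
    """Set one baseline share, rescaling the others to keep the sum at 1."""
    shares = {
        "normal": dist.normal,
        "suspicious": dist.suspicious,
        "high_risk": dist.high_risk,
    }
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"baseline share {which}={value} outside [0, 1]")
    others = [k for k in shares if k != which]
    rest = sum(shares[k] for k in others)
    remaining = 1.0 - value
    if rest > 0:
        for k in others:
            shares[k] = shares[k] / rest * remaining
    else:
        shares[others[0]] = remaining
    shares[which] = value
    return StateDistribution(shares["normal"], shares["suspicious"], shares["high_risk"])


def _resolved(params: ModelParameters, overrides: Mapping[str, float]) -> ModelParameters:
    unknown = set(overrides) - OVERRIDABLE
    if unknown:
        raise KeyError(f"unknown override parameter(s): {sorted(unknown)}")

    cost_kwargs = {
        field: overrides[name] for name, field in _COST_FIELD.items() if name in overrides
    }
    inputs = replace(params.cost_inputs, **cost_kwargs) if cost_kwargs else params.cost_inputs

    if "discount_rate" in overrides:
        base = params.cost_inputs
        raw = base.specialist_cost / (1.0 + base.inflation_rate) ** base.inflation_years
        inputs = replace(
            inputs,
            specialist_cost=inflate_cost(
                raw, overrides["discount_rate"], base.inflation_years
            ),
            inflation_rate=overrides["discount_rate"],
        )

    utilities = dict(params.utilities)
    for name, state in (
        ("utility_normal", HealthState.NORMAL),
        ("utility_suspicious", HealthState.SUSPICIOUS),
        ("utility_high_risk", HealthState.HIGH_RISK),
    ):
        if name in overrides:
            utilities[state] = overrides[name]

    screening_initial = params.screening_initial
    routine_initial = params.routine_initial
    for name, value in overrides.items():
        if name.startswith("screening_baseline_"):
            screening_initial = _override_share(
                screening_initial, name.removeprefix("screening_baseline_"), value
            )
        elif name.startswith("routine_baseline_"):
            routine_initial = _override_share(
                routine_initial, name.removeprefix("routine_baseline_"), value
            )

    return replace(
        params,
        cost_inputs=inputs,
        utilities=utilities,
        screening_initial=screening_initial,
        routine_initial=routine_initial,
        mortality=overrides.get("mortality", params.mortality),
        cycle_years=overrides.get("cycle_years", params.cycle_years),
    )


def _screening_override_value(
    params: ModelParameters, resolved_inputs: CostInputs
) -> float | None:
    """Carry the pinned screening high-risk cost additively through
    component changes (see module docstring)."""
    if params.screening_positive_override is None:
        return None
    shift = screening_positive_cost(resolved_inputs) - screening_positive_cost(
        params.cost_inputs
    )
    return params.screening_positive_override + shift


def build_strategies(
    params: ModelParameters, overrides: Mapping[str, float] | None = None
) -> dict[str, StrategyDefinition]:
    """Assemble the screening and routine-care arms, overrides applied."""
    p = _resolved(params, overrides or {})
    tables = build_state_cost_tables(
        p.cost_inputs,
        screening_positive_override=_screening_override_value(params, p.cost_inputs),
    )
    semantics = p.semantics
    common = dict(
        state_utilities=p.utilities,
        high_risk_mortality=p.mortality,
        cycle_years=p.cycle_years,
    )
    return {
        "screening": StrategyDefinition(
            name="screening",
            initial=p.screening_initial,
            schedule=p.screening_schedule.with_semantics(semantics),
            state_cycle_costs=tables["screening"].as_dict(),
            **common,
        ),
        "routine": StrategyDefinition(
            name="routine",
            initial=p.routine_initial,
            schedule=p.routine_schedule.with_semantics(semantics),
            state_cycle_costs=tables["routine"].as_dict(),
            **common,
        ),
    }


def build_comparison(
    params: ModelParameters, overrides: Mapping[str, float] | None = None
) -> CUAComparison:
    """Roll both arms forward and compare routine care against screening."""
    strategies = build_strategies(params, overrides)
    traces = {
        name: roll_forward(s, renormalize=params.renormalize)
        for name, s in strategies.items()
    }
    outcomes = {
        name: StrategyOutcome(name, t.total_cost, t.total_qalys)
        for name, t in traces.items()
    }
    return incremental_analysis(outcomes["screening"], outcomes["routine"])


def model_builder_for(params: ModelParameters):
    """A ``ModelBuilder`` closure over a fixed parameter bundle."""

    def builder(overrides: Mapping[str, float]) -> CUAComparison:
        return build_comparison(params, overrides)

    return builder


def base_case_report(
    params: ModelParameters,
) -> tuple[dict[str, MarkovTrace], CUAComparison, str, pd.DataFrame]:
    """Base case: traces, comparison, WTP decision, and a summary table.

    The table mirrors the conventional CUA layout: per-arm cost, QALYs and
    average cost-utility ratio, plus increments and the ICUR on the
    comparator row.
    """
    strategies = build_strategies(params)
    traces = {
        name: roll_forward(s, renormalize=params.renormalize)
        for name, s in strategies.items()
    }
    outcomes = {
        name: StrategyOutcome(name, t.total_cost, t.total_qalys)
        for name, t in traces.items()
    }
    comparison = incremental_analysis(outcomes["screening"], outcomes["routine"])
    choice = decide(comparison, params.wtp)
    rows = [
        {
            "strategy": "screening",
            "cost": round(outcomes["screening"].cost, 2),
            "incremental_cost": None,
            "qalys": round(outcomes["screening"].qalys, 2),
            "incremental_qalys": None,
            "icur": None,
            "average_cur": round(cost_utility_ratio(outcomes["screening"]), 2),
        },
        {
            "strategy": "routine",
            "cost": round(outcomes["routine"].cost, 2),
            "incremental_cost": round(comparison.delta_cost, 2),
            "qalys": round(outcomes["routine"].qalys, 2),
            "incremental_qalys": round(comparison.delta_qalys, 2),
            "icur": None if comparison.icur is None else round(comparison.icur, 2),
            "average_cur": round(cost_utility_ratio(outcomes["routine"]), 2),
        },
    ]
    return traces, comparison, choice, pd.DataFrame(rows)
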