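"""Cost-utility metrics: CUR, incremental analysis, dominance, WTP decision.

Conventions follow standard health-economics practice: the comparison is
comparator minus reference (here routine care minus screening), the ICUR is
the ratio of those increments, and dominance labels disambiguate the sign
of a raw ratio.  ``net_monetary_benefit`` gives the equivalent linearized
decision rule (NMB = WTP x QALYs - cost).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

__all__ = [
    "Dominance",
    "StrategyOutcome",
    "CUAComparison",
    "cost_utility_ratio",
    "incremental_analysis",
    "decide",
    "net_monetary_benefit",
]


class Dominance(enum.Enum):
    """Quadrant classification of the comparator relative to the reference."""

    DOMINANT = "dominant"  # comparator cheaper and more effective
    DOMINATED = "dominated"  # comparator dearer and less effective
    TRADE_OFF = "trade_off"  # one up, one down: ICUR vs WTP decides
    TIE = "tie"  # both increments zero


@dataclass(frozen=True)
class StrategyOutcome:
    """Per-capita cost (yuan) and effectiveness (QALYs) of one arm."""

    name: str
    cost: float
    qalys: float

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError("cost must be nonnegative")
        if self.qalys < 0:
            raise ValueError("qalys must be nonnegative")


@dataclass(frozen=True)
class CUAComparison:
    """Incremental comparison of a comparator arm against a reference arm.

    ``icur`` is ``delta_cost / delta_qalys`` (yuan/QALY), or ``None`` when
    the QALY increment is zero — a raw ratio is then undefined and the
    decision falls back to cost minimization.
    """

    reference: StrategyOutcome
    comparator: StrategyOutcome
    delta_cost: float
    delta_qalys: float
    icur: float | None
    dominance: Dominance
    reference_cur: float | None
    comparator_cur: float | None


def cost_utility_ratio(outcome: StrategyOutcome) -> float:
    """Average cost per QALY gained (yuan/QALY)."""
    if outcome.qalys == 0:
        raise ZeroDivisionError(
            f"cost-utility ratio undefined for {outcome.name}: zero QALYs"
        )
    return outcome.cost / outcome.qalys


def incremental_analysis(
    reference: StrategyOutcome, comparator: StrategyOutcome
) -> CUAComparison:
    """Compute increments, the ICUR, and the dominance quadrant."""
    delta_cost = comparator.cost - reference.cost
    delta_qalys = comparator.qalys - reference.qalys
    icur = delta_cost / delta_qalys if delta_qalys != 0 else None

    if delta_cost == 0 and delta_qalys == 0:
        dominance = Dominance.TIE
    elif delta_cost <= 0 and delta_qalys >= 0:
        dominance = Dominance.DOMINANT
    elif delta_cost >= 0 and delta_qalys <= 0:
        dominance = Dominance.DOMINATED
    else:
        dominance = Dominance.TRADE_OFF

    return CUAComparison(
        reference=reference,
        comparator=comparator,
        delta_cost=delta_cost,
        delta_qalys=delta_qalys,
        icur=icur,
        dominance=dominance,
        reference_cur=(
            cost_utility_ratio(reference) if reference.qalys > 0 else None
        ),
        comparator_cur=(
            cost_utility_ratio(comparator) if comparator.qalys > 0 else None
        ),
    )


def decide(comparison: CUAComparison, wtp: float) -> str:
    """Name of the preferred strategy at the given WTP threshold.

    A dominant comparator is always chosen and a dominated one never;
    in trade-off quadrants the comparator is accepted iff its ICUR is at
    most the WTP (north-east: paying for extra QALYs) or at least the WTP
    (south-west: savings large enough to forgo QALYs).  Ties resolve to
    the reference.
    """
    if wtp <= 0:
        raise ValueError("wtp must be positive")
    if comparison.dominance is Dominance.DOMINANT:
        return comparison.comparator.name
    if comparison.dominance in (Dominance.DOMINATED, Dominance.TIE):
        return comparison.reference.name
    assert comparison.icur is not None and not math.isnan(comparison.icur)
    if comparison.delta_qalys > 0:  # north-east: more QALYs, more cost
        accept = comparison.icur <= wtp
    else:  # south-west: fewer QALYs, less cost
        accept = comparison.icur >= wtp
    return comparison.comparator.name if accept else comparison.reference.name


def net_monetary_benefit(outcome: StrategyOutcome, wtp: float) -> float:
    """NMB = WTP x QALYs - cost (yuan); maximizing NMB reproduces decide()."""
    if wtp < 0:
        raise ValueError("wtp must be nonnegative")
    return wtp * outcome.qalys - outcome.cost
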