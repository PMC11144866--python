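"""Delimited-text I/O for every table the pipeline consumes or produces.

All files are UTF-8 CSV with '.' decimals.  Probability tables may carry a
``# units=percent`` or ``# units=fraction`` first line; percent values are
converted to fractions on read and the conversion is logged.  Without the
flag, units are inferred (values above 1.5 must be percentages) and the
inference is logged too.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    ALL_PERIODS,
    CategoryThresholds,
    CohortSummary,
    Trajectory,
    collapse_to_periods,
)
from .sensitivity import DistKind, DSARecord, ParamSpec, PSAResult
from .states import (
    LIVING_STATES,
    TRANSITION_PERIODS,
    HealthState,
    PerinatalPeriod,
    PeriodTransitionMatrix,
    StateDistribution,
    TransitionSchedule,
)

__all__ = [
    "read_transition_csv",
    "write_transition_csv",
    "read_initial_csv",
    "write_initial_csv",
    "read_param_specs_csv",
    "write_param_specs_csv",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_dsa_csv",
    "write_psa_csv",
    "write_cohort_summary_csv",
]

logger = logging.getLogger(__name__)

_SCORE_COLUMNS = ["score_13w", "score_17w", "score_24w", "score_31w", "score_37w", "score_d3", "score_d42"]
_CAT_COLUMNS = ["cat_t1", "cat_t2", "cat_t3", "cat_t4"]
_STATE_BY_NAME = {s.value: s for s in LIVING_STATES}


def _read_units_header(path: Path) -> tuple[str | None, int]:
    """Return (units flag, number of comment lines to skip)."""
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
    if first.startswith("#"):
        body = first.lstrip("#").strip()
        if body.startswith("units="):
            units = body.removeprefix("units=").strip()
            if units not in ("percent", "fraction"):
                raise ValueError(f"{path}: bad units flag {units!r}")
            return units, 1
        return None, 1
    return None, 0


def _to_fraction(values: np.ndarray, units: str | None, what: str) -> np.ndarray:
    if units == "percent":
        logger.info("%s: converting percentages to fractions", what)
        return values / 100.0
    if units == "fraction":
        return values
    if np.nanmax(values) > 1.5:
        logger.info("%s: no units flag; values look like percentages, converting", what)
        return values / 100.0
    logger.info("%s: no units flag; values look like fractions", what)
    return values


def read_transition_csv(path: str | Path) -> TransitionSchedule:
    """Read a period-by-origin transition table.

    Columns: period, from_state, to_normal, to_suspicious, to_high_risk.
    """
    path = Path(path)
    units, skip = _read_units_header(path)
    df = pd.read_csv(path, skiprows=skip)
    required = {"period", "from_state", "to_normal", "to_suspicious", "to_high_risk"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    values = df[["to_normal", "to_suspicious", "to_high_risk"]].to_numpy(dtype=float)
    values = _to_fraction(values, units, str(path))
    matrices = []
    for period in TRANSITION_PERIODS:
        block = df[df["period"] == period.value]
        if len(block) != 3:
            raise ValueError(f"{path}: expected 3 rows for period {period.value}")
        rows = np.zeros((3, 3))
        for _, r in block.iterrows():
            state = r["from_state"]
            if state not in _STATE_BY_NAME:
                raise ValueError(f"{path}: unknown state label {state!r}")
            rows[LIVING_STATES.index(_STATE_BY_NAME[state])] = values[r.name]
        matrices.append(PeriodTransitionMatrix(period, rows))
    return TransitionSchedule(tuple(matrices))


def write_transition_csv(schedule: TransitionSchedule, path: str | Path) -> None:
    path = Path(path)
    rows = []
    for m in schedule.matrices:
        for origin in LIVING_STATES:
            r = m.row(origin)
            rows.append(
                {
                    "period": m.period.value,
                    "from_state": origin.value,
                    "to_normal": r[0],
                    "to_suspicious": r[1],
                    "to_high_risk": r[2],
                }
            )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# units=fraction\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


def read_initial_csv(path: str | Path) -> StateDistribution:
    """Read an initial distribution: columns state, share."""
    path = Path(path)
    units, skip = _read_units_header(path)
    df = pd.read_csv(path, skiprows=skip)
    if not {"state", "share"} <= set(df.columns):
        raise ValueError(f"{path}: need columns state, share")
    shares = _to_fraction(df["share"].to_numpy(dtype=float), units, str(path))
    by_state = {}
    for label, share in zip(df["state"], shares):
        if label not in _STATE_BY_NAME:
            raise ValueError(f"{path}: unknown state label {label!r}")
        by_state[_STATE_BY_NAME[label]] = float(share)
    return StateDistribution(
        by_state.get(HealthState.NORMAL, 0.0),
        by_state.get(HealthState.SUSPICIOUS, 0.0),
        by_state.get(HealthState.HIGH_RISK, 0.0),
    )


def write_initial_csv(dist: StateDistribution, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# units=fraction\n")
        pd.DataFrame(
            {
                "state": [s.value for s in LIVING_STATES],
                "share": [dist.share(s) for s in LIVING_STATES],
            }
        ).to_csv(fh, index=False)


def read_param_specs_csv(path: str | Path) -> list[ParamSpec]:
    """Read the uncertain-parameter table.

    Columns: name, base, low, high, dist (beta|gamma|none), mean, sd
    (mean/sd blank for dist=none).
    """
    df = pd.read_csv(path)
    required = {"name", "base", "low", "high", "dist"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    specs = []
    for _, r in df.iterrows():
        kind = DistKind(str(r["dist"]).strip().lower())
        mean = None if kind is DistKind.NONE else float(r["mean"])
        sd = None if kind is DistKind.NONE else float(r["sd"])
        specs.append(
            ParamSpec(str(r["name"]), float(r["base"]), float(r["low"]), float(r["high"]), kind, mean, sd)
        )
    return specs


def write_param_specs_csv(specs: Sequence[ParamSpec], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "name": p.name,
                "base": p.base,
                "low": p.low,
                "high": p.high,
                "dist": p.dist_kind.value,
                "mean": p.mean,
                "sd": p.sd,
            }
            for p in specs
        ]
    ).to_csv(path, index=False)


def read_cohort_csv(
    path: str | Path, thresholds: CategoryThresholds = CategoryThresholds()
) -> list[Trajectory]:
    """Read a longitudinal cohort.

    Either per-visit scores (id, score_13w .. score_d42; blank = missing),
    which are collapsed to periods and categorized, or pre-categorized
    periods (id, cat_t1 .. cat_t4 with state labels).
    """
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ValueError(f"{path}: need an 'id' column")
    if set(_SCORE_COLUMNS) <= set(df.columns):
        out = []
        for _, r in df.iterrows():
            visit_scores = {
                col.removeprefix("score_"): (None if pd.isna(r[col]) else float(r[col]))
                for col in _SCORE_COLUMNS
            }
            period_scores = collapse_to_periods(visit_scores)
            out.append(Trajectory.from_scores(str(r["id"]), period_scores, thresholds))
        return out
    if set(_CAT_COLUMNS) <= set(df.columns):
        out = []
        for _, r in df.iterrows():
            states: dict[PerinatalPeriod, HealthState | None] = {}
            for col, period in zip(_CAT_COLUMNS, ALL_PERIODS):
                v = r[col]
                if pd.isna(v) or v == "":
                    states[period] = None
                elif str(v) in _STATE_BY_NAME:
                    states[period] = _STATE_BY_NAME[str(v)]
                else:
                    raise ValueError(f"{path}: unknown category {v!r} in {col}")
            out.append(Trajectory(str(r["id"]), states))
        return out
    raise ValueError(
        f"{path}: need either score columns {_SCORE_COLUMNS} or category columns {_CAT_COLUMNS}"
    )


def write_cohort_csv(trajectories: Iterable[Trajectory], path: str | Path) -> None:
    """Write a cohort in the dialect ``read_cohort_csv`` accepts.

    With scores present, each period score is written to both visits of its
    pair (their mean collapses back to the same period score); otherwise
    the pre-categorized dialect is used.
    """
    trajectories = list(trajectories)
    with_scores = all(t.scores is not None for t in trajectories)
    rows = []
    if with_scores:
        pairs = {
            PerinatalPeriod.FIRST_TRIMESTER: ["score_13w"],
            PerinatalPeriod.SECOND_TRIMESTER: ["score_17w", "score_24w"],
            PerinatalPeriod.THIRD_TRIMESTER: ["score_31w", "score_37w"],
            PerinatalPeriod.POSTPARTUM: ["score_d3", "score_d42"],
        }
        for t in trajectories:
            row: dict[str, object] = {"id": t.subject_id}
            assert t.scores is not None
            for period, cols in pairs.items():
                score = t.scores.get(period)
                for col in cols:
                    row[col] = "" if score is None else score
            rows.append(row)
        pd.DataFrame(rows, columns=["id", *_SCORE_COLUMNS]).to_csv(path, index=False)
    else:
        for t in trajectories:
            row = {"id": t.subject_id}
            for col, period in zip(_CAT_COLUMNS, ALL_PERIODS):
                s = t.state(period)
                row[col] = "" if s is None else s.value
            rows.append(row)
        pd.DataFrame(rows, columns=["id", *_CAT_COLUMNS]).to_csv(path, index=False)


def write_dsa_csv(records: Sequence[DSARecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "name": r.name,
                "outcome_at_low": r.outcome_at_low,
                "outcome_at_high": r.outcome_at_high,
                "spread": r.spread,
                "error": r.error,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def write_psa_csv(psa: PSAResult, draws_path: str | Path, summary_path: str | Path) -> None:
    pd.DataFrame(
        {
            "delta_cost": psa.delta_cost,
            "delta_qalys": psa.delta_qalys,
            "reference_cost": psa.reference_cost,
            "reference_qalys": psa.reference_qalys,
            "comparator_cost": psa.comparator_cost,
            "comparator_qalys": psa.comparator_qalys,
        }
    ).to_csv(draws_path, index=False)
    pd.DataFrame(
        [
            {
                "n": psa.n,
                "seed": psa.seed,
                "wtp": psa.wtp,
                "mean_reference_cost": psa.mean_reference_cost,
                "mean_reference_qalys": psa.mean_reference_qalys,
                "mean_comparator_cost": psa.mean_comparator_cost,
                "mean_comparator_qalys": psa.mean_comparator_qalys,
                "fraction_cost_effective": psa.fraction_cost_effective(),
            }
        ]
    ).to_csv(summary_path, index=False)


def write_cohort_summary_csv(summary: CohortSummary, path: str | Path) -> None:
    row: dict[str, float | int] = {
        "n_complete": summary.n_complete,
        "always_normal": summary.always_normal,
        "ever_positive": summary.ever_positive,
        "persistent_positive": summary.persistent_positive,
        "persistent_positive_of_ever": summary.persistent_positive_of_ever,
        "first_positive_postpartum": summary.first_positive_postpartum,
    }
    for p, rate in summary.detection_rates.items():
        row[f"detection_rate_{p.value}"] = rate
    pd.DataFrame([row]).to_csv(path, index=False)
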