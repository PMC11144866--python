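"""One-way deterministic and probabilistic sensitivity analysis.

The deterministic analysis sweeps each parameter to its low and high limit
(others at base) and ranks parameters by outcome spread — the tornado
ordering.  The probabilistic analysis draws parameters jointly and
independently from moment-fitted distributions (Beta for utilities, Gamma
for costs and counts, the default families in health-economics modelling)
and pushes each draw through the full two-arm model.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .cua import CUAComparison

__all__ = [
    "DistKind",
    "ParamSpec",
    "DSARecord",
    "PSAResult",
    "fit_beta_moments",
    "fit_gamma_moments",
    "one_way_dsa",
    "run_psa",
    "ceac",
]

logger = logging.getLogger(__name__)

#: A model builder maps a {parameter name: value} override mapping to the
#: full two-arm incremental comparison.
ModelBuilder = Callable[[Mapping[str, float]], CUAComparison]


class DistKind(enum.Enum):
    BETA = "beta"
    GAMMA = "gamma"
    NONE = "none"


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain parameter: deterministic range and/or PSA distribution.

    ``base``, ``low`` and ``high`` drive the one-way analysis; ``mean`` and
    ``sd`` parameterize the PSA distribution when ``dist_kind`` is BETA or
    GAMMA (method-of-moments fit).  Parameters with ``dist_kind`` NONE are
    held at ``base`` during PSA.
    """

    name: str
    base: float
    low: float
    high: float
    dist_kind: DistKind = DistKind.NONE
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(
                f"{self.name}: need low <= base <= high, got "
                f"{self.low}/{self.base}/{self.high}"
            )
        if self.dist_kind is not DistKind.NONE:
            if self.mean is None or self.sd is None:
                raise ValueError(f"{self.name}: {self.dist_kind.value} needs mean and sd")
            if self.sd < 0:
                raise ValueError(f"{self.name}: sd must be nonnegative")
            if self.dist_kind is DistKind.BETA and not 0.0 < self.mean < 1.0:
                raise ValueError(f"{self.name}: Beta mean must lie in (0, 1)")


@dataclass(frozen=True)
class DSARecord:
    """Outcome at the low and high limit of one parameter, and the spread."""

    name: str
    outcome_at_low: float | None
    outcome_at_high: float | None
    spread: float
    error: str | None = None


@dataclass(frozen=True)
class PSAResult:
    """Monte Carlo draws through the two-arm model.

    ``delta_cost``/``delta_qalys`` are comparator-minus-reference per draw
    (routine minus screening under the default wiring); the cost-effective
    fraction counts draws where the reference (screening) arm has the
    higher net monetary benefit at ``wtp``.
    """

    n: int
    seed: int
    wtp: float
    delta_cost: np.ndarray
    delta_qalys: np.ndarray
    reference_cost: np.ndarray
    reference_qalys: np.ndarray
    comparator_cost: np.ndarray
    comparator_qalys: np.ndarray
    draws: dict[str, np.ndarray]

    @property
    def mean_reference_cost(self) -> float:
        return float(self.reference_cost.mean())

    @property
    def mean_reference_qalys(self) -> float:
        return float(self.reference_qalys.mean())

    @property
    def mean_comparator_cost(self) -> float:
        return float(self.comparator_cost.mean())

    @property
    def mean_comparator_qalys(self) -> float:
        return float(self.comparator_qalys.mean())

    def fraction_cost_effective(self, wtp: float | None = None) -> float:
        """Fraction of draws preferring the reference arm at ``wtp``.

        A draw prefers the reference when the comparator's incremental NMB,
        wtp x delta_qalys - delta_cost, is nonpositive — equivalently the
        draw lies on the reference side of the WTP line through the origin
        of the incremental cost-effectiveness plane.
        """
        w = self.wtp if wtp is None else wtp
        if w < 0:
            raise ValueError("wtp must be nonnegative")
        inmb = w * self.delta_qalys - self.delta_cost
        return float(np.mean(inmb <= 0.0))


def fit_beta_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments Beta(alpha, beta) fit to a mean and SD.

    alpha = mean * k, beta = (1 - mean) * k with
    k = mean (1 - mean) / sd^2 - 1; feasible only when sd^2 < mean(1-mean).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError("Beta mean must lie in (0, 1)")
    if sd <= 0:
        raise ValueError("sd must be positive")
    if sd * sd >= mean * (1.0 - mean):
        raise ValueError(
            f"infeasible moments: sd^2 = {sd * sd:.4g} >= mean(1-mean) = "
            f"{mean * (1.0 - mean):.4g}"
        )
    k = mean * (1.0 - mean) / (sd * sd) - 1.0
    return mean * k, (1.0 - mean) * k


def fit_gamma_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments Gamma fit; returns (shape, scale)."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return shape, scale


def one_way_dsa(
    model_builder: ModelBuilder,
    params: Sequence[ParamSpec],
    outcome_selector: Callable[[CUAComparison], float],
) -> list[DSARecord]:
    """Sweep each parameter to its limits and rank by spread (tornado order).

    The ranking is deterministic and invariant to the listing order of
    ``params`` (ties broken alphabetically).  A builder failure at one
    limit is recorded on that parameter's record and the sweep continues.
    """
    records: list[DSARecord] = []
    for p in params:
        values: list[float | None] = []
        error: str | None = None
        for limit in (p.low, p.high):
            try:
                values.append(float(outcome_selector(model_builder({p.name: limit}))))
            except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                values.append(None)
                error = f"{type(exc).__name__}: {exc}"
                logger.warning("DSA evaluation failed for %s at %s: %s", p.name, limit, exc)
        lo, hi = values
        spread = abs(hi - lo) if lo is not None and hi is not None else 0.0
        records.append(DSARecord(p.name, lo, hi, spread, error))
    return sorted(records, key=lambda r: (-r.spread, r.name))


def _sample_param(rng: np.random.Generator, p: ParamSpec, n: int) -> np.ndarray:
    if p.dist_kind is DistKind.NONE:
        return np.full(n, p.base)
    assert p.mean is not None and p.sd is not None
    if p.sd == 0:
        return np.full(n, p.mean)
    if p.dist_kind is DistKind.BETA:
        alpha, beta = fit_beta_moments(p.mean, p.sd)
        return rng.beta(alpha, beta, n)
    shape, scale = fit_gamma_moments(p.mean, p.sd)
    return rng.gamma(shape, scale, n)


def run_psa(
    model_builder: ModelBuilder,
    params: Sequence[ParamSpec],
    n: int,
    seed: int,
    wtp: float,
) -> PSAResult:
    """Monte Carlo probabilistic sensitivity analysis.

    Draws are independent across parameters (no correlation structure is
    imposed) and reproducible bit-for-bit from ``seed``.  Distribution
    feasibility is checked before any model evaluation.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    # fail fast on infeasible moments, before burning any draws
    for p in params:
        if p.dist_kind is DistKind.BETA and p.sd:
            fit_beta_moments(p.mean, p.sd)  # type: ignore[arg-type]
        elif p.dist_kind is DistKind.GAMMA and p.sd:
            fit_gamma_moments(p.mean, p.sd)  # type: ignore[arg-type]

    rng = np.random.default_rng(seed)
    draws = {p.name: _sample_param(rng, p, n) for p in params}

    dc = np.empty(n)
    dq = np.empty(n)
    rc = np.empty(n)
    rq = np.empty(n)
    cc = np.empty(n)
    cq = np.empty(n)
    for i in range(n):
        comparison = model_builder({name: float(v[i]) for name, v in draws.items()})
        dc[i] = comparison.delta_cost
        dq[i] = comparison.delta_qalys
        rc[i] = comparison.reference.cost
        rq[i] = comparison.reference.qalys
        cc[i] = comparison.comparator.cost
        cq[i] = comparison.comparator.qalys
    return PSAResult(
        n=n,
        seed=seed,
        wtp=wtp,
        delta_cost=dc,
        delta_qalys=dq,
        reference_cost=rc,
        reference_qalys=rq,
        comparator_cost=cc,
        comparator_qalys=cq,
        draws=draws,
    )


def ceac(psa: PSAResult, wtp_grid: Iterable[float]) -> list[tuple[float, float]]:
    """Cost-effectiveness acceptability curve over a WTP grid.

    At each threshold, the fraction of draws for which the reference arm is
    preferred, by the same rule as ``PSAResult.fraction_cost_effective``.
    """
    grid = [float(w) for w in wtp_grid]
    if not grid:
        raise ValueError("wtp_grid must be nonempty")
    if any(w < 0 for w in grid):
        raise ValueError("wtp values must be nonnegative")
    if grid != sorted(grid):
        raise ValueError("wtp_grid must be ascending")
    return [(w, psa.fraction_cost_effective(w)) for w in grid]
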