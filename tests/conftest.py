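import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import periscreen as ps
from periscreen.states import (
    TRANSITION_PERIODS,
    PeriodTransitionMatrix,
    Semantics,
    StateDistribution,
    TransitionSchedule,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params():
    """The built-in base-case two-arm model."""
    return ps.reference_parameters()


@pytest.fixture(scope="session")
def base_traces(params):
    strategies = ps.build_strategies(params)
    return {name: ps.roll_forward(s) for name, s in strategies.items()}


def identity_schedule(semantics: Semantics = Semantics.ANCHORED) -> TransitionSchedule:
    return TransitionSchedule(
        tuple(PeriodTransitionMatrix(p, np.eye(3)) for p in TRANSITION_PERIODS),
        semantics,
    )


def make_schedule(rows, semantics: Semantics = Semantics.ANCHORED) -> TransitionSchedule:
    """Build a schedule from one 3x3 row set or three of them."""
    rows = np.asarray(rows, dtype=float)
    if rows.shape == (3, 3):
        rows = np.stack([rows] * 3)
    return TransitionSchedule(
        tuple(
            PeriodTransitionMatrix(p, rows[i]) for i, p in enumerate(TRANSITION_PERIODS)
        ),
        semantics,
    )


def uniform_distribution() -> StateDistribution:
    return StateDistribution(1 / 3, 1 / 3, 1 / 3)
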