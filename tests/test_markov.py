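"""Markov engine: transitions, mortality, roll-forward, cost accrual."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import periscreen as ps
from periscreen.states import (
    HealthState,
    PerinatalPeriod,
    PeriodTransitionMatrix,
    Semantics,
    StateDistribution,
    validate_transition_matrix,
)
from conftest import identity_schedule, make_schedule

N, S, H = HealthState.NORMAL, HealthState.SUSPICIOUS, HealthState.HIGH_RISK

UTIL = {N: 0.86, S: 0.80, H: 0.63}
SCREEN_COSTS = {N: 19.0, S: 84.0, H: 820.32}
ROUTINE_COSTS = {N: 0.0, S: 0.0, H: 829.48}


def strategy(initial, schedule, costs=SCREEN_COSTS, utilities=UTIL, **kw):
    return ps.StrategyDefinition(
        name="test",
        initial=initial,
        schedule=schedule,
        state_cycle_costs=costs,
        state_utilities=utilities,
        **kw,
    )


class TestValidation:
    def test_identity_matrix_is_clean(self):
        m = PeriodTransitionMatrix(PerinatalPeriod.SECOND_TRIMESTER, np.eye(3))
        assert validate_transition_matrix(m) == []

    def test_deficient_row_mass_above_band_passes(self):
        # follow-up loss leaving 95.8% of the row accounted for is tolerated
        rows = np.array([[0.934, 0.021, 0.003]] * 3)
        m = PeriodTransitionMatrix(PerinatalPeriod.SECOND_TRIMESTER, rows)
        assert validate_transition_matrix(m) == []

    def test_row_sum_above_one_errors(self):
        rows = np.array([[0.7, 0.5, 0.1], [1, 0, 0], [1, 0, 0]])
        m = PeriodTransitionMatrix(PerinatalPeriod.SECOND_TRIMESTER, rows)
        issues = validate_transition_matrix(m)
        assert any(i.level == "error" and "1.3" in i.message for i in issues)

    def test_heavy_loss_warns(self):
        rows = np.array([[0.5, 0.2, 0.1], [1, 0, 0], [1, 0, 0]])
        m = PeriodTransitionMatrix(PerinatalPeriod.SECOND_TRIMESTER, rows)
        issues = validate_transition_matrix(m)
        assert any(i.level == "warning" for i in issues)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="3x3"):
            PeriodTransitionMatrix(PerinatalPeriod.SECOND_TRIMESTER, np.eye(4))


class TestApplyTransition:
    def test_identity_preserves_distribution(self):
        d = StateDistribution(0.5, 0.3, 0.1, dead=0.1)
        m = PeriodTransitionMatrix(PerinatalPeriod.SECOND_TRIMESTER, np.eye(3))
        out = ps.apply_transition(d, m)
        assert out == d

    def test_screening_baseline_step(self, params):
        out = ps.apply_transition(
            params.screening_initial,
            params.screening_schedule.matrix(PerinatalPeriod.SECOND_TRIMESTER),
        )
        assert out.living == pytest.approx([0.952075, 0.039065, 0.008125], abs=1e-9)

    def test_routine_baseline_step_carries_followup_loss(self, params):
        out = ps.apply_transition(
            params.routine_initial,
            params.routine_schedule.matrix(PerinatalPeriod.SECOND_TRIMESTER),
        )
        assert out.living == pytest.approx([0.850139, 0.102159, 0.017126], abs=1e-9)
        assert out.total == pytest.approx(0.969424, abs=1e-9)


class TestApplyMortality:
    def test_zero_rate_is_identity(self):
        d = StateDistribution(0.9, 0.05, 0.05)
        assert ps.apply_mortality(d, 0.0) == d

    def test_full_transfer(self):
        d = StateDistribution(0.9, 0.05, 0.05)
        out = ps.apply_mortality(d, 1.0)
        assert out.high_risk == 0.0
        assert out.dead == pytest.approx(0.05)

    def test_partial_transfer_conserves_mass(self):
        d = StateDistribution(0.7, 0.15, 0.077)
        out = ps.apply_mortality(d, 0.04)
        assert out.dead == pytest.approx(0.04 * 0.077)
        assert out.total == pytest.approx(d.total)

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ps.apply_mortality(StateDistribution(1, 0, 0), 1.5)


class TestRollForward:
    def test_static_cohort_accrues_flat_utility(self):
        s = strategy(StateDistribution(1, 0, 0), identity_schedule())
        trace = ps.roll_forward(s)
        assert trace.total_qalys == pytest.approx(4 * 0.86 * 0.25)

    def test_screening_arm_total_qalys(self, base_traces):
        t = base_traces["screening"]
        assert t.total_qalys == pytest.approx(0.8516811, abs=1e-6)
        assert round(t.total_qalys, 2) == 0.85

    def test_routine_arm_total_qalys(self, base_traces):
        t = base_traces["routine"]
        assert t.total_qalys == pytest.approx(0.8365715, abs=1e-6)
        assert round(t.total_qalys, 2) == 0.84

    def test_totals_equal_cycle_sums(self, base_traces):
        for t in base_traces.values():
            assert t.total_cost == pytest.approx(sum(t.cycle_costs))
            assert t.total_qalys == pytest.approx(sum(t.cycle_qalys))

    def test_anchored_and_chained_agree_at_cycle_two(self, params):
        for sched, init in (
            (params.screening_schedule, params.screening_initial),
            (params.routine_schedule, params.routine_initial),
        ):
            a = ps.roll_forward(strategy(init, sched.with_semantics(Semantics.ANCHORED)))
            c = ps.roll_forward(strategy(init, sched.with_semantics(Semantics.CHAINED)))
            np.testing.assert_allclose(
                a.distributions[1].living, c.distributions[1].living, atol=1e-12
            )

    def test_two_state_toy_matches_closed_form(self):
        # 2 living states (high-risk share 0), chained: pi_t = pi_0 M^t.
        # Closed-form expansion of total QALYs for M=[[1-a,a],[b,1-b]].
        a, b = 0.2, 0.5
        rows = np.array([[1 - a, a, 0], [b, 1 - b, 0], [0, 0, 1]])
        init = StateDistribution(0.7, 0.3, 0.0)
        s = strategy(init, make_schedule(rows, Semantics.CHAINED))
        trace = ps.roll_forward(s)
        M = np.array([[1 - a, a], [b, 1 - b]])
        pi = np.array([0.7, 0.3])
        u = np.array([0.86, 0.80])
        expected = sum(float(pi @ np.linalg.matrix_power(M, t) @ u) * 0.25 for t in range(4))
        assert trace.total_qalys == pytest.approx(expected, abs=1e-12)

    def test_mortality_moves_mass_to_death(self, params):
        s = strategy(
            params.routine_initial,
            params.routine_schedule.with_semantics(Semantics.CHAINED).normalized(),
            high_risk_mortality=0.04,
        )
        trace = ps.roll_forward(s)
        assert trace.distributions[-1].dead > 0
        for d in trace.distributions:
            assert d.total == pytest.approx(1.0, abs=1e-9)

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
        st.floats(0.0, 0.2),
    )
    def test_mass_conserved_with_stochastic_rows(self, raw, mortality):
        # row-stochastic matrices + mortality: living+dead mass is constant
        rng = np.random.default_rng(int(sum(raw) * 1e6) % 2**31)
        rows = rng.random((3, 3)) + 0.01
        rows /= rows.sum(axis=1, keepdims=True)
        init = np.array(raw) / sum(raw)
        s = strategy(
            StateDistribution(*init),
            make_schedule(rows, Semantics.CHAINED),
            high_risk_mortality=mortality,
        )
        for d in ps.roll_forward(s).distributions:
            assert d.total == pytest.approx(1.0, abs=1e-9)

    @given(st.floats(0.0, 1.0))
    def test_qalys_monotone_in_utility(self, u_high):
        init = StateDistribution(0.5, 0.3, 0.2)
        base = strategy(init, identity_schedule(), utilities={N: 0.86, S: 0.80, H: 0.0})
        bumped = strategy(init, identity_schedule(), utilities={N: 0.86, S: 0.80, H: u_high})
        assert ps.roll_forward(bumped).total_qalys >= ps.roll_forward(base).total_qalys

    def test_qalys_bounded_by_max_utility(self, base_traces, params):
        cap = max(params.utilities.values()) * 4 * 0.25
        for t in base_traces.values():
            assert 0.0 <= t.total_qalys <= cap

    def test_invalid_matrix_rejected_at_rollforward(self):
        rows = np.array([[0.7, 0.5, 0.1], [1, 0, 0], [1, 0, 0]])
        s = strategy(StateDistribution(1, 0, 0), make_schedule(rows))
        with pytest.raises(ValueError, match="invalid"):
            ps.roll_forward(s)

    def test_renormalize_restores_unit_mass(self, params):
        s = strategy(params.routine_initial, params.routine_schedule)
        trace = ps.roll_forward(s, renormalize=True)
        for d in trace.distributions:
            assert d.total == pytest.approx(1.0, abs=1e-9)


class TestAccrueCosts:
    def test_zero_costs_zero_total(self, base_traces):
        per_cycle, total = ps.accrue_costs(
            base_traces["screening"], {N: 0.0, S: 0.0, H: 0.0}
        )
        assert total == 0.0

    def test_screening_first_cycle_cost(self, base_traces):
        per_cycle, _ = ps.accrue_costs(base_traces["screening"], SCREEN_COSTS)
        assert per_cycle[0] == pytest.approx(52.25, abs=0.005)

    def test_routine_first_cycle_cost(self, base_traces):
        per_cycle, _ = ps.accrue_costs(base_traces["routine"], ROUTINE_COSTS)
        assert per_cycle[0] == pytest.approx(63.87, abs=0.005)

    def test_cost_monotone_in_state_cost(self, base_traces):
        t = base_traces["screening"]
        _, lo = ps.accrue_costs(t, {N: 19.0, S: 84.0, H: 500.0})
        _, hi = ps.accrue_costs(t, {N: 19.0, S: 84.0, H: 900.0})
        assert hi >= lo

    def test_negative_cost_rejected(self, base_traces):
        with pytest.raises(ValueError):
            ps.accrue_costs(base_traces["screening"], {N: -1.0, S: 0.0, H: 0.0})
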