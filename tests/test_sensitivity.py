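"""Moment fitting, tornado ordering, Monte Carlo PSA and the CEAC."""

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st
from scipy import stats

import periscreen as ps
from periscreen.cua import StrategyOutcome, incremental_analysis
from periscreen.sensitivity import DistKind


class TestBetaMoments:
    def test_symmetric_case(self):
        assert ps.fit_beta_moments(0.5, 0.1) == pytest.approx((12.0, 12.0))

    @pytest.mark.parametrize(
        "mean, sd, expected",
        [
            (0.86, 0.09, (11.9232, 1.9410)),  # normal-state utility
            (0.63, 0.15, (5.8968, 3.4632)),  # high-risk utility
            (0.80, 0.08, (19.2, 4.8)),  # suspicious utility
        ],
    )
    def test_surveyed_utilities(self, mean, sd, expected):
        alpha, beta = ps.fit_beta_moments(mean, sd)
        assert (alpha, beta) == pytest.approx(expected, abs=5e-4)
        # independent check: analytic moments of the fitted distribution
        m, v = stats.beta.stats(alpha, beta, moments="mv")
        assert m == pytest.approx(mean, rel=1e-12)
        assert np.sqrt(v) == pytest.approx(sd, rel=1e-12)

    def test_infeasible_moments_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            ps.fit_beta_moments(0.5, 0.6)

    @given(st.floats(0.05, 0.95), st.floats(0.01, 0.2))
    def test_round_trip(self, mean, sd):
        assume(sd * sd < mean * (1 - mean) * 0.99)
        alpha, beta = ps.fit_beta_moments(mean, sd)
        fitted_mean = alpha / (alpha + beta)
        fitted_var = alpha * beta / ((alpha + beta) ** 2 * (alpha + beta + 1))
        assert fitted_mean == pytest.approx(mean, rel=1e-9)
        assert np.sqrt(fitted_var) == pytest.approx(sd, rel=1e-9)


class TestGammaMoments:
    def test_exponential_boundary(self):
        shape, scale = ps.fit_gamma_moments(5.0, 5.0)
        assert shape == pytest.approx(1.0)
        assert scale == pytest.approx(5.0)

    @pytest.mark.parametrize(
        "mean, sd, expected",
        [
            (229.0, 209.41, (1.1958, 191.4958)),  # per-session treatment cost
            (3.33, 0.84, (15.7156, 0.2119)),  # treatment frequency
            (19.0, 21.83, (0.7575, 25.0815)),  # screening fee (SD > mean: shape < 1)
        ],
    )
    def test_surveyed_costs(self, mean, sd, expected):
        shape, scale = ps.fit_gamma_moments(mean, sd)
        assert (shape, scale) == pytest.approx(expected, abs=5e-4)
        m, v = stats.gamma.stats(shape, scale=scale, moments="mv")
        assert m == pytest.approx(mean, rel=1e-12)
        assert np.sqrt(v) == pytest.approx(sd, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ps.fit_gamma_moments(0.0, 1.0)

    @given(st.floats(0.1, 1e4), st.floats(0.1, 1e4))
    def test_round_trip(self, mean, sd):
        shape, scale = ps.fit_gamma_moments(mean, sd)
        assert shape * scale == pytest.approx(mean, rel=1e-9)
        assert np.sqrt(shape) * scale == pytest.approx(sd, rel=1e-9)


def linear_toy_builder(base_a=0.0, base_b=0.0):
    """Outcome 2a + b, exposed as the delta_cost of a synthetic comparison."""

    def builder(overrides):
        a = overrides.get("a", base_a)
        b = overrides.get("b", base_b)
        val = 2 * a + b
        ref = StrategyOutcome("ref", 0.0, 1.0)
        cmp_ = StrategyOutcome("cmp", max(val, 0.0), 1.0)
        return incremental_analysis(ref, cmp_)

    return builder


class TestOneWayDSA:
    def test_degenerate_range_has_zero_spread_and_ranks_last(self):
        specs = [
            ps.ParamSpec("a", 1.0, 0.0, 2.0),
            ps.ParamSpec("fixed", 1.0, 1.0, 1.0),
        ]
        records = ps.one_way_dsa(linear_toy_builder(), specs, lambda c: c.delta_cost)
        assert records[-1].name == "fixed"
        assert records[-1].spread == 0.0

    def test_toy_model_ordering(self):
        # outcome = 2a + b over ranges +/-1: spread 4 for a, 2 for b
        specs = [
            ps.ParamSpec("b", 2.0, 1.0, 3.0),
            ps.ParamSpec("a", 2.0, 1.0, 3.0),
        ]
        records = ps.one_way_dsa(linear_toy_builder(), specs, lambda c: c.delta_cost)
        assert [r.name for r in records] == ["a", "b"]
        assert records[0].spread == pytest.approx(4.0)
        assert records[1].spread == pytest.approx(2.0)

    def test_order_invariant_to_listing(self, params):
        specs = ps.reference_param_specs()
        builder = ps.model_builder_for(params)
        sel = lambda c: params.wtp * c.delta_qalys - c.delta_cost
        fwd = ps.one_way_dsa(builder, specs, sel)
        rev = ps.one_way_dsa(builder, list(reversed(specs)), sel)
        assert [r.name for r in fwd] == [r.name for r in rev]

    def test_discount_sweep_is_monotone(self, params):
        builder = ps.model_builder_for(params)
        # routine-arm cost grows with the conversion rate of the specialist cost
        costs = [
            builder({"discount_rate": r}).comparator.cost
            for r in np.linspace(0.0, 0.07, 8)
        ]
        assert all(b > a for a, b in zip(costs, costs[1:]))

    def test_builder_failure_recorded_not_fatal(self):
        def builder(overrides):
            if overrides.get("bad", 0) > 0:
                raise RuntimeError("boom")
            return linear_toy_builder()(overrides)

        specs = [ps.ParamSpec("bad", 0.0, 0.0, 1.0), ps.ParamSpec("a", 1.0, 0.0, 2.0)]
        records = ps.one_way_dsa(builder, specs, lambda c: c.delta_cost)
        by_name = {r.name: r for r in records}
        assert by_name["bad"].error is not None
        assert by_name["a"].error is None


class TestPSA:
    def test_same_seed_identical_results(self, params):
        builder = ps.model_builder_for(params)
        specs = ps.reference_param_specs()
        a = ps.run_psa(builder, specs, 40, seed=7, wtp=params.wtp)
        b = ps.run_psa(builder, specs, 40, seed=7, wtp=params.wtp)
        np.testing.assert_array_equal(a.delta_cost, b.delta_cost)
        np.testing.assert_array_equal(a.delta_qalys, b.delta_qalys)
        for name in a.draws:
            np.testing.assert_array_equal(a.draws[name], b.draws[name])

    def test_different_seed_differs(self, params):
        builder = ps.model_builder_for(params)
        specs = ps.reference_param_specs()
        a = ps.run_psa(builder, specs, 40, seed=7, wtp=params.wtp)
        b = ps.run_psa(builder, specs, 40, seed=8, wtp=params.wtp)
        assert not np.array_equal(a.delta_cost, b.delta_cost)

    def test_parameter_sample_means_converge(self):
        # 3-sigma standard-error bound at n = 10,000 on each drawn parameter
        specs = [p for p in ps.reference_param_specs() if p.dist_kind is not DistKind.NONE]

        def trivial(overrides):
            return incremental_analysis(
                StrategyOutcome("ref", 0.0, 1.0), StrategyOutcome("cmp", 0.0, 1.0)
            )

        psa = ps.run_psa(trivial, specs, 10_000, seed=11, wtp=1.0)
        for p in specs:
            draws = psa.draws[p.name]
            se = p.sd / np.sqrt(len(draws))
            assert abs(draws.mean() - p.mean) < 3 * se, p.name

    def test_degenerate_distributions_reproduce_base_case(self, params, base_traces):
        specs = [
            ps.ParamSpec(p.name, p.base, p.base, p.base, p.dist_kind, p.base, 0.0)
            if p.dist_kind is not DistKind.NONE
            else p
            for p in ps.reference_param_specs()
        ]
        psa = ps.run_psa(ps.model_builder_for(params), specs, 5, seed=1, wtp=params.wtp)
        assert psa.mean_reference_cost == pytest.approx(
            base_traces["screening"].total_cost, abs=1e-6
        )
        assert psa.mean_reference_qalys == pytest.approx(
            base_traces["screening"].total_qalys, abs=1e-6
        )
        assert psa.mean_comparator_cost == pytest.approx(
            base_traces["routine"].total_cost, abs=1e-6
        )
        assert psa.mean_comparator_qalys == pytest.approx(
            base_traces["routine"].total_qalys, abs=1e-6
        )

    def test_dominant_increments_always_cost_effective(self):
        # fixed increments (routine costs 50 more, yields 0.1 fewer QALYs):
        # the screening reference wins at any positive threshold
        def builder(overrides):
            return incremental_analysis(
                StrategyOutcome("ref", 100.0, 0.9), StrategyOutcome("cmp", 150.0, 0.8)
            )

        psa = ps.run_psa(builder, [ps.ParamSpec("x", 1, 0, 2)], 20, seed=3, wtp=80_976)
        assert psa.fraction_cost_effective() == 1.0
        assert psa.fraction_cost_effective(1.0) == 1.0

    def test_infeasible_distribution_fails_before_drawing(self, params):
        bad = [ps.ParamSpec("u", 0.5, 0.0, 1.0, DistKind.BETA, 0.5, 0.9)]
        with pytest.raises(ValueError, match="infeasible"):
            ps.run_psa(ps.model_builder_for(params), bad, 10, seed=1, wtp=1.0)


class TestCEAC:
    @staticmethod
    def _fixed_psa(delta_cost, delta_qalys, n=10):
        def builder(overrides):
            return incremental_analysis(
                StrategyOutcome("ref", 100.0, 0.85),
                StrategyOutcome("cmp", 100.0 + delta_cost, 0.85 + delta_qalys),
            )

        return ps.run_psa(builder, [ps.ParamSpec("x", 1, 0, 2)], n, seed=5, wtp=80_976)

    def test_all_reference_dominant_fraction_one(self):
        psa = self._fixed_psa(delta_cost=50.0, delta_qalys=-0.1)
        curve = ps.ceac(psa, [0.0, 10_000.0, 80_976.0])
        assert all(f == 1.0 for _, f in curve)

    def test_all_reference_dominated_fraction_zero(self):
        psa = self._fixed_psa(delta_cost=-50.0, delta_qalys=0.1)
        curve = ps.ceac(psa, [1_000.0, 80_976.0])
        assert all(f == 0.0 for _, f in curve)

    def test_mixed_dominance_fraction_is_count_ratio(self):
        toggle = {"i": 0}

        def builder(overrides):
            toggle["i"] += 1
            if toggle["i"] % 5 < 3:  # 60% of draws dominated comparator
                return incremental_analysis(
                    StrategyOutcome("ref", 100.0, 0.9), StrategyOutcome("cmp", 150.0, 0.8)
                )
            return incremental_analysis(
                StrategyOutcome("ref", 150.0, 0.8), StrategyOutcome("cmp", 100.0, 0.9)
            )

        psa = ps.run_psa(builder, [ps.ParamSpec("x", 1, 0, 2)], 100, seed=2, wtp=80_976)
        for _, f in ps.ceac(psa, [1.0, 50_000.0, 200_000.0]):
            assert f == pytest.approx(0.6)

    def test_empty_or_descending_grid_rejected(self):
        psa = self._fixed_psa(50.0, -0.1)
        with pytest.raises(ValueError):
            ps.ceac(psa, [])
        with pytest.raises(ValueError):
            ps.ceac(psa, [100.0, 50.0])
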