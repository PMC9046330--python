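"""Cohort engine: probability construction, traces and rewards."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fallscea as fc
from fallscea import Arm, HealthState, annual_to_cycle_prob
from fallscea.engine import build_transition_matrix, fall_outcome_distribution
from fallscea.states import TUNNEL_STATES

S = HealthState


class TestAnnualToCycleProb:
    @pytest.mark.parametrize(
        "p, f, expected",
        [
            (0.36, 0.25, 0.10557280900008414),  # 1 - 0.64**0.25
            (0.0, 0.25, 0.0),
            (1.0, 0.25, 1.0),
            (0.5, 1.0, 0.5),
        ],
    )
    def test_constant_rate_transform(self, p, f, expected):
        assert annual_to_cycle_prob(p, f) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_both_arguments(self):
        grid = np.linspace(0.0, 1.0, 21)
        vals = annual_to_cycle_prob(grid, 0.25)
        assert np.all(np.diff(vals) >= 0)
        fracs = np.linspace(0.05, 1.0, 20)
        vals = np.array([annual_to_cycle_prob(0.36, f) for f in fracs])
        assert np.all(np.diff(vals) > 0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            annual_to_cycle_prob(1.5, 0.25)
        with pytest.raises(ValueError):
            annual_to_cycle_prob(0.5, 0.0)


class TestFallOutcomeDistribution:
    def test_control_at_age_68(self, params):
        """Frozen values from independent branch-product enumeration."""
        dist = fall_outcome_distribution(params, Arm.CONTROL, 68.0)
        expected = {
            S.FRACTURE_MAJOR: 0.0712008,
            S.FRACTURE_MINOR: 0.0456,
            S.INJURY_MAJOR: 0.044466048,
            S.INJURY_MINOR: 0.727936,
            S.AT_RISK_RECURRENT: 0.1056,
            S.DEAD: 0.005197152,
        }
        for state, value in expected.items():
            assert dist[state] == pytest.approx(value, rel=1e-9), state
        assert dist[S.AT_RISK_FIRST] == 0.0
        assert dist.sum() == pytest.approx(1.0, abs=1e-12)

    def test_exercise_conditional_probabilities(self, params):
        """Marginal RRs for fracture, conditional RR for injury."""
        dist = fall_outcome_distribution(params, Arm.INTERVENTION, 68.0)
        q_fx = 0.12 * 0.44 / 0.76
        p_inj = 0.88 * 0.70
        pd = 0.043
        assert dist[S.FRACTURE_MAJOR] == pytest.approx(q_fx * 0.62 * (1 - pd), rel=1e-12)
        assert dist[S.FRACTURE_MINOR] == pytest.approx(q_fx * 0.38, rel=1e-12)
        assert dist[S.AT_RISK_RECURRENT] == pytest.approx((1 - q_fx) * (1 - p_inj), rel=1e-12)
        assert dist.sum() == pytest.approx(1.0, abs=1e-12)

    def test_only_major_events_can_be_fatal(self, params):
        certain_death = params.replace(
            p_death_fall_60_64=1.0, p_death_fall_65_69=1.0, p_death_fall_70_74=1.0
        )
        dist = fall_outcome_distribution(certain_death, Arm.CONTROL, 68.0)
        assert dist[S.FRACTURE_MAJOR] == 0.0
        assert dist[S.INJURY_MAJOR] == 0.0
        # minor branches are untouched: minor events are never fatal
        assert dist[S.FRACTURE_MINOR] == pytest.approx(0.12 * 0.38, rel=1e-12)
        assert dist[S.DEAD] == pytest.approx(
            0.12 * 0.62 + 0.88 * 0.88 * 0.06, rel=1e-12
        )

    def test_infeasible_decomposition_named(self, params):
        bad = params.replace(rr_fracture_exercise=9.0, rr_fall_exercise=0.9)
        with pytest.raises(fc.InfeasibleDecompositionError, match="fracture"):
            fall_outcome_distribution(bad, Arm.INTERVENTION, 68.0)


class TestTransitionMatrix:
    @pytest.mark.parametrize("arm", list(Arm))
    @pytest.mark.parametrize("cycle", [0, 5, 11])
    def test_rows_stochastic_and_structure(self, params, arm, cycle):
        M = build_transition_matrix(params, arm, cycle).probs
        assert np.allclose(M.sum(axis=-1), 1.0, atol=1e-12)
        assert np.all((M >= 0) & (M <= 1))
        # absent transitions are exactly zero
        assert np.all(M[:, S.AT_RISK_FIRST][np.arange(7) != S.AT_RISK_FIRST] == 0)
        for s in TUNNEL_STATES:
            allowed = np.zeros(7, bool)
            allowed[[S.AT_RISK_RECURRENT, S.DEAD]] = True
            assert np.all(M[s][~allowed] == 0)
        assert np.array_equal(M[S.DEAD], np.eye(7)[S.DEAD])

    def test_first_fall_probability_embedded(self, params):
        """The aggregate per-cycle fall probability matches the conversion."""
        M = build_transition_matrix(params, Arm.CONTROL, 0).probs
        dist = fall_outcome_distribution(params, Arm.CONTROL, 68.0)
        p_fall = M[S.AT_RISK_FIRST, S.FRACTURE_MAJOR] / dist[S.FRACTURE_MAJOR]
        assert p_fall == pytest.approx(0.10557280900008414, rel=1e-12)

    def test_exercise_reduces_first_falls_not_recurrent(self, params):
        Mc = build_transition_matrix(params, Arm.CONTROL, 0).probs
        Me = build_transition_matrix(params, Arm.INTERVENTION, 0).probs
        dc = fall_outcome_distribution(params, Arm.CONTROL, 68.0)
        de = fall_outcome_distribution(params, Arm.INTERVENTION, 68.0)
        pf_c = Mc[S.AT_RISK_FIRST, S.FRACTURE_MINOR] / dc[S.FRACTURE_MINOR]
        pf_e = Me[S.AT_RISK_FIRST, S.FRACTURE_MINOR] / de[S.FRACTURE_MINOR]
        assert pf_e == pytest.approx(annual_to_cycle_prob(0.36 * 0.76, 0.25), rel=1e-12)
        assert pf_e < pf_c
        # recurrent-fall hazard is arm-independent
        pr_c = Mc[S.AT_RISK_RECURRENT, S.FRACTURE_MINOR] / dc[S.FRACTURE_MINOR]
        pr_e = Me[S.AT_RISK_RECURRENT, S.FRACTURE_MINOR] / de[S.FRACTURE_MINOR]
        assert pr_c == pytest.approx(pr_e, rel=1e-12)
        assert pr_c == pytest.approx(annual_to_cycle_prob(0.65, 0.25), rel=1e-12)

    def test_cycle_index_bounds(self, params):
        with pytest.raises(ValueError):
            build_transition_matrix(params, Arm.CONTROL, 12)


class TestCohortTrace:
    def test_occupancy_conservation_and_start(self, params):
        for arm in Arm:
            trace = fc.run_cohort(params, arm)
            assert trace.occupancy.shape == (13, 7)
            assert trace.occupancy[0, S.AT_RISK_FIRST] == 1.0
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)

    def test_occupancy_is_repeated_matrix_product(self, params):
        trace = fc.run_cohort(params, Arm.CONTROL)
        occ = np.zeros(7)
        occ[S.AT_RISK_FIRST] = 1.0
        for t in range(12):
            occ = occ @ build_transition_matrix(params, Arm.CONTROL, t).probs
            assert np.allclose(trace.occupancy[t + 1], occ, atol=1e-12)

    def test_no_falls_no_divergence(self, params):
        """With no falls the arms differ only by the intervention cost."""
        quiet = params.replace(p_fall_year1=0.0, p_fall_recurrent=0.0)
        tc = fc.run_cohort(quiet, Arm.CONTROL)
        ti = fc.run_cohort(quiet, Arm.INTERVENTION)
        # FOF never applies: nobody reaches the recurrent state
        assert float(ti.total_qalys) == pytest.approx(float(tc.total_qalys), abs=1e-12)
        assert float(ti.total_cost) - float(tc.total_cost) == pytest.approx(
            quiet.c_intervention, abs=1e-9
        )

    def test_no_falls_no_mortality_gives_full_quality_time(self, params):
        """Undiscounted QALYs equal u_baseline * horizon exactly (2.37)."""
        still = params.replace(
            p_fall_year1=0.0,
            p_fall_recurrent=0.0,
            discount_annual=0.0,
            background_mortality={a: 0.0 for a in range(60, 76)},
        )
        for arm in Arm:
            trace = fc.run_cohort(still, arm)
            assert float(trace.total_qalys) == pytest.approx(0.79 * 3, abs=1e-12)
            assert float(trace.life_years_undiscounted) == pytest.approx(3.0, abs=1e-12)

    def test_discounting_strictly_shrinks_totals(self, params):
        undisc = params.replace(discount_annual=0.0)
        for arm in Arm:
            t0 = fc.run_cohort(undisc, arm)
            t5 = fc.run_cohort(params, arm)
            assert float(t5.total_qalys) < float(t0.total_qalys)
            assert float(t5.total_cost) < float(t0.total_cost) + (
                params.c_intervention if arm is Arm.INTERVENTION else 0.0
            )

    def test_life_years_bounded_by_horizon(self, params):
        trace = fc.run_cohort(params, Arm.CONTROL)
        assert 2.9 <= float(trace.life_years_undiscounted) <= 3.0

    def test_reward_monotonicity(self, params):
        base = fc.run_cohort(params, Arm.CONTROL)
        costlier = fc.run_cohort(params.replace(c_fx_major=30000), Arm.CONTROL)
        assert float(costlier.total_cost) > float(base.total_cost)
        happier = fc.run_cohort(params.replace(u_fx_major=0.6), Arm.CONTROL)
        assert float(happier.total_qalys) > float(base.total_qalys)

    def test_trace_frame_layout(self, params):
        frame = fc.trace_frame(fc.run_cohort(params, Arm.INTERVENTION))
        assert len(frame) == 13
        assert frame["cycle"].tolist() == list(range(13))
        assert frame["arm"].unique().tolist() == ["intervention"]
        assert frame["cumulative_cost"].iloc[-1] == pytest.approx(
            frame["discounted_cost"].sum()
        )
        # upfront intervention cost sits in cycle 0, undiscounted
        assert frame["discounted_cost"].iloc[0] == pytest.approx(767.0)

    def test_batched_parameters_match_scalar_runs(self, params):
        """Array-valued fields give the same totals as per-draw scalar runs."""
        values = np.array([0.30, 0.36, 0.42])
        batched = params.replace(p_fall_year1=values)
        bt = fc.run_cohort(batched, Arm.CONTROL)
        for i, v in enumerate(values):
            st_ = fc.run_cohort(params.replace(p_fall_year1=float(v)), Arm.CONTROL)
            assert float(bt.total_cost[i]) == pytest.approx(float(st_.total_cost), rel=1e-12)
            assert float(bt.total_qalys[i]) == pytest.approx(float(st_.total_qalys), rel=1e-12)


@st.composite
def random_parameters(draw):
    """Arbitrary valid parameter sets for property tests."""
    base = fc.load_parameters()
    p_fx_major = draw(st.floats(0.05, 0.95))
    p_inj_major = draw(st.floats(0.05, 0.95))
    rr_fall = draw(st.floats(0.3, 1.2))
    # keep the exercise-arm conditional fracture probability below 1
    rr_fracture = draw(st.floats(0.1, rr_fall))
    return base.replace(
        p_fall_year1=draw(st.floats(0.0, 0.9)),
        p_fall_recurrent=draw(st.floats(0.0, 0.95)),
        rr_fall_exercise=rr_fall,
        p_fracture_annual=draw(st.floats(0.0, 0.9)),
        rr_fracture_exercise=rr_fracture,
        p_fx_major=p_fx_major,
        p_fx_minor=1.0 - p_fx_major,
        p_nonfx_injury=draw(st.floats(0.0, 1.0)),
        rr_injury_exercise=draw(st.floats(0.1, 1.0)),
        p_inj_major=p_inj_major,
        p_inj_minor=1.0 - p_inj_major,
        u_baseline=draw(st.floats(0.1, 1.0)),
        discount_annual=draw(st.floats(0.0, 0.1)),
    )


@settings(max_examples=60, deadline=None, derandomize=True)
@given(random_parameters())
def test_conservation_under_arbitrary_valid_parameters(rparams):
    """Occupancy rows sum to 1 within 1e-9, both arms, every cycle."""
    for arm in Arm:
        trace = fc.run_cohort(rparams, arm)
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(trace.occupancy >= -1e-15)
        assert float(trace.life_years_undiscounted) <= rparams.horizon_years + 1e-9
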