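"""Cohort engine: transition math, conservation, discounting, accrual."""

import dataclasses

import pytest

from milkcea.engine import (ARMS, StateVector, cost_accrual, cycle_probabilities,
                            cycle_transition, escalate_probability,
                            multipliers_for_arm, run_all_cohorts, run_cohort,
                            utility_accrual)
from milkcea.params import DomainError

from conftest import constant_epi_table, with_settings


class TestEscalation:
    @pytest.mark.parametrize("p0, rate, t, expected", [
        (0.2, 0.0, 5, 0.2),        # zero rate is the identity
        (0.1, 0.05, 2, 0.11025),   # closed form
        (0.9, 0.5, 10, 1.0),       # capped at certainty
    ])
    def test_closed_form(self, p0, rate, t, expected):
        assert escalate_probability(p0, rate, t) == pytest.approx(expected, abs=1e-12)

    def test_rate_below_minus_one_rejected(self):
        with pytest.raises(DomainError):
            escalate_probability(0.5, -1.5, 1)


class TestCycleProbabilities:
    def test_age_62_stroke_risk_before_competition(self, params):
        # 2000/100,000 at 60-64 in the do-nothing arm
        p = cycle_probabilities(params, multipliers_for_arm(params, "do-nothing"), 62)
        assert p["well_p_stroke"] == pytest.approx(0.02)
        assert p["well_cf_stroke"] == pytest.approx(0.2170)

    def test_intervention_scales_incidence_not_fatality(self, params):
        base = cycle_probabilities(params, multipliers_for_arm(params, "do-nothing"), 62)
        trt = cycle_probabilities(params, multipliers_for_arm(params, "intervention"), 62)
        assert trt["well_p_stroke"] == pytest.approx(base["well_p_stroke"] * 0.8089)
        assert trt["well_cf_stroke"] == base["well_cf_stroke"]
        assert trt["chr_p_mi"] == pytest.approx(base["chr_p_mi"] * 0.8489)


class TestCycleTransition:
    def test_absorbing_free_identity(self, zero_risk_params):
        state = StateVector(0.9, 0.1, 0.0, 0.0)
        mult = multipliers_for_arm(zero_risk_params, "do-nothing")
        nxt, rec = cycle_transition(state, 50, zero_risk_params, mult)
        assert nxt == state
        assert rec.mi_events == rec.stroke_events == 0

    def test_degenerate_certain_fatal_stroke(self, zero_risk_params):
        ps = zero_risk_params.replace(
            epi_well=constant_epi_table("well", stroke_incidence=100_000,
                                        stroke_cf28=100.0))
        mult = multipliers_for_arm(ps, "do-nothing")
        state = StateVector(1.0, 0.0, 0.0, 0.0)
        nxt, rec = cycle_transition(state, 50, ps, mult)
        assert nxt.dead_cvd == pytest.approx(1.0)
        assert rec.stroke_events == pytest.approx(1.0)
        assert rec.stroke_deaths == pytest.approx(1.0)

    def test_events_at_least_attributed_deaths(self, params):
        mult = multipliers_for_arm(params, "do-nothing")
        state = StateVector(0.5, 0.5, 0.0, 0.0)
        _, rec = cycle_transition(state, 70, params, mult)
        assert rec.stroke_events >= rec.stroke_deaths
        assert rec.mi_events >= rec.mi_deaths


class TestRunCohort:
    def test_single_cycle_well_utility_identity(self, zero_risk_params):
        ps = with_settings(zero_risk_params, horizon=1)
        tr = run_cohort("do-nothing", 50, ps)
        assert tr.total_qaly == pytest.approx(1.0)
        assert tr.total_cost == pytest.approx(0.0)

    def test_state_conservation_every_cycle(self, params):
        for arm in ARMS:
            tr = run_cohort(arm, 35, params)
            for rec in tr.records:
                assert abs(rec.state.total - 1.0) < 1e-12

    def test_discounting_closed_form_for_constant_reward(self, zero_risk_params):
        # alive forever, utility 1/cycle: total = sum d^t = (1-d^n)/(1-d)
        tr = run_cohort("do-nothing", 35, zero_risk_params)
        d = 1 / 1.03
        n = zero_risk_params.settings.horizon
        assert tr.total_qaly == pytest.approx((1 - d ** n) / (1 - d), rel=1e-12)

    def test_null_effect_arms_differ_only_by_milk(self, params):
        rows = [dataclasses.replace(r, rr_reduction_ldl=0.0, rr_reduction_sbp=0.0,
                                    rr_reduction_compound=0.0, rr_ratio_compound=100.0)
                for r in params.effects]
        ps = params.replace(effects=tuple(rows))
        dn = run_cohort("do-nothing", 55, ps)
        trt = run_cohort("intervention", 55, ps)
        assert trt.total_qaly == pytest.approx(dn.total_qaly, rel=1e-12)
        assert trt.total_cost_hs == pytest.approx(dn.total_cost_hs, rel=1e-12)
        milk = sum(r.state.alive * ps.costs.milk_price_per_day * 365.0
                   * 1.03 ** (-r.cycle) for r in trt.records)
        assert trt.total_cost - dn.total_cost == pytest.approx(milk, rel=1e-9)

    def test_cumulative_deaths_monotone(self, params):
        tr = run_cohort("do-nothing", 45, params)
        dead = [r.state.dead_cvd + r.state.dead_other for r in tr.records]
        assert all(b >= a - 1e-15 for a, b in zip(dead, dead[1:]))

    def test_prefix_suffix_split_matches_full_run(self, params):
        full = run_cohort("intervention", 40, params)
        head = run_cohort("intervention", 40, params, horizon=15)
        tail = run_cohort("intervention", 40, params,
                          initial_state=head._final_engine_state,
                          cycle_offset=15, horizon=params.settings.horizon - 15)
        assert head.total_cost + tail.total_cost == pytest.approx(full.total_cost, rel=1e-12)
        assert head.total_qaly + tail.total_qaly == pytest.approx(full.total_qaly, rel=1e-12)
        assert (head.cum_stroke_events + tail.cum_stroke_events
                == pytest.approx(full.cum_stroke_events, rel=1e-12))

    def test_intervention_never_produces_more_events(self, params):
        traces = run_all_cohorts(params)
        for age in params.settings.start_ages:
            assert (traces["intervention"][age].cum_mi_events
                    <= traces["do-nothing"][age].cum_mi_events)
            assert (traces["intervention"][age].cum_stroke_events
                    <= traces["do-nothing"][age].cum_stroke_events)

    def test_discounted_never_exceeds_undiscounted(self, params):
        tr = run_cohort("do-nothing", 60, params)
        for rec in tr.records[1:]:
            assert rec.cost_discounted <= rec.cost_undiscounted
            assert rec.qaly_discounted <= rec.qaly_undiscounted

    def test_invalid_start_age_rejected(self, params):
        with pytest.raises(DomainError):
            run_cohort("do-nothing", 30, params)

    def test_events_first_ordering_also_conserves(self, params):
        ps = with_settings(params, competing_risk_order="events_first")
        tr = run_cohort("do-nothing", 55, ps)
        for rec in tr.records:
            assert abs(rec.state.total - 1.0) < 1e-12


class TestAccrual:
    def test_milk_only_cost(self, params):
        ps = with_settings(params, htn_prevalence=0.0, chol_prevalence=0.0)
        total, hs = cost_accrual(arm="intervention", params=ps, alive=1.0,
                                 mi_events=0, stroke_events=0, new_chronic_mi=0,
                                 new_chronic_stroke=0, prev_chronic_mi=0,
                                 prev_chronic_stroke=0)
        assert total == pytest.approx(182.5)
        assert hs == 0.0

    def test_comparator_pays_no_milk(self, params):
        ps = with_settings(params, htn_prevalence=0.0, chol_prevalence=0.0)
        total, _ = cost_accrual(arm="do-nothing", params=ps, alive=1.0,
                                mi_events=0, stroke_events=0, new_chronic_mi=0,
                                new_chronic_stroke=0, prev_chronic_mi=0,
                                prev_chronic_stroke=0)
        assert total == 0.0

    def test_single_mi_event_cost(self, params):
        ps = with_settings(params, htn_prevalence=0.0, chol_prevalence=0.0)
        total, hs = cost_accrual(arm="do-nothing", params=ps, alive=0.0,
                                 mi_events=1.0, stroke_events=0,
                                 new_chronic_mi=1.0, new_chronic_stroke=0,
                                 prev_chronic_mi=0, prev_chronic_stroke=0)
        assert total == hs == pytest.approx(9491.00 + 305.23)

    @pytest.mark.parametrize("kwargs, expected", [
        (dict(well_no_event=1.0, new_mi=0, new_stroke=0, chronic_no_event=0), 1.0),
        (dict(well_no_event=0, new_mi=0, new_stroke=0, chronic_no_event=1.0), 0.64),
        (dict(well_no_event=0, new_mi=0, new_stroke=0, chronic_no_event=0), 0.0),
        (dict(well_no_event=0, new_mi=1.0, new_stroke=0, chronic_no_event=0), 0.45),
        (dict(well_no_event=0, new_mi=0, new_stroke=1.0, chronic_no_event=0), 0.56),
    ])
    def test_utility_weights(self, params, kwargs, expected):
        assert utility_accrual(params=params, **kwargs) == pytest.approx(expected)
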