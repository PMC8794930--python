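"""Cohort engine: transition matrix assembly, iteration, discounted rewards."""

import numpy as np
import pytest

from strokecea import (
    HealthState,
    InitialCohort,
    LifeTable,
    build_transition_matrix,
    discount_factor,
    initial_cohort,
    run_cohort,
    strategy_by_name,
)

S = HealthState


def make_lt(q=0.010, start=50, end=120):
    n = end - start + 1
    return LifeTable(ages=np.arange(start, end + 1), qx=np.full(n, q))


ZERO_RISK = dict(
    risk_new_minor=0.0,
    detection_rate_undetected=0.0,
    risk_major_from_well=0.0,
    risk_major_detected_y1=0.0,
    risk_major_detected_later=0.0,
    add_death_undetected=0.0,
    add_death_detected=0.0,
    rr_death_post_major=1.0,
)


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "rate,t,expected", [(0.03, 0, 1.0), (0.03, 1, 1 / 1.03), (0.0, 17, 1.0)]
    )
    def test_values(self, rate, t, expected):
        assert discount_factor(rate, t) == pytest.approx(expected)


class TestTransitionMatrix:
    def test_rows_stochastic_at_all_ages(self, params, life_table):
        for age in range(50, 115):
            M = build_transition_matrix(params, life_table, age)
            np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(M >= 0)

    def test_dead_is_absorbing(self, params, life_table):
        M = build_transition_matrix(params, life_table, 61)
        assert M[S.DEAD, S.DEAD] == 1.0
        assert M[S.DEAD].sum() == 1.0

    def test_undetected_y1_death_entry(self, params):
        M = build_transition_matrix(params, make_lt(0.010), 61)
        assert M[S.UNDETECTED_Y1, S.DEAD] == pytest.approx(0.085)

    def test_undetected_y1_major_stroke_entry(self, params):
        # survivors of the (q + excess) death draw face the 0.255 untreated risk
        M = build_transition_matrix(params, make_lt(0.010), 61)
        assert M[S.UNDETECTED_Y1, S.POST_MAJOR] == pytest.approx((1 - 0.085) * 0.255)

    def test_detection_routes_to_detected_post(self, params):
        M = build_transition_matrix(params, make_lt(0.010), 61)
        surv = 1 - 0.085
        no_major = surv * (1 - 0.255)
        assert M[S.UNDETECTED_Y1, S.DETECTED_POST] == pytest.approx(no_major * 0.1)
        assert M[S.UNDETECTED_Y1, S.UNDETECTED_POST] == pytest.approx(no_major * 0.9)

    def test_tunnel_states_empty_next_cycle(self, params, life_table):
        M = build_transition_matrix(params, life_table, 61)
        assert M[S.UNDETECTED_Y1, S.UNDETECTED_Y1] == 0.0
        assert M[S.DETECTED_Y1, S.DETECTED_Y1] == 0.0

    def test_zero_risk_degenerates_to_pure_mortality(self, params):
        p = params.with_overrides(**ZERO_RISK)
        M = build_transition_matrix(p, make_lt(0.010), 61)
        for s in (S.WELL, S.POST_MAJOR):
            assert M[s, S.DEAD] == pytest.approx(0.010)
            assert M[s, s] == pytest.approx(0.990)
        # tunnels still advance to their post states, but only there
        assert M[S.DETECTED_Y1, S.DETECTED_POST] == pytest.approx(0.990)
        assert M[S.UNDETECTED_Y1, S.UNDETECTED_POST] == pytest.approx(0.990)


class TestRunCohort:
    def all_well(self, params):
        dist = np.zeros(7)
        dist[S.WELL] = 1.0
        return InitialCohort(state_distribution=dist, upfront_cost=0.0)

    def test_immortal_undiscounted_cohort_collects_full_qalys(self, params):
        p = params.with_overrides(discount_rate=0.0, **ZERO_RISK)
        res = run_cohort(self.all_well(p), p, make_lt(0.0))
        assert res.total_qalys == pytest.approx(30.0)
        assert res.total_cost == pytest.approx(0.0)

    def test_immortal_discounted_cohort_matches_annuity(self, params):
        p = params.with_overrides(**ZERO_RISK)
        res = run_cohort(self.all_well(p), p, make_lt(0.0))
        assert res.total_qalys == pytest.approx((1 - 1.03**-30) / 0.03, abs=5e-5)

    def test_mass_conserved_and_dead_monotone(self, params, life_table):
        strat = strategy_by_name("additional_short_protocol_mri", params)
        res = run_cohort(initial_cohort(strat, params), params, life_table)
        occ = res.trace.occupancy
        np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(np.diff(occ[:, S.DEAD]) >= -1e-12)
        assert np.all(occ >= -1e-15)

    def test_discounting_reduces_totals(self, params, life_table):
        strat = strategy_by_name("no_additional_imaging", params)
        init = initial_cohort(strat, params)
        disc = run_cohort(init, params, life_table)
        undisc = run_cohort(init, params.with_overrides(discount_rate=0.0), life_table)
        assert disc.total_qalys < undisc.total_qalys
        assert disc.total_cost < undisc.total_cost

    def test_total_cost_at_least_upfront(self, params, life_table):
        strat = strategy_by_name("additional_short_protocol_mri", params)
        init = initial_cohort(strat, params)
        res = run_cohort(init, params, life_table)
        assert res.total_cost >= init.upfront_cost

    def test_equal_accuracy_invariance(self, params, life_table):
        """Equal sensitivities ⇒ ΔQALY = 0 and ΔCost = cost_mri, exactly."""
        p = params.with_overrides(sens_no_imaging=0.94)
        res_ct = run_cohort(
            initial_cohort(strategy_by_name("no_additional_imaging", p), p), p, life_table
        )
        res_mri = run_cohort(
            initial_cohort(strategy_by_name("additional_short_protocol_mri", p), p),
            p,
            life_table,
        )
        assert res_mri.total_qalys - res_ct.total_qalys == 0.0
        assert res_mri.total_cost - res_ct.total_cost == pytest.approx(
            p.cost_mri, abs=1e-9
        )

    def test_half_cycle_correction_raises_qalys(self, params, life_table):
        # trapezoid counts part of the (fully alive) cycle-0 membership
        strat = strategy_by_name("no_additional_imaging", params)
        init = initial_cohort(strat, params)
        plain = run_cohort(init, params, life_table)
        hcc = run_cohort(init, params.with_overrides(half_cycle_correction=True), life_table)
        assert hcc.total_qalys > plain.total_qalys

    def test_acute_major_cost_charged_once_per_entrant(self, params):
        # deterministic path: all start detected-Y1, risk 1 → everyone has a
        # major stroke in cycle 1 and never again; zero mortality, no discount
        p = params.with_overrides(
            discount_rate=0.0,
            risk_major_detected_y1=1.0,
            risk_major_undetected_y1=1.0,
            risk_major_undetected_later=1.0,
            add_death_detected=0.0,
            rr_death_post_major=0.0,
            n_cycles=3,
        )
        dist = np.zeros(7)
        dist[S.DETECTED_Y1] = 1.0
        res = run_cohort(InitialCohort(dist, 0.0), p, make_lt(0.0))
        expected = p.cost_acute_major + 3 * p.cost_year_post_major
        assert res.total_cost == pytest.approx(expected)
        assert res.total_qalys == pytest.approx(3 * p.utility_post_major)
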