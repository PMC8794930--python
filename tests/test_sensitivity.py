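"""Sensitivity machinery: tornado DSA, ICER curves, moment matching, PSA, CEAC."""

import numpy as np
import pytest

from strokecea import (
    DistributionSpec,
    ParameterError,
    ParameterRange,
    base_case,
    ceac,
    icer_vs_parameter,
    moment_match,
    one_way_dsa,
    run_psa,
    sample_parameters,
)
from strokecea.sensitivity import parameter_distributions


class TestMomentMatch:
    def test_beta_example(self):
        m = moment_match(DistributionSpec("beta", 0.06, 0.012))
        alpha, beta = m.args
        assert alpha == pytest.approx(23.44, abs=0.01)
        assert beta == pytest.approx(367.23, abs=0.01)

    def test_gamma_example(self):
        m = moment_match(DistributionSpec("gamma", 309, 61.8))
        shape, scale = m.args
        assert shape == pytest.approx(25.0)
        assert scale == pytest.approx(12.36)

    def test_boundary_beta_mean_coerced_to_fixed(self):
        spec = DistributionSpec("beta", 1.0, 0.2)
        assert spec.family == "fixed"
        assert moment_match(spec).sample(np.random.default_rng(0)) == 1.0

    def test_infeasible_beta_spread_rejected(self):
        with pytest.raises(ParameterError, match="infeasible"):
            moment_match(DistributionSpec("beta", 0.5, 0.6))

    def test_matched_moments_recovered_empirically(self):
        rng = np.random.default_rng(7)
        for spec in (DistributionSpec("beta", 0.33, 0.066), DistributionSpec("gamma", 6500, 1300)):
            x = moment_match(spec).sample(rng, size=40_000)
            se = spec.sd / np.sqrt(x.size)
            assert abs(x.mean() - spec.mean) < 3 * se


class TestDSA:
    def test_degenerate_range_reproduces_base_case(self, params, life_table):
        _, base = base_case(params, life_table)
        entries = one_way_dsa(
            params, life_table, [ParameterRange("cost_mri", 309.0, 309.0)]
        )
        e = entries[0]
        assert e.outcome_at_low == e.outcome_at_high == pytest.approx(base.incremental_nmb)

    def test_entries_sorted_by_swing(self, params, life_table):
        ranges = [
            ParameterRange("cost_mri", 155.0, 500.0),
            ParameterRange("utility_post_major", 0.165, 0.495),
            ParameterRange("detection_rate_undetected", 0.05, 0.15),
        ]
        entries = one_way_dsa(params, life_table, ranges)
        swings = [e.swing for e in entries]
        assert swings == sorted(swings, reverse=True)

    def test_invalid_range_rejected(self, params, life_table):
        with pytest.raises(ParameterError):
            one_way_dsa(params, life_table, [ParameterRange("prevalence_minor", 0.5, 1.5)])

    def test_low_above_high_rejected(self):
        with pytest.raises(ParameterError):
            ParameterRange("cost_mri", 500.0, 155.0)


class TestICERCurve:
    def test_one_row_per_grid_value(self, params, life_table):
        pts = icer_vs_parameter(params, life_table, "sens_no_imaging", [0.6, 0.7, 0.8])
        assert [v for v, _ in pts] == [0.6, 0.7, 0.8]

    def test_single_point_at_default_matches_base_case(self, params, life_table):
        _, base = base_case(params, life_table)
        [(_, c)] = icer_vs_parameter(params, life_table, "sens_no_imaging", [0.60])
        assert c.delta_cost == pytest.approx(base.delta_cost)
        assert c.delta_effect == pytest.approx(base.delta_effect)

    def test_equal_sensitivity_grid_point_kills_delta_effect(self, params, life_table):
        [(_, c)] = icer_vs_parameter(params, life_table, "sens_no_imaging", [0.94])
        assert c.delta_effect == 0.0
        assert c.delta_cost == pytest.approx(params.cost_mri)


class TestSampling:
    def test_boundary_parameters_never_sampled(self, params):
        specs = parameter_distributions(params)
        assert specs["spec_mri"].family == "fixed"
        assert specs["utility_no_major"].family == "fixed"
        assert specs["rr_death_post_major"].family == "gamma"

    def test_samples_valid_and_rederived(self, params):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = sample_parameters(params, rng)
            assert 0 <= p.risk_major_undetected_y1 <= 1
            assert p.risk_major_undetected_y1 == pytest.approx(
                p.risk_major_detected_y1 / (1 - p.rrr_prophylaxis)
            )

    def test_sample_means_match_specs(self, params):
        rng = np.random.default_rng(11)
        draws = [sample_parameters(params, rng) for _ in range(3000)]
        for name in ("utility_post_major", "cost_mri", "sens_no_imaging"):
            spec = parameter_distributions(params)[name]
            xs = np.array([getattr(p, name) for p in draws])
            se = spec.sd / np.sqrt(xs.size)
            # rejection of invalid joint draws barely perturbs these marginals
            assert abs(xs.mean() - spec.mean) < 4 * se


@pytest.fixture(scope="module")
def psa(params, life_table):
    return run_psa(params, life_table, n_iterations=300, seed=42, spread_cv=0.2)


class TestPSA:
    def test_same_seed_reproduces_bit_identically(self, params, life_table, psa):
        again = run_psa(params, life_table, n_iterations=300, seed=42, spread_cv=0.2)
        np.testing.assert_array_equal(psa.costs, again.costs)
        np.testing.assert_array_equal(psa.effects, again.effects)

    def test_small_cv_collapses_to_base_case(self, params, life_table):
        """With cv = 0.01 every iteration's totals sit within 5% of base case."""
        results, _ = base_case(params, life_table)
        ct = results["no_additional_imaging"]
        mri = results["additional_short_protocol_mri"]
        psa = run_psa(params, life_table, n_iterations=40, seed=1, spread_cv=0.01)
        assert np.all(np.abs(psa.costs[:, 0] / ct.total_cost - 1) < 0.05)
        assert np.all(np.abs(psa.costs[:, 1] / mri.total_cost - 1) < 0.05)
        assert np.all(np.abs(psa.effects[:, 0] / ct.total_qalys - 1) < 0.05)
        assert np.all(np.abs(psa.effects[:, 1] / mri.total_qalys - 1) < 0.05)

    def test_fraction_dominant_in_unit_interval(self, psa):
        assert 0.0 <= psa.fraction_intervention_dominant <= 1.0

    def test_ceac_limits(self, psa):
        pts = dict(ceac(psa, [0.0, 1e9]))
        lower_cost = float((psa.costs[:, 1] < psa.costs[:, 0]).mean())
        assert pts[0.0] == pytest.approx(lower_cost)
        higher_eff = float(
            (psa.effects[:, 1] > psa.effects[:, 0]).mean()
        )
        # at astronomically high WTP the effect term dominates
        assert abs(pts[1e9] - higher_eff) < 0.05

    def test_degenerate_single_iteration_prefers_intervention(self, params, life_table):
        psa = run_psa(params, life_table, n_iterations=1, seed=5, spread_cv=0.01)
        [(_, prob)] = ceac(psa, [100_000])
        assert prob == 1.0

    def test_empty_wtp_grid_rejected(self, psa):
        with pytest.raises(ParameterError):
            ceac(psa, [])
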