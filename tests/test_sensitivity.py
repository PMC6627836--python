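"""Sensitivity analyses: distribution fits, tornado bars, PSA contract."""

import numpy as np
import pytest

from milkcea.params import DomainError
from milkcea.sensitivity import (DistributionSpec, _draw, build_distributions,
                                 fit_beta, fit_gamma, run_psa, tornado,
                                 tornado_parameter_names)


class TestGammaFit:
    def test_moment_identities(self):
        assert fit_gamma(4, 2) == (pytest.approx(4.0), pytest.approx(1.0))

    def test_default_sd_rule_on_inpatient_cost(self):
        shape, scale = fit_gamma(9491.00, 0.2 * 9491.00)
        assert shape == pytest.approx(25.0)
        assert scale == pytest.approx(379.64)

    def test_sampled_mean_recovers_input(self):
        shape, scale = fit_gamma(9491.00, 0.2 * 9491.00)
        draws = np.random.default_rng(0).gamma(shape, scale, 100_000)
        assert draws.mean() == pytest.approx(9491.00, rel=0.01)

    def test_nonpositive_moments_rejected(self):
        with pytest.raises(DomainError):
            fit_gamma(0, 1)
        with pytest.raises(DomainError):
            fit_gamma(1, 0)


class TestBetaFit:
    def test_symmetric_solution(self):
        a, b = fit_beta(0.5, 0.1)
        assert a == pytest.approx(12.0)
        assert b == pytest.approx(12.0)

    def test_chronic_utility_under_default_sd_rule(self):
        a, b = fit_beta(0.64, 0.2 * 0.64)
        assert a / (a + b) == pytest.approx(0.64)

    def test_infeasible_variance_rejected(self):
        with pytest.raises(DomainError):
            fit_beta(0.5, 0.5)


class TestTornado:
    def test_inert_parameters_have_zero_width(self, params):
        bars = tornado(params, ["costs.mi_inpatient_days",
                                "costs.stroke_inpatient_days"])
        assert all(b.width == 0.0 for b in bars)

    def test_bars_sorted_descending_by_width(self, params):
        bars = tornado(params, ["costs.milk_price_per_day",
                                "costs.mi_inpatient_days", "utilities.chronic"])
        widths = [b.width for b in bars]
        assert widths == sorted(widths, reverse=True)

    def test_published_range_used_for_antihypertensive_drug_cost(self, params):
        bar = tornado(params, ["costs.drug_cost_htn"])[0]
        assert (bar.low_value, bar.high_value) == (19.38, 329.38)

    def test_unknown_parameter_lists_valid_names(self, params):
        with pytest.raises(DomainError, match="valid names"):
            tornado(params, ["costs.nonexistent"])

    def test_zero_width_range_gives_zero_width_bar(self, params):
        bar = tornado(params, ["utilities.chronic"], rel_range=0.0)[0]
        assert bar.width == pytest.approx(0.0, abs=1e-9)

    def test_chronic_utility_among_widest_bars(self, params):
        bars = tornado(params)
        top = [b.parameter for b in bars[:10]]
        assert "utilities.chronic" in top
        assert len(bars) == len(tornado_parameter_names(params))


class TestDistributions:
    def test_families_assigned_per_published_rule(self, params):
        specs = {s.parameter: s for s in build_distributions(params)}
        assert specs["costs.inpatient_mi"].family == "gamma"
        assert specs["utilities.chronic"].family == "beta"
        assert specs["epi.well.0.noncvd_mortality"].family == "normal"
        # 5% sd on mortality inputs
        s = specs["epi.well.0.stroke_cf28"]
        assert s.sd == pytest.approx(0.05 * s.mean)
        # range-derived sd where the published table has a range
        s = specs["costs.inpatient_mi"]
        assert s.sd == pytest.approx((10586.81 - 8395.18) / 3.92)

    @pytest.mark.parametrize("parameter, family, mean, sd", [
        ("costs.inpatient_mi", "gamma", 9491.0, 559.09),
        ("utilities.chronic", "beta", 0.64, 0.128),
        ("epi.well.0.stroke_cf28", "normal", 17.80, 0.89),
    ])
    def test_draw_means_converge_to_base_value(self, parameter, family, mean, sd):
        spec = DistributionSpec(parameter, family, mean, sd)
        rng = np.random.default_rng(11)
        draws = np.array([_draw(spec, rng) for _ in range(100_000)])
        assert draws.mean() == pytest.approx(mean, rel=0.01)

    def test_truncated_normal_stays_on_probability_scale(self):
        spec = DistributionSpec("epi.well.0.stroke_cf28", "normal", 99.0, 30.0)
        rng = np.random.default_rng(5)
        draws = [_draw(spec, rng) for _ in range(2000)]
        assert all(0 <= v <= 100 for v in draws)


class TestPsa:
    def test_same_seed_reproduces_sample_list(self, params):
        r1 = run_psa(params, n_replicates=25, seed=42)
        r2 = run_psa(params, n_replicates=25, seed=42)
        assert [(s.delta_cost, s.delta_qaly, s.cost_effective) for s in r1.samples] == \
               [(s.delta_cost, s.delta_qaly, s.cost_effective) for s in r2.samples]

    def test_degenerate_distributions_reproduce_base_case(self, params):
        from milkcea.cea import compare
        base = compare(params)
        specs = [DistributionSpec(s.parameter, s.family, s.mean, 0.0)
                 for s in build_distributions(params)]
        res = run_psa(params, n_replicates=5, seed=1, distributions=specs)
        for s in res.samples:
            assert s.delta_cost == pytest.approx(base.delta_cost, rel=1e-9)
            assert s.delta_qaly == pytest.approx(base.delta_qaly, rel=1e-9)
        assert res.fraction_cost_effective in (0.0, 1.0)

    def test_mc_standard_error_is_binomial(self, params):
        res = run_psa(params, n_replicates=30, seed=3)
        p = res.fraction_cost_effective
        assert res.mc_standard_error == pytest.approx(np.sqrt(p * (1 - p) / 30))

    def test_replicate_cost_effectiveness_flag_consistent(self, params):
        wtp = params.settings.wtp_per_qaly
        res = run_psa(params, n_replicates=25, seed=9)
        for s in res.samples:
            expected = (s.delta_qaly > 0 and
                        (s.delta_cost <= 0 or s.delta_cost / s.delta_qaly <= wtp))
            assert s.cost_effective == expected
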