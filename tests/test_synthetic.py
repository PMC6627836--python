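"""Synthetic data: perturbation contract and the microsimulation oracle."""

import numpy as np
import pytest

from milkcea.engine import multipliers_for_arm, cycle_probabilities, run_cohort
from milkcea.synthetic import (IndividualHistory, PerturbationSpec,
                               microsim_occupancy, microsimulate,
                               perturb_parameters)

from conftest import (constant_epi_table, occupancy_z, sidak_z, with_costs,
                      with_settings)


class TestPerturbation:
    def test_zero_sd_is_identity(self, params):
        assert perturb_parameters(params, PerturbationSpec(0.0, 7)) == params

    def test_same_seed_same_output(self, params):
        a = perturb_parameters(params, PerturbationSpec(0.2, 7))
        b = perturb_parameters(params, PerturbationSpec(0.2, 7))
        assert a == b
        c = perturb_parameters(params, PerturbationSpec(0.2, 8))
        assert c != a

    def test_lognormal_median_preserves_point_value(self, params):
        import warnings
        with warnings.catch_warnings():
            # large-rate cells occasionally clip at their ceiling; irrelevant
            # to the cost field whose median is under test
            warnings.simplefilter("ignore", UserWarning)
            draws = [perturb_parameters(params, PerturbationSpec(0.2, seed))
                     .costs.inpatient_mi.value for seed in range(1000)]
        assert np.median(draws) == pytest.approx(9491.00, rel=0.02)

    def test_utilities_clipped_to_feasible_bound(self, params):
        high = with_costs(params, utility_chronic=0.999)
        with pytest.warns(UserWarning, match="clipped"):
            out = perturb_parameters(
                high, PerturbationSpec(0.5, 3, fields_included=["costs.utility_chronic"]))
        assert out.costs.utility_chronic <= 1.0

    def test_field_selection_limits_perturbation(self, params):
        out = perturb_parameters(
            params, PerturbationSpec(0.3, 5, fields_included=["costs.inpatient_mi"]))
        assert out.costs.inpatient_mi.value != params.costs.inpatient_mi.value
        assert out.epi_well == params.epi_well
        assert out.costs.milk_price_per_day == params.costs.milk_price_per_day


class TestMicrosimDegenerateCases:
    def test_zero_probabilities_leave_everyone_well(self, zero_risk_params):
        histories = microsimulate(zero_risk_params, "do-nothing", 50, 200, seed=1)
        assert all(h.final_state == "well" and h.events == () for h in histories)

    def test_certain_fatal_event_kills_everyone_in_first_cycle(self, zero_risk_params):
        ps = zero_risk_params.replace(
            epi_well=constant_epi_table("well", stroke_incidence=100_000,
                                        stroke_cf28=100.0))
        histories = microsimulate(ps, "do-nothing", 50, 200, seed=1)
        for h in histories:
            assert h.final_state == "dead_cvd"
            assert (0, "stroke") in h.events
            assert (0, "death_cvd") in h.events

    def test_history_invariants_enforced(self):
        with pytest.raises(Exception):
            IndividualHistory(50, ((1, "death_cvd"), (0, "stroke")), "dead_cvd")
        with pytest.raises(Exception):
            IndividualHistory(50, ((0, "death_cvd"), (1, "death_other")), "dead_cvd")


class TestOracleEquivalence:
    """The cohort trace must be the large-n limit of the microsimulation.

    Each (cycle, state) occupancy is a binomial estimate of the cohort
    value; the 3-SE criterion is applied simultaneously across all
    40 cycles x 4 states via a Sidak-corrected joint threshold so the check
    keeps the intended confidence level instead of false-alarming on the
    maximum of 160 comparisons.
    """

    N = 200_000

    @pytest.mark.parametrize("arm", ["do-nothing", "intervention"])
    def test_cohort_trace_is_large_n_limit_of_microsimulation(self, params, arm):
        seed = params.settings.random_seed
        occ = microsim_occupancy(params, arm, 55, self.N, seed)
        tr = run_cohort(arm, 55, params)
        z = occupancy_z(occ, tr)
        assert np.abs(z).max() <= sidak_z(z.size)

    def test_equivalence_holds_for_perturbed_parameters(self, params):
        ps = perturb_parameters(params, PerturbationSpec(0.1, 21))
        occ = microsim_occupancy(ps, "do-nothing", 65, 100_000, seed=22)
        tr = run_cohort("do-nothing", 65, ps)
        z = occupancy_z(occ, tr)
        assert np.abs(z).max() <= sidak_z(z.size)

    def test_seed_reproducibility(self, params):
        a = microsim_occupancy(params, "do-nothing", 55, 5000, seed=4)
        b = microsim_occupancy(params, "do-nothing", 55, 5000, seed=4)
        assert np.array_equal(a["occupancy"], b["occupancy"])


class TestParameterRecovery:
    def test_first_cycle_event_frequency_recovers_incidence(self, params):
        # all-well start: the cycle-0 stroke frequency estimates
        # (1 - q_nc) * incidence * multiplier
        ps = with_settings(params, initial_chronic_fraction=0.0,
                           initial_well_fraction=1.0)
        n = 200_000
        occ = microsim_occupancy(ps, "intervention", 60, n, seed=17)
        p = cycle_probabilities(ps, multipliers_for_arm(ps, "intervention"), 60)
        expected = (1 - p["well_q_nc"]) * p["well_p_stroke"]
        observed = occ["events"][0]["stroke_events"] / n
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) <= 3 * se
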