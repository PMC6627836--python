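import dataclasses

import numpy as np
import pytest
from scipy.stats import norm

from milkcea.params import (AgeBand, EpiRow, EpiTable, ParameterSet,
                            load_parameters)


def sidak_z(n_cells: int, per_cell_z: float = 3.0) -> float:
    """Joint threshold giving ``n_cells`` simultaneous comparisons the same
    family-wise confidence as a single ``per_cell_z``-SE check.

    A per-cell 3-SE bound holds one cell with probability 99.73%; applied
    naively to ~160 cells it false-alarms for about a third of seeds even
    when the compared quantities are identical in expectation.
    """
    alpha = 2 * norm.sf(per_cell_z)
    return float(norm.isf((1 - (1 - alpha) ** (1 / n_cells)) / 2))


def occupancy_z(occ: dict, trace) -> np.ndarray:
    """Per-(cycle, state) z-scores of microsim occupancy vs the cohort trace."""
    coh = np.array([[r.state.well, r.state.chronic,
                     r.state.dead_cvd, r.state.dead_other]
                    for r in trace.records])
    se = np.sqrt(coh * (1 - coh) / occ["n"])
    return (occ["occupancy"][1:] - coh) / np.maximum(se, 1e-12)


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    """The packaged base-case parameter set (published tables)."""
    return load_parameters()


def constant_epi_table(population: str, *, stroke_incidence=0.0, stroke_cf28=0.0,
                       mi_incidence=0.0, mi_cf30=0.0, noncvd=0.0) -> EpiTable:
    """A 9-band table (35-79) with the same rates in every band."""
    rows = []
    for lo in range(35, 80, 5):
        kw = dict(band=AgeBand(lo, lo + 4), stroke_incidence=stroke_incidence,
                  stroke_cf28=stroke_cf28, mi_incidence=mi_incidence,
                  mi_cf30=mi_cf30)
        if population == "well":
            kw["noncvd_mortality"] = noncvd
        else:
            kw["noncvd_mortality_stroke"] = noncvd
            kw["noncvd_mortality_mi"] = noncvd
        rows.append(EpiRow(**kw))
    return EpiTable(population, tuple(rows))


def with_settings(ps: ParameterSet, **kwargs) -> ParameterSet:
    return ps.replace(settings=dataclasses.replace(ps.settings, **kwargs))


def with_costs(ps: ParameterSet, **kwargs) -> ParameterSet:
    return ps.replace(costs=dataclasses.replace(ps.costs, **kwargs))


@pytest.fixture()
def zero_risk_params(params) -> ParameterSet:
    """No events, no mortality, no management costs or milk: only well-state
    utility accrues.  Useful for closed-form discounting checks."""
    ps = params.replace(
        epi_well=constant_epi_table("well"),
        epi_chronic=constant_epi_table("chronic"),
    )
    ps = with_settings(ps, htn_prevalence=0.0, chol_prevalence=0.0,
                       initial_chronic_fraction=0.0, initial_well_fraction=1.0)
    return with_costs(ps, milk_price_per_day=0.0)
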