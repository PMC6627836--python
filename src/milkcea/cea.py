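"""Arm comparison: incremental costs/QALYs, ICER, WHO classification,
nationwide event projection and per-person health-system savings.

The headline ratio is the age-weighted average over the 5-year start-age
bands (35, 40, ..., 75): incremental discounted cost per person divided by
incremental discounted QALYs per person.  The ICER includes the milk product
as the intervention's cost; the "annual savings" figure deliberately
excludes it, because it is a consumer expense and the savings are framed for
the health-care system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

from .engine import ARMS, CohortTrace, run_all_cohorts
from .params import DomainError, ParameterSet

__all__ = ["CEAResult", "icer", "classify_who", "project_population",
           "annual_savings", "compare", "net_monetary_benefit"]

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


@dataclass
class CEAResult:
    delta_cost: float            # per person, discounted, milk included
    delta_qaly: float            # per person, discounted
    icer: Optional[float]        # int$/QALY, None when a flag applies
    icer_flag: Optional[str]     # dominant / dominated / undefined / None
    who_class: str
    events_prevented: Dict[str, float]   # population-scaled counts
    deaths_prevented: Dict[str, float]
    pct_reduction: Dict[str, float]      # % vs do-nothing cumulative totals
    annual_savings_per_person: float     # int$/person/year, milk excluded
    savings_pct_of_expenditure: float
    per_start_age_icer: Dict[int, Optional[float]] = field(default_factory=dict)


def icer(delta_cost: float, delta_qaly: float):
    """ICER with dominance handling: ``(value, flag)``.

    A positive-cost, positive-QALY pair yields the ratio; negative cost with
    positive QALYs is dominant (the flag replaces the ratio), positive cost
    with negative QALYs dominated; zero QALY gain leaves the ratio undefined.
    """
    if delta_qaly == 0:
        return None, UNDEFINED
    if delta_qaly > 0 and delta_cost < 0:
        return None, DOMINANT
    if delta_qaly < 0 and delta_cost > 0:
        return None, DOMINATED
    if delta_qaly < 0 and delta_cost < 0:
        # less effective but cheaper: report the south-west ratio
        return delta_cost / delta_qaly, None
    return delta_cost / delta_qaly, None


def classify_who(icer_value: Optional[float], gdp_per_capita: float,
                 flag: Optional[str] = None) -> str:
    """WHO GDP-threshold classification.

    Very cost-effective up to 1x GDP per capita, cost-effective up to 3x,
    not cost-effective above; band boundaries resolve downward (<=).
    Dominance flags pass through.
    """
    if gdp_per_capita <= 0:
        raise DomainError("gdp_per_capita must be positive")
    if flag in (DOMINANT, DOMINATED):
        return flag
    if icer_value is None:
        raise DomainError("icer_value required unless a dominance flag applies")
    if icer_value <= gdp_per_capita:
        return "very cost-effective"
    if icer_value <= 3 * gdp_per_capita:
        return "cost-effective"
    return "not cost-effective"


def _weighted(traces: Dict[int, CohortTrace], weights: Dict[int, float], attr: str) -> float:
    return sum(weights[a] * getattr(traces[a], attr) for a in traces)


def _check_grids(traces: Dict[str, Dict[int, CohortTrace]], params: ParameterSet) -> Dict[int, float]:
    ages = tuple(params.settings.start_ages)
    for arm in ARMS:
        if arm not in traces:
            raise DomainError(f"missing arm {arm!r} in traces")
        if tuple(sorted(traces[arm])) != tuple(sorted(ages)):
            raise DomainError(f"trace grid for {arm!r} does not match configured start ages")
    return dict(zip(ages, params.settings.age_weights))


def project_population(traces: Dict[str, Dict[int, CohortTrace]],
                       params: ParameterSet) -> dict:
    """Nationwide events/deaths prevented over the horizon.

    Per-person cumulative differences (do-nothing minus intervention),
    age-weighted, scaled by the population size; percentage reductions are
    relative to the do-nothing arm's cumulative totals.
    """
    w = _check_grids(traces, params)
    pop = params.settings.population_size
    out = {"events_prevented": {}, "deaths_prevented": {}, "pct_reduction": {},
           "baseline_events": {}, "baseline_deaths": {}}
    for kind, attr in (("mi", "cum_mi_events"), ("stroke", "cum_stroke_events")):
        base = _weighted(traces["do-nothing"], w, attr)
        new = _weighted(traces["intervention"], w, attr)
        out["events_prevented"][kind] = (base - new) * pop
        out["baseline_events"][kind] = base * pop
        out["pct_reduction"][kind] = 100.0 * (base - new) / base if base > 0 else 0.0
    for kind, attr in (("mi", "cum_mi_deaths"), ("stroke", "cum_stroke_deaths")):
        base = _weighted(traces["do-nothing"], w, attr)
        new = _weighted(traces["intervention"], w, attr)
        out["deaths_prevented"][kind] = (base - new) * pop
        out["baseline_deaths"][kind] = base * pop
    return out


def annual_savings(traces: Dict[str, Dict[int, CohortTrace]],
                   params: ParameterSet) -> dict:
    """Discounted health-system savings per person per year (milk excluded)."""
    w = _check_grids(traces, params)
    base = _weighted(traces["do-nothing"], w, "total_cost_hs")
    new = _weighted(traces["intervention"], w, "total_cost_hs")
    per_year = (base - new) / params.settings.horizon
    pct = 100.0 * per_year / params.settings.annual_health_expenditure
    return {"annual_savings_per_person": per_year, "pct_of_expenditure": pct}


def net_monetary_benefit(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Incremental net monetary benefit ``wtp * dQALY - dCost``."""
    return wtp * delta_qaly - delta_cost


def compare(params: ParameterSet,
            traces: Optional[Dict[str, Dict[int, CohortTrace]]] = None) -> CEAResult:
    """Full base-case comparison of the two arms."""
    if traces is None:
        traces = run_all_cohorts(params)
    w = _check_grids(traces, params)
    d_cost = (_weighted(traces["intervention"], w, "total_cost")
              - _weighted(traces["do-nothing"], w, "total_cost"))
    d_qaly = (_weighted(traces["intervention"], w, "total_qaly")
              - _weighted(traces["do-nothing"], w, "total_qaly"))
    value, flag = icer(d_cost, d_qaly)
    who = classify_who(value, params.settings.wtp_per_qaly, flag)
    proj = project_population(traces, params)
    sav = annual_savings(traces, params)
    per_age = {}
    for a in params.settings.start_ages:
        dc = traces["intervention"][a].total_cost - traces["do-nothing"][a].total_cost
        dq = traces["intervention"][a].total_qaly - traces["do-nothing"][a].total_qaly
        v, f = icer(dc, dq)
        per_age[a] = v
    return CEAResult(
        delta_cost=d_cost, delta_qaly=d_qaly, icer=value, icer_flag=flag,
        who_class=who,
        events_prevented=proj["events_prevented"],
        deaths_prevented=proj["deaths_prevented"],
        pct_reduction=proj["pct_reduction"],
        annual_savings_per_person=sav["annual_savings_per_person"],
        savings_pct_of_expenditure=sav["pct_of_expenditure"],
        per_start_age_icer=per_age)
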