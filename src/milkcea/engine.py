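"""Cohort state-transition engine.

Four aggregate states — well, chronic CVD, CVD death, other death — advanced
in 1-year cycles.  MI and stroke are within-cycle branch events, not
persistent states: an event resolves in the same cycle to 30/28-day case
fatality or to (entry into / continuation of) the chronic state.  The
chronic compartment is internally split by origin (post-stroke vs post-MI)
because the published chronic-state non-CVD mortality and maintenance costs
are endpoint-specific, while the public state vector reports the pooled
chronic occupancy.

Within a cycle (default ordering) non-CVD death is applied first; MI and
stroke risks then act independently on survivors, and each event kills with
its case fatality.  The alternative "events_first" ordering resolves events
and their fatality before non-CVD death; both are exposed because the choice
materially affects results.  Expected-value bookkeeping uses the exact
factorized survival probability (1 − p_s·cf_s)(1 − p_m·cf_m), so the state
vector is conserved to machine precision and an individual-level Bernoulli
simulation with the same probabilities converges to the cohort trace.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .effects import MultiplierTable, build_multipliers, null_multipliers
from .params import DomainError, ParameterSet, lookup_epi

__all__ = [
    "NumericalContractError",
    "StateVector",
    "CycleRecord",
    "CohortTrace",
    "escalate_probability",
    "cycle_transition",
    "run_cohort",
    "run_all_cohorts",
    "cost_accrual",
    "utility_accrual",
    "multipliers_for_arm",
    "PER_100K",
]

PER_100K = 100_000.0

ARMS = ("do-nothing", "intervention")


class NumericalContractError(ArithmeticError):
    """An intermediate quantity left its legal range (e.g. probability > 1)."""


@dataclass(frozen=True)
class StateVector:
    """Occupancy proportions of the four aggregate states (sum to 1)."""

    well: float
    chronic: float
    dead_cvd: float
    dead_other: float

    def __post_init__(self) -> None:
        for name in ("well", "chronic", "dead_cvd", "dead_other"):
            v = getattr(self, name)
            if v < -1e-12:
                raise NumericalContractError(f"state.{name} = {v} is negative")
        if abs(self.total - 1.0) > 1e-9:
            raise NumericalContractError(f"state vector sums to {self.total}, not 1")

    @property
    def total(self) -> float:
        return self.well + self.chronic + self.dead_cvd + self.dead_other

    @property
    def alive(self) -> float:
        return self.well + self.chronic


@dataclass
class CycleRecord:
    """Per-cycle tallies for one arm (per person of the starting cohort)."""

    cycle: int
    mean_age: float
    state: StateVector
    mi_events: float
    stroke_events: float
    mi_deaths: float
    stroke_deaths: float
    cost_undiscounted: float
    cost_discounted: float
    cost_hs_undiscounted: float   # health-system share (milk excluded)
    cost_hs_discounted: float
    qaly_undiscounted: float
    qaly_discounted: float


@dataclass
class CohortTrace:
    """Complete trajectory of one arm from one start age."""

    arm: str
    start_age: int
    records: List[CycleRecord]
    total_cost: float = 0.0
    total_cost_hs: float = 0.0
    total_qaly: float = 0.0
    cum_mi_events: float = 0.0
    cum_stroke_events: float = 0.0
    cum_mi_deaths: float = 0.0
    cum_stroke_deaths: float = 0.0

    def finalize(self) -> "CohortTrace":
        self.total_cost = sum(r.cost_discounted for r in self.records)
        self.total_cost_hs = sum(r.cost_hs_discounted for r in self.records)
        self.total_qaly = sum(r.qaly_discounted for r in self.records)
        self.cum_mi_events = sum(r.mi_events for r in self.records)
        self.cum_stroke_events = sum(r.stroke_events for r in self.records)
        self.cum_mi_deaths = sum(r.mi_deaths for r in self.records)
        self.cum_stroke_deaths = sum(r.stroke_deaths for r in self.records)
        return self


def escalate_probability(p0: float, rate: float, t: float) -> float:
    """Escalated probability ``min(1, p0 * (1 + rate)^t)``.

    Models the published convention of growing a baseline probability by a
    constant annual rate with years since state entry.
    """
    if rate < -1:
        raise DomainError(f"escalation rate {rate} below -1")
    if not (0 <= p0 <= 1):
        raise DomainError(f"p0={p0} outside [0, 1]")
    if t < 0:
        raise DomainError(f"t={t} negative")
    return min(1.0, p0 * (1.0 + rate) ** t)


def multipliers_for_arm(params: ParameterSet, arm: str) -> MultiplierTable:
    if arm == "intervention":
        return MultiplierTable(build_multipliers(params.effects))
    if arm == "do-nothing":
        return MultiplierTable(null_multipliers(params.effects))
    raise DomainError(f"unknown arm {arm!r}; expected one of {ARMS}")


# ---------------------------------------------------------------------------
# per-cycle probability lookup

def _check_prob(name: str, p: float) -> float:
    if not (0.0 <= p <= 1.0):
        raise NumericalContractError(f"{name} = {p} outside [0, 1]")
    return p


def cycle_probabilities(params: ParameterSet, mult: MultiplierTable, age: float) -> dict:
    """All per-person transition probabilities active at ``age``.

    Incidences and non-CVD mortality are converted from per-100,000 rates,
    case fatalities from percent; the arm's RR multipliers scale event
    incidence (first-ever and recurrent) but never case fatality.
    """
    w = lookup_epi(params.epi_well, age)
    c = lookup_epi(params.epi_chronic, age)
    m_s = mult.get("stroke", age)
    m_m = mult.get("mi", age)
    return {
        "well_q_nc": _check_prob("well non-CVD mortality", w.noncvd_mortality / PER_100K),
        "well_p_stroke": _check_prob("well stroke risk", w.stroke_incidence / PER_100K * m_s),
        "well_cf_stroke": _check_prob("well stroke case fatality", w.stroke_cf28 / 100.0),
        "well_p_mi": _check_prob("well MI risk", w.mi_incidence / PER_100K * m_m),
        "well_cf_mi": _check_prob("well MI case fatality", w.mi_cf30 / 100.0),
        "chr_q_nc_stroke": _check_prob("chronic post-stroke non-CVD mortality",
                                       c.noncvd_mortality_stroke / PER_100K),
        "chr_q_nc_mi": _check_prob("chronic post-MI non-CVD mortality",
                                   c.noncvd_mortality_mi / PER_100K),
        "chr_p_stroke": _check_prob("chronic stroke risk", c.stroke_incidence / PER_100K * m_s),
        "chr_cf_stroke": _check_prob("chronic stroke case fatality", c.stroke_cf28 / 100.0),
        "chr_p_mi": _check_prob("chronic MI risk", c.mi_incidence / PER_100K * m_m),
        "chr_cf_mi": _check_prob("chronic MI case fatality", c.mi_cf30 / 100.0),
    }


# ---------------------------------------------------------------------------
# core expected-value update (shared source of truth with the microsimulator)

def _branch_expectations(pop: float, p_s: float, cf_s: float, p_m: float, cf_m: float,
                         order: str, q_nc: float) -> dict:
    """Resolve one compartment's within-cycle event/death branches.

    Returns expected fractions of ``pop``: non-CVD deaths, stroke/MI events,
    attributed CVD deaths (joint-event deaths split evenly), event survivors
    by originating endpoint (joint survivors split evenly) and the no-event
    survivors.
    """
    if order == "death_first":
        nc_dead = pop * q_nc
        exposed = pop - nc_dead
    elif order == "events_first":
        nc_dead = 0.0  # applied to survivors below
        exposed = pop
    else:
        raise DomainError(f"unknown competing_risk_order {order!r}")

    s_ev = exposed * p_s
    m_ev = exposed * p_m
    # exact survival through both independent event branches
    death_prob = 1.0 - (1.0 - p_s * cf_s) * (1.0 - p_m * cf_m)
    cvd_dead = exposed * death_prob
    joint = p_s * cf_s * p_m * cf_m
    s_dead = exposed * (p_s * cf_s - 0.5 * joint)
    m_dead = exposed * (p_m * cf_m - 0.5 * joint)
    both_surv = p_s * p_m * (1.0 - cf_s) * (1.0 - cf_m)
    surv_s = exposed * (p_s * (1.0 - p_m) * (1.0 - cf_s) + 0.5 * both_surv)
    surv_m = exposed * (p_m * (1.0 - p_s) * (1.0 - cf_m) + 0.5 * both_surv)
    no_event = exposed * (1.0 - p_s) * (1.0 - p_m)

    if order == "events_first":
        # non-CVD death now thins every surviving branch
        keep = 1.0 - q_nc
        nc_dead = (surv_s + surv_m + no_event) * q_nc
        surv_s *= keep
        surv_m *= keep
        no_event *= keep

    return {"nc_dead": nc_dead, "stroke_events": s_ev, "mi_events": m_ev,
            "cvd_dead": cvd_dead, "stroke_deaths": s_dead, "mi_deaths": m_dead,
            "surv_stroke": surv_s, "surv_mi": surv_m, "no_event": no_event}


@dataclass
class _EngineState:
    """Internal 5-compartment state with chronic origin split and mean
    years-in-state clocks (used by the case-fatality escalation formula)."""

    well: float
    chronic_stroke: float
    chronic_mi: float
    dead_cvd: float
    dead_other: float
    tau_stroke: float = 0.0  # mean years since entry, stroke-origin chronic
    tau_mi: float = 0.0

    def public(self) -> StateVector:
        return StateVector(self.well, self.chronic_stroke + self.chronic_mi,
                           self.dead_cvd, self.dead_other)


def _advance(es: _EngineState, probs: dict, order: str,
             esc_stroke: float, esc_mi: float) -> Tuple[_EngineState, dict]:
    """One cycle of the expected-value update; returns next state + tallies."""
    # --- well compartment -------------------------------------------------
    wb = _branch_expectations(es.well, probs["well_p_stroke"], probs["well_cf_stroke"],
                              probs["well_p_mi"], probs["well_cf_mi"],
                              order, probs["well_q_nc"])
    # --- chronic compartments (case fatality optionally escalated with the
    #     compartment's mean time in state) --------------------------------
    out_c = {}
    for origin, pop, tau, q_nc in (
        ("stroke", es.chronic_stroke, es.tau_stroke, probs["chr_q_nc_stroke"]),
        ("mi", es.chronic_mi, es.tau_mi, probs["chr_q_nc_mi"]),
    ):
        cf_s = escalate_probability(probs["chr_cf_stroke"], esc_stroke, tau)
        cf_m = escalate_probability(probs["chr_cf_mi"], esc_mi, tau)
        out_c[origin] = _branch_expectations(pop, probs["chr_p_stroke"], cf_s,
                                             probs["chr_p_mi"], cf_m, order, q_nc)

    cs, cm = out_c["stroke"], out_c["mi"]
    entrants_s = wb["surv_stroke"]
    entrants_m = wb["surv_mi"]
    # chronic survivors stay chronic under their first-event origin
    stay_s = cs["surv_stroke"] + cs["surv_mi"] + cs["no_event"]
    stay_m = cm["surv_stroke"] + cm["surv_mi"] + cm["no_event"]

    next_cs = stay_s + entrants_s
    next_cm = stay_m + entrants_m
    nxt = _EngineState(
        well=wb["no_event"],
        chronic_stroke=next_cs,
        chronic_mi=next_cm,
        dead_cvd=es.dead_cvd + wb["cvd_dead"] + cs["cvd_dead"] + cm["cvd_dead"],
        dead_other=es.dead_other + wb["nc_dead"] + cs["nc_dead"] + cm["nc_dead"],
        tau_stroke=((stay_s * (es.tau_stroke + 1.0)) / next_cs) if next_cs > 0 else 0.0,
        tau_mi=((stay_m * (es.tau_mi + 1.0)) / next_cm) if next_cm > 0 else 0.0,
    )
    tallies = {
        "stroke_events": wb["stroke_events"] + cs["stroke_events"] + cm["stroke_events"],
        "mi_events": wb["mi_events"] + cs["mi_events"] + cm["mi_events"],
        "stroke_deaths": wb["stroke_deaths"] + cs["stroke_deaths"] + cm["stroke_deaths"],
        "mi_deaths": wb["mi_deaths"] + cs["mi_deaths"] + cm["mi_deaths"],
        "new_chronic_stroke": entrants_s,
        "new_chronic_mi": entrants_m,
        # prevalent chronic members surviving the whole cycle, by origin
        "prev_chronic_stroke": stay_s,
        "prev_chronic_mi": stay_m,
        "well_no_event": wb["no_event"],
        # chronic survivors of a recurrent event this cycle, by event type
        "chronic_event_stroke": cs["surv_stroke"] + cm["surv_stroke"],
        "chronic_event_mi": cs["surv_mi"] + cm["surv_mi"],
        "chronic_no_event": cs["no_event"] + cm["no_event"],
        "alive_end": nxt.well + nxt.chronic_stroke + nxt.chronic_mi,
    }
    return nxt, tallies


# ---------------------------------------------------------------------------
# reward accrual

def cost_accrual(*, arm: str, params: ParameterSet, alive: float,
                 mi_events: float, stroke_events: float,
                 new_chronic_mi: float, new_chronic_stroke: float,
                 prev_chronic_mi: float, prev_chronic_stroke: float) -> Tuple[float, float]:
    """Undiscounted cost of one cycle, per person of the starting cohort.

    Returns ``(total, health_system)`` where the health-system share excludes
    the milk product (a consumer expense).  Components: acute inpatient cost
    per event (fatal events included — the admission happens either way);
    first-year chronic cost for new entrants and subsequent-year chronic cost
    for prevalent chronic members, both by origin endpoint; risk-factor
    management (drugs + screening) weighted by the hypertension and
    hypercholesterolemia prevalences for the alive population of both arms;
    and, in the intervention arm only, the milk product for the alive.
    """
    if arm not in ARMS:
        raise DomainError(f"unknown arm {arm!r}")
    c = params.costs
    s = params.settings
    for name, v in (("alive", alive), ("mi_events", mi_events),
                    ("stroke_events", stroke_events)):
        if v < 0:
            raise NumericalContractError(f"cost_accrual: negative {name} = {v}")
    acute = mi_events * c.inpatient_mi.value + stroke_events * c.inpatient_stroke.value
    chronic = (new_chronic_mi * c.chronic_mi_year1_rest.value
               + new_chronic_stroke * c.chronic_stroke_year1_rest
               + prev_chronic_mi * c.chronic_mi_after
               + prev_chronic_stroke * c.chronic_stroke_after)
    mgmt_per_person = (
        s.htn_prevalence * (c.drug_cost_htn.value
                            + c.screen_visits_htn * c.screen_cost_htn.value)
        + s.chol_prevalence * (c.drug_cost_chol.value
                               + c.screen_visits_chol * c.screen_cost_chol.value)
    )
    hs = acute + chronic + alive * mgmt_per_person
    milk = alive * c.milk_price_per_day * 365.0 if arm == "intervention" else 0.0
    total = hs + milk
    if total < 0:
        raise NumericalContractError("cost_accrual: negative total cost")
    return total, hs


def utility_accrual(*, params: ParameterSet, well_no_event: float,
                    new_mi: float, new_stroke: float,
                    chronic_no_event: float,
                    chronic_event_mi: float = 0.0,
                    chronic_event_stroke: float = 0.0) -> float:
    """QALYs accrued in one cycle, per person of the starting cohort.

    Members experiencing an event this cycle contribute the event utility
    (overriding their state utility for the year); surviving chronic members
    without an event contribute the chronic utility; event-free well members
    contribute 1; the dead contribute 0.
    """
    c = params.costs
    return (well_no_event * c.utility_well
            + (new_mi + chronic_event_mi) * c.utility_mi
            + (new_stroke + chronic_event_stroke) * c.utility_stroke
            + chronic_no_event * c.utility_chronic)


# ---------------------------------------------------------------------------
# public stepping / cohort run

def cycle_transition(state: StateVector, age: float, params: ParameterSet,
                     mult: MultiplierTable, years_since_entry: float = 0.0,
                     chronic_stroke_share: Optional[float] = None,
                     arm: str = "do-nothing", cycle: int = 0) -> Tuple[StateVector, CycleRecord]:
    """Advance a public state vector one cycle and tally the cycle's rewards.

    Convenience wrapper over the internal update for callers holding only
    the 4-state view; the chronic origin mix defaults to the configured
    initial split and the escalation clock to ``years_since_entry``.
    """
    if age < 35:
        raise DomainError(f"age {age} below modelled range")
    share = (params.settings.initial_chronic_stroke_share
             if chronic_stroke_share is None else chronic_stroke_share)
    es = _EngineState(state.well, state.chronic * share, state.chronic * (1 - share),
                      state.dead_cvd, state.dead_other,
                      tau_stroke=years_since_entry, tau_mi=years_since_entry)
    probs = cycle_probabilities(params, mult, age)
    nxt, t = _advance(es, probs, params.settings.competing_risk_order,
                      params.settings.escalation_stroke, params.settings.escalation_mi)
    rec = _make_record(cycle, age, nxt.public(), t, arm, params)
    return nxt.public(), rec


def _make_record(cycle: int, age: float, state: StateVector, t: dict,
                 arm: str, params: ParameterSet) -> CycleRecord:
    disc = (1.0 + params.costs.discount_rate) ** (-cycle)
    cost, cost_hs = cost_accrual(
        arm=arm, params=params, alive=t["alive_end"],
        mi_events=t["mi_events"], stroke_events=t["stroke_events"],
        new_chronic_mi=t["new_chronic_mi"], new_chronic_stroke=t["new_chronic_stroke"],
        prev_chronic_mi=t["prev_chronic_mi"], prev_chronic_stroke=t["prev_chronic_stroke"])
    qaly = utility_accrual(
        params=params, well_no_event=t["well_no_event"],
        new_mi=t["new_chronic_mi"], new_stroke=t["new_chronic_stroke"],
        chronic_no_event=t["chronic_no_event"],
        chronic_event_mi=t["chronic_event_mi"],
        chronic_event_stroke=t["chronic_event_stroke"])
    return CycleRecord(
        cycle=cycle, mean_age=age, state=state,
        mi_events=t["mi_events"], stroke_events=t["stroke_events"],
        mi_deaths=t["mi_deaths"], stroke_deaths=t["stroke_deaths"],
        cost_undiscounted=cost, cost_discounted=cost * disc,
        cost_hs_undiscounted=cost_hs, cost_hs_discounted=cost_hs * disc,
        qaly_undiscounted=qaly, qaly_discounted=qaly * disc)


def run_cohort(arm: str, start_age: int, params: ParameterSet,
               mult: Optional[MultiplierTable] = None,
               initial_state: Optional[_EngineState] = None,
               cycle_offset: int = 0,
               horizon: Optional[int] = None,
               probs_cache: Optional[dict] = None) -> CohortTrace:
    """Run one arm's cohort from ``start_age`` over the configured horizon.

    The cohort starts 96.17% well / 3.83% chronic (origin split per config);
    cycle ``k`` happens at age ``start_age + k`` and is discounted by
    ``(1 + r)^-k``.  ``initial_state``/``cycle_offset`` allow resuming a
    trace mid-horizon (used by the prefix/suffix consistency checks).
    """
    s = params.settings
    if not (35 <= start_age <= 75):
        raise DomainError(f"start_age {start_age} outside [35, 75]")
    if mult is None:
        mult = multipliers_for_arm(params, arm)
    if initial_state is None:
        share = s.initial_chronic_stroke_share
        es = _EngineState(
            well=s.initial_well_fraction,
            chronic_stroke=s.initial_chronic_fraction * share,
            chronic_mi=s.initial_chronic_fraction * (1.0 - share),
            dead_cvd=0.0, dead_other=0.0)
    else:
        es = initial_state
    n_cycles = s.horizon if horizon is None else horizon
    records: List[CycleRecord] = []
    for k in range(n_cycles):
        cycle = cycle_offset + k
        age = start_age + cycle
        if probs_cache is not None:
            probs = probs_cache.get(age)
            if probs is None:
                probs = probs_cache[age] = cycle_probabilities(params, mult, age)
        else:
            probs = cycle_probabilities(params, mult, age)
        es, t = _advance(es, probs, s.competing_risk_order,
                         s.escalation_stroke, s.escalation_mi)
        records.append(_make_record(cycle, age, es.public(), t, arm, params))
    trace = CohortTrace(arm=arm, start_age=start_age, records=records).finalize()
    trace._final_engine_state = es  # for resumption / diagnostics
    return trace


def run_all_cohorts(params: ParameterSet) -> Dict[str, Dict[int, CohortTrace]]:
    """Both arms across every configured start age (the base-case grid)."""
    out: Dict[str, Dict[int, CohortTrace]] = {}
    for arm in ARMS:
        mult = multipliers_for_arm(params, arm)
        cache: dict = {}  # cycle ages repeat across start-age bands
        out[arm] = {a: run_cohort(arm, a, params, mult=mult, probs_cache=cache)
                    for a in params.settings.start_ages}
    return out
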