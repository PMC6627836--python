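"""Synthetic inputs for testing: perturbed parameter sets and an
individual-level microsimulation oracle.

The cohort engine propagates expected fractions; the microsimulator draws
the same per-cycle probabilities as Bernoulli outcomes for ``n`` simulated
individuals using exactly the engine's within-cycle ordering (non-CVD death
first, then independent MI/stroke events, each with its case fatality,
joint-event survivors entering the chronic state under a fair-coin origin).
Its aggregate occupancy therefore converges to the cohort trace as ``n``
grows, which is the package's main structural cross-check.

Parameter perturbations are lognormal (median 1) so that rates, costs and
utilities stay positive without rejection loops; values that would leave a
feasible bound are clipped and tallied.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .engine import cycle_probabilities, multipliers_for_arm
from .params import (CostValue, DomainError, EpiTable, ParameterSet)

__all__ = ["PerturbationSpec", "IndividualHistory", "perturb_parameters",
           "microsimulate", "microsim_occupancy"]

# state codes used by the vectorized simulator
WELL, CHRONIC_STROKE, CHRONIC_MI, DEAD_CVD, DEAD_OTHER = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class PerturbationSpec:
    """How to jitter a parameter set: one lognormal factor per scalar."""

    relative_sd: float
    seed: int
    fields_included: Optional[Sequence[str]] = None   # dotted-name prefixes

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise DomainError("relative_sd must be >= 0")


@dataclass(frozen=True)
class IndividualHistory:
    """One simulated person: (cycle, event) pairs and the final state."""

    start_age: int
    events: Tuple[Tuple[int, str], ...]
    final_state: str

    def __post_init__(self) -> None:
        deaths = [e for _, e in self.events if e.startswith("death")]
        if len(deaths) > 1:
            raise DomainError("history records more than one death")
        cycles = [c for c, _ in self.events]
        if cycles != sorted(cycles):
            raise DomainError("history events out of chronological order")


def _included(name: str, prefixes: Optional[Sequence[str]]) -> bool:
    return prefixes is None or any(name.startswith(p) for p in prefixes)


def perturb_parameters(base: ParameterSet, spec: PerturbationSpec) -> ParameterSet:
    """Multiply scalar rates, costs and utilities by independent lognormal
    factors (median 1, sd ≈ ``relative_sd``); re-validated on return.

    Perturbed values that would violate an invariant (utility above 1, case
    fatality above 100%, rate above the per-100,000 ceiling) are clipped to
    the feasible bound; a single warning reports how many were clipped.
    """
    rng = np.random.default_rng(spec.seed)
    sd = spec.relative_sd
    clipped = 0

    def factor() -> float:
        return float(np.exp(rng.normal(0.0, sd))) if sd > 0 else 1.0

    def bounded(name: str, value: float, hi: float) -> float:
        nonlocal clipped
        if not _included(name, spec.fields_included):
            return value
        v = value * factor()
        if v > hi:
            clipped += 1
            v = hi
        return v

    tables = {}
    for tname in ("well", "chronic"):
        src: EpiTable = getattr(base, f"epi_{tname}")
        rows = []
        for i, row in enumerate(src.rows):
            updates = {}
            for col, hi in (("stroke_incidence", 100_000.0), ("mi_incidence", 100_000.0),
                            ("stroke_cf28", 100.0), ("mi_cf30", 100.0),
                            ("noncvd_mortality", 100_000.0),
                            ("noncvd_mortality_stroke", 100_000.0),
                            ("noncvd_mortality_mi", 100_000.0)):
                v = getattr(row, col)
                if v is None:
                    continue
                updates[col] = bounded(f"epi.{tname}.{i}.{col}", v, hi)
            rows.append(dataclasses.replace(row, **updates))
        tables[f"epi_{tname}"] = EpiTable(tname, tuple(rows))

    c = base.costs
    cost_updates: Dict[str, object] = {}
    for name in ("drug_cost_chol", "drug_cost_htn", "screen_cost_chol",
                 "screen_cost_htn", "inpatient_mi", "inpatient_stroke",
                 "chronic_mi_year1_rest"):
        cv: CostValue = getattr(c, name)
        # a perturbed point cost no longer carries the published range
        v = bounded(f"costs.{name}", cv.value, np.inf)
        cost_updates[name] = cv if v == cv.value and sd == 0 else CostValue(v)
    for name in ("screen_visits_chol", "screen_visits_htn", "mi_inpatient_days",
                 "stroke_inpatient_days", "chronic_mi_after",
                 "chronic_stroke_year1_rest", "chronic_stroke_after",
                 "milk_price_per_day"):
        cost_updates[name] = bounded(f"costs.{name}", getattr(c, name), np.inf)
    for name in ("utility_mi", "utility_stroke", "utility_chronic"):
        cost_updates[name] = bounded(f"costs.{name}", getattr(c, name), 1.0)

    out = base.replace(costs=dataclasses.replace(c, **cost_updates), **tables)
    if clipped:
        warnings.warn(f"perturb_parameters: {clipped} value(s) clipped to a feasible bound")
    return out


# ---------------------------------------------------------------------------
# microsimulation

def _simulate(params: ParameterSet, arm: str, start_age: int, n: int,
              seed: int, record_events: bool):
    """Vectorized Bernoulli simulation mirroring the cohort engine's cycle.

    Returns (occupancy counts per cycle [horizon+1, 5] including the initial
    distribution, per-cycle event count dicts, and — when requested — the
    sparse per-individual event log).
    """
    if n < 1:
        raise DomainError("n_individuals must be >= 1")
    s = params.settings
    if not (35 <= start_age <= 75):
        raise DomainError(f"start_age {start_age} outside [35, 75]")
    mult = multipliers_for_arm(params, arm)
    rng = np.random.default_rng(seed)

    state = np.full(n, WELL, dtype=np.int8)
    n_chronic = int(round(n * s.initial_chronic_fraction))
    n_chronic_stroke = int(round(n_chronic * s.initial_chronic_stroke_share))
    state[:n_chronic_stroke] = CHRONIC_STROKE
    state[n_chronic_stroke:n_chronic] = CHRONIC_MI
    rng.shuffle(state)
    entry_cycle = np.zeros(n, dtype=np.int32)   # chronic-entry cycle (P_t clock)

    horizon = s.horizon
    occupancy = np.zeros((horizon + 1, 5), dtype=np.int64)
    occupancy[0] = np.bincount(state, minlength=5)
    events_per_cycle: List[Dict[str, int]] = []
    log: List[Tuple[int, int, str]] = []   # (individual, cycle, event)
    order = s.competing_risk_order

    for cycle in range(horizon):
        age = start_age + cycle
        p = cycle_probabilities(params, mult, age)
        tally = {"stroke_events": 0, "mi_events": 0,
                 "stroke_deaths": 0, "mi_deaths": 0}
        u = rng  # alias
        next_global = state.copy()  # groups must be read from the pre-cycle state

        for group, is_chronic in ((WELL, False), (CHRONIC_STROKE, True),
                                  (CHRONIC_MI, True)):
            idx = np.nonzero(state == group)[0]
            if idx.size == 0:
                continue
            if is_chronic:
                q_nc = (p["chr_q_nc_stroke"] if group == CHRONIC_STROKE
                        else p["chr_q_nc_mi"])
                tau = (cycle - entry_cycle[idx]).astype(float)
                cf_s = np.minimum(
                    1.0, p["chr_cf_stroke"] * (1.0 + s.escalation_stroke) ** tau)
                cf_m = np.minimum(
                    1.0, p["chr_cf_mi"] * (1.0 + s.escalation_mi) ** tau)
                p_s, p_m = p["chr_p_stroke"], p["chr_p_mi"]
            else:
                q_nc = p["well_q_nc"]
                cf_s = p["well_cf_stroke"]
                cf_m = p["well_cf_mi"]
                p_s, p_m = p["well_p_stroke"], p["well_p_mi"]

            nc_dead = u.random(idx.size) < q_nc
            stroke = u.random(idx.size) < p_s
            mi = u.random(idx.size) < p_m
            die_s = stroke & (u.random(idx.size) < cf_s)
            die_m = mi & (u.random(idx.size) < cf_m)
            if order == "death_first":
                at_risk = ~nc_dead
            else:
                at_risk = np.ones(idx.size, dtype=bool)
            stroke &= at_risk
            mi &= at_risk
            die_s &= stroke
            die_m &= mi
            cvd_dead = die_s | die_m
            if order == "events_first":
                # non-CVD death only threatens those not killed by an event
                nc_dead &= ~cvd_dead

            tally["stroke_events"] += int(stroke.sum())
            tally["mi_events"] += int(mi.sum())
            # attribute joint-event deaths by a fair coin, as in the engine's
            # even split of the (tiny) joint term
            both_dead = die_s & die_m
            coin = u.random(idx.size) < 0.5
            s_death = die_s & (~both_dead | coin)
            m_death = die_m & (~both_dead | ~coin)
            tally["stroke_deaths"] += int(s_death.sum())
            tally["mi_deaths"] += int(m_death.sum())

            new_state = np.full(idx.size, group, dtype=np.int8)
            new_state[nc_dead] = DEAD_OTHER
            new_state[cvd_dead] = DEAD_CVD
            survivors = ~nc_dead & ~cvd_dead
            if not is_chronic:
                entrant = survivors & (stroke | mi)
                both = entrant & stroke & mi
                origin_coin = u.random(idx.size) < 0.5
                to_stroke = entrant & (stroke & ~mi | (both & origin_coin))
                to_mi = entrant & (mi & ~stroke | (both & ~origin_coin))
                new_state[to_stroke] = CHRONIC_STROKE
                new_state[to_mi] = CHRONIC_MI
                entry_cycle[idx[entrant]] = cycle + 1
            next_global[idx] = new_state

            if record_events:
                for name, mask in (("stroke", stroke), ("MI", mi),
                                   ("death_cvd", cvd_dead), ("death_other", nc_dead)):
                    for j in idx[mask]:
                        log.append((int(j), cycle, name))

        state = next_global
        occupancy[cycle + 1] = np.bincount(state, minlength=5)
        events_per_cycle.append(tally)

    return occupancy, events_per_cycle, state, log


def microsim_occupancy(params: ParameterSet, arm: str, start_age: int,
                       n_individuals: int, seed: int) -> dict:
    """Aggregate microsimulation output for oracle-vs-engine comparisons.

    Returns per-cycle occupancy *fractions* over the public four states
    (rows: cycle 0 .. horizon) plus per-cycle event/death counts.
    """
    occ, events, _, _ = _simulate(params, arm, start_age, n_individuals, seed, False)
    frac = occ.astype(float) / n_individuals
    public = np.column_stack([frac[:, WELL],
                              frac[:, CHRONIC_STROKE] + frac[:, CHRONIC_MI],
                              frac[:, DEAD_CVD], frac[:, DEAD_OTHER]])
    return {"occupancy": public, "events": events, "n": n_individuals}


_STATE_NAMES = {WELL: "well", CHRONIC_STROKE: "chronic", CHRONIC_MI: "chronic",
                DEAD_CVD: "dead_cvd", DEAD_OTHER: "dead_other"}


def microsimulate(params: ParameterSet, arm: str, start_age: int,
                  n_individuals: int, seed: int) -> List[IndividualHistory]:
    """Simulate ``n_individuals`` and return their event histories."""
    _, _, state, log = _simulate(params, arm, start_age, n_individuals, seed, True)
    per_ind: List[List[Tuple[int, str]]] = [[] for _ in range(n_individuals)]
    for ind, cycle, name in log:
        per_ind[ind].append((cycle, name))
    return [IndividualHistory(start_age, tuple(sorted(ev, key=lambda e: e[0])),
                              _STATE_NAMES[int(state[i])])
            for i, ev in enumerate(per_ind)]
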