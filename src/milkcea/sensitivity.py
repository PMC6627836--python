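"""Deterministic (tornado) and probabilistic sensitivity analysis.

The tornado analysis re-runs the full two-arm comparison at the low and high
value of one parameter at a time — the published range where one exists,
otherwise ±20% — and measures the excursion of the incremental net monetary
benefit at the willingness-to-pay threshold (a metric that, unlike the raw
ICER, stays well-behaved across sign changes).

The probabilistic analysis draws every distribution-assigned parameter
jointly and independently — gamma for costs and resource counts, beta for
utilities, normal with a 5% standard deviation (truncated to the probability
scale) for the age-banded mortality inputs — re-runs both arms per
replicate, and reports the fraction of replicates in which the intervention
is cost-effective at the threshold.  Published point estimates come with
ranges but not standard deviations, so the documented rule is
sd = range width / (2 * 1.96) where a range exists and sd = 20% of the mean
otherwise.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cea import compare, net_monetary_benefit
from .engine import run_all_cohorts
from .params import CostValue, DomainError, EpiTable, ParameterSet

__all__ = ["TornadoBar", "DistributionSpec", "PSASample", "PSAResult",
           "tornado", "fit_gamma", "fit_beta", "run_psa",
           "tornado_parameter_names", "build_distributions"]

RANGE_Z = 2 * 1.96          # range assumed to span mean +/- 1.96 sd
DEFAULT_REL_SD = 0.20       # sd rule when no published range exists
MORTALITY_REL_SD = 0.05     # published rule for mortality inputs


# ---------------------------------------------------------------------------
# moment-matched distribution fits

def fit_gamma(mean: float, sd: float) -> Tuple[float, float]:
    """Moment-matched gamma ``(shape, scale)``: shape=(m/s)^2, scale=s^2/m."""
    if mean <= 0 or sd <= 0:
        raise DomainError(f"gamma moments must be positive (mean={mean}, sd={sd})")
    return (mean / sd) ** 2, sd ** 2 / mean


def fit_beta(mean: float, sd: float) -> Tuple[float, float]:
    """Moment-matched beta ``(alpha, beta)`` for a mean in (0,1)."""
    if not (0 < mean < 1):
        raise DomainError(f"beta mean {mean} outside (0, 1)")
    if sd <= 0 or sd ** 2 >= mean * (1 - mean):
        raise DomainError(f"beta variance {sd**2} infeasible for mean {mean}")
    factor = mean * (1 - mean) / sd ** 2 - 1
    return mean * factor, (1 - mean) * factor


# ---------------------------------------------------------------------------
# scalar-parameter registry (shared by tornado and the PSA)

@dataclass(frozen=True)
class _Param:
    name: str
    get: Callable[[ParameterSet], float]
    set: Callable[[ParameterSet, float], ParameterSet]
    low: Optional[float] = None         # published range, if any
    high: Optional[float] = None
    kind: str = "cost"                  # cost | utility | mortality | share | inert
    bounds: Tuple[float, float] = (0.0, math.inf)


def _set_cost(field: str, wrap: bool) -> Callable[[ParameterSet, float], ParameterSet]:
    def setter(ps: ParameterSet, v: float) -> ParameterSet:
        new = CostValue(v) if wrap else v
        return ps.replace(costs=dataclasses.replace(ps.costs, **{field: new}))
    return setter


def _epi_scale(table: str, column: str) -> Tuple[Callable, Callable]:
    """Scale a whole epi column by a factor (the 'value' is the factor, 1.0)."""

    def get(ps: ParameterSet) -> float:
        return 1.0

    def setter(ps: ParameterSet, factor: float) -> ParameterSet:
        src: EpiTable = getattr(ps, f"epi_{table}")
        cap = 100.0 if column.endswith(("cf28", "cf30")) else 100_000.0
        rows = tuple(
            dataclasses.replace(
                r, **{column: min(cap, getattr(r, column) * factor)})
            for r in src.rows)
        return ps.replace(**{f"epi_{table}": EpiTable(table, rows)})

    return get, setter


def _registry(ps: ParameterSet) -> Dict[str, _Param]:
    c = ps.costs
    reg: Dict[str, _Param] = {}

    def add(p: _Param) -> None:
        reg[p.name] = p

    for field, wrapped, kind in [
        ("drug_cost_chol", True, "cost"), ("drug_cost_htn", True, "cost"),
        ("screen_cost_chol", True, "cost"), ("screen_cost_htn", True, "cost"),
        ("screen_visits_chol", False, "cost"), ("screen_visits_htn", False, "cost"),
        ("inpatient_mi", True, "cost"), ("inpatient_stroke", True, "cost"),
        ("mi_inpatient_days", False, "inert"), ("stroke_inpatient_days", False, "inert"),
        ("chronic_mi_year1_rest", True, "cost"), ("chronic_mi_after", False, "cost"),
        ("chronic_stroke_year1_rest", False, "cost"),
        ("chronic_stroke_after", False, "cost"),
        ("milk_price_per_day", False, "cost"),
    ]:
        v = getattr(c, field)
        if wrapped:
            add(_Param(f"costs.{field}", lambda ps, f=field: getattr(ps.costs, f).value,
                       _set_cost(field, True), v.low, v.high, kind))
        else:
            add(_Param(f"costs.{field}", lambda ps, f=field: getattr(ps.costs, f),
                       _set_cost(field, False), None, None, kind))

    for uname in ("mi", "stroke", "chronic"):
        field = f"utility_{uname}"
        add(_Param(f"utilities.{uname}",
                   lambda ps, f=field: getattr(ps.costs, f),
                   _set_cost(field, False), None, None, "utility", (0.0, 1.0)))

    for table, cols in (("well", ("stroke_incidence", "stroke_cf28", "mi_incidence",
                                  "mi_cf30", "noncvd_mortality")),
                        ("chronic", ("stroke_incidence", "stroke_cf28", "mi_incidence",
                                     "mi_cf30", "noncvd_mortality_stroke",
                                     "noncvd_mortality_mi"))):
        for col in cols:
            get, setter = _epi_scale(table, col)
            kind = "mortality" if ("cf" in col or "noncvd" in col) else "cost"
            add(_Param(f"epi.{table}.{col}", get, setter, None, None, kind))

    for field in ("htn_prevalence", "chol_prevalence"):
        def setter(ps: ParameterSet, v: float, f=field) -> ParameterSet:
            return ps.replace(settings=dataclasses.replace(ps.settings, **{f: v}))
        add(_Param(f"settings.{field}", lambda ps, f=field: getattr(ps.settings, f),
                   setter, None, None, "share", (0.0, 1.0)))
    return reg


def tornado_parameter_names(ps: ParameterSet) -> List[str]:
    """Every scalar input the one-way analysis varies by default."""
    return list(_registry(ps))


# ---------------------------------------------------------------------------
# tornado

@dataclass
class TornadoBar:
    parameter: str
    low_value: float
    high_value: float
    ev_low: float       # incremental NMB at the parameter's low value
    ev_high: float
    width: float


def tornado(params: ParameterSet,
            varied: Optional[Sequence[str]] = None,
            rel_range: float = 0.20) -> List[TornadoBar]:
    """One-way excursions of every varied parameter, sorted by bar width.

    Each parameter is set to its published low/high (Table ranges) or to
    mean*(1 ± ``rel_range``), all else fixed; the expected-value metric is
    the incremental net monetary benefit at the configured threshold.
    """
    reg = _registry(params)
    if varied is None:
        varied = list(reg)
    unknown = [v for v in varied if v not in reg]
    if unknown:
        raise DomainError(
            f"unknown tornado parameter(s) {unknown}; valid names: {sorted(reg)}")
    wtp = params.settings.wtp_per_qaly
    bars = []
    for name in varied:
        p = reg[name]
        base = p.get(params)
        if p.low is not None:
            lo, hi = p.low, p.high
        else:
            lo, hi = base * (1 - rel_range), base * (1 + rel_range)
        lo = max(lo, p.bounds[0])
        hi = min(hi, p.bounds[1])
        evs = []
        for v in (lo, hi):
            res = compare(p.set(params, v))
            evs.append(net_monetary_benefit(res.delta_cost, res.delta_qaly, wtp))
        bars.append(TornadoBar(name, lo, hi, evs[0], evs[1],
                               abs(evs[1] - evs[0])))
    bars.sort(key=lambda b: b.width, reverse=True)
    return bars


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

@dataclass(frozen=True)
class DistributionSpec:
    """One drawn parameter: family and (mean, sd) on the parameter's scale."""

    parameter: str
    family: str            # gamma | beta | normal
    mean: float
    sd: float

    def validate(self) -> None:
        if self.sd == 0:
            return  # degenerate point mass: always the mean
        if self.family == "gamma":
            fit_gamma(self.mean, self.sd)
        elif self.family == "beta":
            fit_beta(self.mean, self.sd)
        elif self.family == "normal":
            if self.sd <= 0:
                raise DomainError(f"{self.parameter}: normal sd must be positive")
        else:
            raise DomainError(f"{self.parameter}: unknown family {self.family!r}")


@dataclass
class PSASample:
    replicate: int
    delta_cost: float
    delta_qaly: float
    cost_effective: bool


@dataclass
class PSAResult:
    samples: List[PSASample]
    fraction_cost_effective: float
    mc_standard_error: float     # binomial SE of the fraction at n replicates
    n_replicates: int
    seed: int


def _sd_from_range(cv: CostValue) -> Optional[float]:
    if cv.low is None:
        return None
    return (cv.high - cv.low) / RANGE_Z


def build_distributions(ps: ParameterSet) -> List[DistributionSpec]:
    """The PSA's parameter -> distribution assignment under the sd rule."""
    c = ps.costs
    specs: List[DistributionSpec] = []

    def gamma(name: str, mean: float, sd: Optional[float]) -> None:
        if mean <= 0:
            return  # a zero cost has nothing to draw
        specs.append(DistributionSpec(name, "gamma", mean,
                                      sd if sd is not None else DEFAULT_REL_SD * mean))

    for field in ("drug_cost_chol", "drug_cost_htn", "screen_cost_chol",
                  "screen_cost_htn", "inpatient_mi", "inpatient_stroke",
                  "chronic_mi_year1_rest"):
        cv: CostValue = getattr(c, field)
        gamma(f"costs.{field}", cv.value, _sd_from_range(cv))
    for field in ("screen_visits_chol", "screen_visits_htn", "mi_inpatient_days",
                  "stroke_inpatient_days", "chronic_mi_after",
                  "chronic_stroke_year1_rest", "chronic_stroke_after",
                  "milk_price_per_day"):
        gamma(f"costs.{field}", getattr(c, field), None)

    for uname in ("mi", "stroke", "chronic"):
        mean = getattr(c, f"utility_{uname}")
        specs.append(DistributionSpec(f"utilities.{uname}", "beta",
                                      mean, DEFAULT_REL_SD * mean))

    # age-banded mortality inputs: 5% sd normals, one per table row and column
    for tname, table, cols in (
        ("well", ps.epi_well, ("stroke_cf28", "mi_cf30", "noncvd_mortality")),
        ("chronic", ps.epi_chronic, ("stroke_cf28", "mi_cf30",
                                     "noncvd_mortality_stroke", "noncvd_mortality_mi")),
    ):
        for i, row in enumerate(table.rows):
            for col in cols:
                mean = getattr(row, col)
                if mean > 0:
                    specs.append(DistributionSpec(f"epi.{tname}.{i}.{col}", "normal",
                                                  mean, MORTALITY_REL_SD * mean))
    for s in specs:
        s.validate()
    return specs


def _draw(spec: DistributionSpec, rng: np.random.Generator) -> float:
    if spec.sd == 0:
        return spec.mean
    if spec.family == "gamma":
        shape, scale = fit_gamma(spec.mean, spec.sd)
        return float(rng.gamma(shape, scale))
    if spec.family == "beta":
        a, b = fit_beta(spec.mean, spec.sd)
        return float(rng.beta(a, b))
    # truncated normal by rejection: probabilities stay on their legal scale
    cap = 100.0 if spec.parameter.endswith(("cf28", "cf30")) else 100_000.0
    for _ in range(1000):
        v = float(rng.normal(spec.mean, spec.sd))
        if 0.0 <= v <= cap:
            return v
    raise DomainError(f"{spec.parameter}: truncated-normal rejection failed")


def _apply_draws(ps: ParameterSet, values: Dict[str, float]) -> ParameterSet:
    cost_updates = {}
    for field in ("drug_cost_chol", "drug_cost_htn", "screen_cost_chol",
                  "screen_cost_htn", "inpatient_mi", "inpatient_stroke",
                  "chronic_mi_year1_rest"):
        key = f"costs.{field}"
        if key in values:
            cost_updates[field] = CostValue(values[key])  # drawn: range no longer applies
    for field in ("screen_visits_chol", "screen_visits_htn", "mi_inpatient_days",
                  "stroke_inpatient_days", "chronic_mi_after",
                  "chronic_stroke_year1_rest", "chronic_stroke_after",
                  "milk_price_per_day"):
        key = f"costs.{field}"
        if key in values:
            cost_updates[field] = values[key]
    for uname in ("mi", "stroke", "chronic"):
        key = f"utilities.{uname}"
        if key in values:
            cost_updates[f"utility_{uname}"] = values[key]
    costs = dataclasses.replace(ps.costs, **cost_updates)

    tables = {}
    for tname in ("well", "chronic"):
        src: EpiTable = getattr(ps, f"epi_{tname}")
        rows = []
        for i, row in enumerate(src.rows):
            row_updates = {}
            for col in ("stroke_cf28", "mi_cf30", "noncvd_mortality",
                        "noncvd_mortality_stroke", "noncvd_mortality_mi"):
                key = f"epi.{tname}.{i}.{col}"
                if key in values:
                    row_updates[col] = values[key]
            rows.append(dataclasses.replace(row, **row_updates) if row_updates else row)
        tables[f"epi_{tname}"] = EpiTable(tname, tuple(rows))
    return ps.replace(costs=costs, **tables)


def run_psa(params: ParameterSet, n_replicates: int = 5000,
            seed: Optional[int] = None,
            distributions: Optional[Sequence[DistributionSpec]] = None) -> PSAResult:
    """Monte Carlo over the parameter distributions with full re-evaluation.

    Each replicate draws all parameters independently, re-runs both arms
    over every start-age band and records the incremental cost/QALY pair;
    a replicate is cost-effective when the intervention dominates or its
    ICER is at or below the willingness-to-pay threshold.
    """
    if n_replicates < 1:
        raise DomainError("n_replicates must be >= 1")
    if seed is None:
        seed = params.settings.random_seed
    specs = list(distributions) if distributions is not None else build_distributions(params)
    for s in specs:
        s.validate()
    rng = np.random.default_rng(seed)
    wtp = params.settings.wtp_per_qaly
    samples: List[PSASample] = []
    n_ce = 0
    for rep in range(n_replicates):
        values = {s.parameter: _draw(s, rng) for s in specs}
        drawn = _apply_draws(params, values)
        traces = run_all_cohorts(drawn)
        w = dict(zip(drawn.settings.start_ages, drawn.settings.age_weights))
        d_cost = sum(w[a] * (traces["intervention"][a].total_cost
                             - traces["do-nothing"][a].total_cost) for a in w)
        d_qaly = sum(w[a] * (traces["intervention"][a].total_qaly
                             - traces["do-nothing"][a].total_qaly) for a in w)
        ce = (d_qaly > 0 and d_cost <= 0) or (d_qaly > 0 and d_cost / d_qaly <= wtp)
        n_ce += ce
        samples.append(PSASample(rep, d_cost, d_qaly, ce))
    frac = n_ce / n_replicates
    se = math.sqrt(frac * (1 - frac) / n_replicates)
    return PSAResult(samples, frac, se, n_replicates, seed)
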