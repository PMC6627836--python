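"""Typed, validated parameter store for the fortified-milk Markov model.

Every model input — the age-banded epidemiology tables, the intervention
effectiveness rows, the cost/utility book and the scalar settings — lives in
one :class:`ParameterSet` that round-trips losslessly through a plain YAML
file.  Rates are kept exactly as published (incidence and non-CVD mortality
per 100,000 person-years, case fatality in percent) so the configuration can
be diffed against the source tables; conversion to per-person probabilities
happens only inside the engine.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "ValidationError",
    "DomainError",
    "AgeBand",
    "EpiRow",
    "EpiTable",
    "EffectRow",
    "CostValue",
    "CostUtilityBook",
    "Settings",
    "ParameterSet",
    "load_parameters",
    "save_parameters",
    "lookup_epi",
    "export_tables",
]

#: open upper bound used to represent "75+" style bands
OPEN_UPPER = 120


class ValidationError(ValueError):
    """A parameter file or parameter object violates a model invariant."""


class DomainError(ValueError):
    """An operation was called outside its domain (e.g. age below 35)."""


@dataclass(frozen=True)
class AgeBand:
    """Closed age interval [lower, upper] in whole years."""

    lower: int
    upper: int

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValidationError(f"age band {self.lower}-{self.upper}: lower must be < upper")

    def contains(self, age: float) -> bool:
        return self.lower <= age <= self.upper

    @property
    def label(self) -> str:
        return f"{self.lower}+" if self.upper >= OPEN_UPPER else f"{self.lower}-{self.upper}"

    @classmethod
    def parse(cls, text: str) -> "AgeBand":
        text = str(text).strip()
        if text.endswith("+"):
            return cls(int(text[:-1]), OPEN_UPPER)
        lo, _, hi = text.partition("-")
        try:
            return cls(int(lo), int(hi))
        except ValueError as exc:
            raise ValidationError(f"cannot parse age band {text!r}") from exc


@dataclass(frozen=True)
class EpiRow:
    """One age band of the incidence / mortality table.

    Incidences and non-CVD mortality are per 100,000 person-years; case
    fatality (28-day stroke, 30-day MI) in percent.  The well table carries a
    single non-CVD mortality column; the chronic table carries separate
    post-stroke and post-MI columns.
    """

    band: AgeBand
    stroke_incidence: float
    stroke_cf28: float
    mi_incidence: float
    mi_cf30: float
    noncvd_mortality: Optional[float] = None
    noncvd_mortality_stroke: Optional[float] = None
    noncvd_mortality_mi: Optional[float] = None

    def validate(self, population: str) -> None:
        where = f"epi_{population} row {self.band.label}"
        for name in ("stroke_incidence", "mi_incidence"):
            v = getattr(self, name)
            if not (0 <= v <= 100_000):
                raise ValidationError(f"{where}: {name}={v} outside [0, 100000]")
        for name in ("stroke_cf28", "mi_cf30"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValidationError(f"{where}: {name}={v} outside [0, 100]")
        if population == "well":
            cols = ("noncvd_mortality",)
        else:
            cols = ("noncvd_mortality_stroke", "noncvd_mortality_mi")
        for name in cols:
            v = getattr(self, name)
            if v is None:
                raise ValidationError(f"{where}: missing field {name}")
            if not (0 <= v <= 100_000):
                raise ValidationError(f"{where}: {name}={v} outside [0, 100000]")


@dataclass(frozen=True)
class EpiTable:
    """Ordered, gap-free epidemiology table for one population."""

    population: str  # "well" | "chronic"
    rows: tuple

    def validate(self) -> None:
        if self.population not in ("well", "chronic"):
            raise ValidationError(f"unknown epi population {self.population!r}")
        if not self.rows:
            raise ValidationError(f"epi_{self.population}: empty table")
        prev = None
        for row in self.rows:
            row.validate(self.population)
            if prev is not None and row.band.lower != prev.band.upper + 1:
                raise ValidationError(
                    f"epi_{self.population}: bands {prev.band.label} and "
                    f"{row.band.label} overlap or leave a gap"
                )
            prev = row
        if self.rows[0].band.lower != 35 or self.rows[-1].band.upper < 79:
            raise ValidationError(f"epi_{self.population}: table must cover ages 35-79")


def lookup_epi(table: EpiTable, age: float) -> EpiRow:
    """Row whose band contains ``age``; ages above the last band clamp to it.

    The published tables stop at 79 while the 40-year horizon does not, so
    rates for ages 80+ are held at the 75-79 row.
    """
    if age < 35:
        raise DomainError(f"age {age} below modelled range (35+)")
    for row in table.rows:
        if row.band.contains(age):
            return row
    return table.rows[-1]


@dataclass(frozen=True)
class EffectRow:
    """One (age band, endpoint) row of the effectiveness table.

    All four columns are percentages; the compounded reduction is the exact
    sum of the LDL-c and SBP pathway reductions and the compounded RR ratio
    its complement.
    """

    band: AgeBand
    endpoint: str  # "stroke" | "mi"
    rr_reduction_ldl: float
    rr_reduction_sbp: float
    rr_reduction_compound: float
    rr_ratio_compound: float

    def validate(self) -> None:
        where = f"effect row ({self.endpoint}, {self.band.label})"
        if self.endpoint not in ("stroke", "mi"):
            raise ValidationError(f"{where}: unknown endpoint")
        for name in ("rr_reduction_ldl", "rr_reduction_sbp", "rr_reduction_compound",
                     "rr_ratio_compound"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValidationError(f"{where}: {name}={v} outside [0, 100]")
        if abs(self.rr_reduction_compound - (self.rr_reduction_ldl + self.rr_reduction_sbp)) > 1e-9:
            raise ValidationError(f"{where}: compounded reduction is not the additive sum")
        if abs(self.rr_ratio_compound - (100.0 - self.rr_reduction_compound)) > 1e-9:
            raise ValidationError(f"{where}: RR ratio is not the complement of the reduction")


@dataclass(frozen=True)
class CostValue:
    """A point cost with an optional published (low, high) range."""

    value: float
    low: Optional[float] = None
    high: Optional[float] = None

    def validate(self, name: str) -> None:
        if self.value < 0:
            raise ValidationError(f"costs.{name}: negative value {self.value}")
        if (self.low is None) != (self.high is None):
            raise ValidationError(f"costs.{name}: range must give both bounds")
        if self.low is not None and not (self.low <= self.value <= self.high):
            raise ValidationError(
                f"costs.{name}: range ({self.low}, {self.high}) does not bracket {self.value}"
            )


@dataclass(frozen=True)
class CostUtilityBook:
    """Costs (2016 int$), resource counts, discount rate and QALY weights."""

    drug_cost_chol: CostValue
    drug_cost_htn: CostValue
    screen_cost_chol: CostValue
    screen_cost_htn: CostValue
    screen_visits_chol: float
    screen_visits_htn: float
    inpatient_mi: CostValue
    inpatient_stroke: CostValue
    mi_inpatient_days: float
    stroke_inpatient_days: float
    chronic_mi_year1_rest: CostValue
    chronic_mi_after: float
    chronic_stroke_year1_rest: float
    chronic_stroke_after: float
    milk_price_per_day: float
    discount_rate: float
    utility_mi: float
    utility_stroke: float
    utility_chronic: float
    utility_well: float
    utility_death: float

    _COST_VALUES = ("drug_cost_chol", "drug_cost_htn", "screen_cost_chol",
                    "screen_cost_htn", "inpatient_mi", "inpatient_stroke",
                    "chronic_mi_year1_rest")
    _SCALARS = ("screen_visits_chol", "screen_visits_htn", "mi_inpatient_days",
                "stroke_inpatient_days", "chronic_mi_after",
                "chronic_stroke_year1_rest", "chronic_stroke_after",
                "milk_price_per_day")

    def validate(self) -> None:
        for name in self._COST_VALUES:
            getattr(self, name).validate(name)
        for name in self._SCALARS:
            if getattr(self, name) < 0:
                raise ValidationError(f"costs.{name}: negative value")
        if not (0 <= self.discount_rate < 1):
            raise ValidationError(f"costs.discount_rate={self.discount_rate} outside [0, 1)")
        for name in ("utility_mi", "utility_stroke", "utility_chronic",
                     "utility_well", "utility_death"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"utilities.{name[8:]}={v} outside [0, 1]")
        if self.utility_death != 0:
            raise ValidationError("utilities.death must be 0")
        if self.utility_well != 1:
            raise ValidationError("utilities.well must be 1")


@dataclass(frozen=True)
class EffectSpec:
    """The intervention's nutrient doses and risk-factor deltas."""

    potassium_delta: float = 1050.28   # mg/day
    phytosterol_delta: float = 1200.0  # mg/day
    sbp_delta: float = -3.68           # mmHg
    ldl_delta: float = -4.81           # % change in LDL-c
    plateau_threshold: float = 2.5     # g/day total phytosterol intake

    def validate(self) -> None:
        if self.sbp_delta > 0:
            raise ValidationError("intervention.sbp_delta must be <= 0 (a reduction)")
        if self.ldl_delta > 0:
            raise ValidationError("intervention.ldl_delta must be <= 0 (a reduction)")


@dataclass(frozen=True)
class Settings:
    """Scalar run settings: horizon, cohort structure, thresholds, seeds."""

    horizon: int = 40
    start_ages: tuple = (35, 40, 45, 50, 55, 60, 65, 70, 75)
    age_weights: tuple = tuple([1.0 / 9] * 9)
    initial_chronic_fraction: float = 0.0383
    initial_well_fraction: float = 0.9617
    initial_chronic_stroke_share: float = 0.5
    population_size: float = 11_100_000
    wtp_per_qaly: float = 27_000.0
    htn_prevalence: float = 0.303
    chol_prevalence: float = 0.477
    annual_health_expenditure: float = 1040.0
    escalation_stroke: float = 0.0
    escalation_mi: float = 0.0
    competing_risk_order: str = "death_first"
    random_seed: int = 12345

    def validate(self) -> None:
        if self.horizon < 1:
            raise ValidationError("settings.horizon must be >= 1")
        if abs(self.initial_chronic_fraction + self.initial_well_fraction - 1.0) > 1e-9:
            raise ValidationError("settings: initial state fractions must sum to 1")
        if len(self.start_ages) != len(self.age_weights):
            raise ValidationError("settings: start_ages and age_weights differ in length")
        if abs(sum(self.age_weights) - 1.0) > 1e-9:
            raise ValidationError("settings.age_weights must sum to 1")
        for a in self.start_ages:
            if not (35 <= a <= 75):
                raise ValidationError(f"settings.start_ages: {a} outside [35, 75]")
        for name in ("htn_prevalence", "chol_prevalence",
                     "initial_chronic_stroke_share"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"settings.{name}={v} outside [0, 1]")
        if self.wtp_per_qaly <= 0:
            raise ValidationError("settings.wtp_per_qaly must be positive")
        if self.escalation_stroke < -1 or self.escalation_mi < -1:
            raise ValidationError("settings: escalation rate below -1")
        if self.competing_risk_order not in ("death_first", "events_first"):
            raise ValidationError(
                f"settings.competing_risk_order={self.competing_risk_order!r}: "
                "expected 'death_first' or 'events_first'"
            )


@dataclass(frozen=True)
class ParameterSet:
    """The complete, validated model parameterization."""

    epi_well: EpiTable
    epi_chronic: EpiTable
    effects: tuple
    costs: CostUtilityBook
    settings: Settings
    intervention: EffectSpec = field(default_factory=EffectSpec)

    def validate(self) -> None:
        self.epi_well.validate()
        self.epi_chronic.validate()
        seen = set()
        for row in self.effects:
            row.validate()
            key = (row.endpoint, row.band.lower, row.band.upper)
            if key in seen:
                raise ValidationError(f"duplicate effect row ({row.endpoint}, {row.band.label})")
            seen.add(key)
        self.costs.validate()
        self.settings.validate()
        self.intervention.validate()

    def replace(self, **kwargs) -> "ParameterSet":
        """Functional update returning a re-validated copy."""
        data = {"epi_well": self.epi_well, "epi_chronic": self.epi_chronic,
                "effects": self.effects, "costs": self.costs,
                "settings": self.settings, "intervention": self.intervention}
        data.update(kwargs)
        ps = ParameterSet(**data)
        ps.validate()
        return ps


# ---------------------------------------------------------------------------
# (de)serialization

def _epi_row_from_dict(d: dict, population: str) -> EpiRow:
    try:
        band = AgeBand.parse(d["ages"])
        return EpiRow(
            band=band,
            stroke_incidence=float(d["stroke_incidence"]),
            stroke_cf28=float(d["stroke_cf28"]),
            mi_incidence=float(d["mi_incidence"]),
            mi_cf30=float(d["mi_cf30"]),
            noncvd_mortality=(float(d["noncvd_mortality"])
                              if "noncvd_mortality" in d else None),
            noncvd_mortality_stroke=(float(d["noncvd_mortality_stroke"])
                                     if "noncvd_mortality_stroke" in d else None),
            noncvd_mortality_mi=(float(d["noncvd_mortality_mi"])
                                 if "noncvd_mortality_mi" in d else None),
        )
    except KeyError as exc:
        raise ValidationError(f"epi_{population} row {d.get('ages', '?')}: missing field {exc}")


def parameters_from_dict(doc: dict) -> ParameterSet:
    try:
        epi = doc["epidemiology"]
        well = EpiTable("well", tuple(_epi_row_from_dict(r, "well") for r in epi["well"]))
        chronic = EpiTable("chronic",
                           tuple(_epi_row_from_dict(r, "chronic") for r in epi["chronic"]))
        effects = tuple(
            EffectRow(
                band=AgeBand.parse(r["ages"]),
                endpoint=str(r["endpoint"]).lower(),
                rr_reduction_ldl=float(r["rr_reduction_ldl"]),
                rr_reduction_sbp=float(r["rr_reduction_sbp"]),
                rr_reduction_compound=float(r["rr_reduction_compound"]),
                rr_ratio_compound=float(r["rr_ratio_compound"]),
            )
            for r in doc["effects"]
        )
        c = doc["costs"]

        def costval(name: str) -> CostValue:
            v = c[name]
            if isinstance(v, dict):
                rng = v.get("range")
                if rng is not None:
                    return CostValue(float(v["value"]), float(rng[0]), float(rng[1]))
                return CostValue(float(v["value"]))
            return CostValue(float(v))

        u = doc["utilities"]
        costs = CostUtilityBook(
            drug_cost_chol=costval("drug_cost_chol"),
            drug_cost_htn=costval("drug_cost_htn"),
            screen_cost_chol=costval("screen_cost_chol"),
            screen_cost_htn=costval("screen_cost_htn"),
            screen_visits_chol=float(c["screen_visits_chol"]),
            screen_visits_htn=float(c["screen_visits_htn"]),
            inpatient_mi=costval("inpatient_mi"),
            inpatient_stroke=costval("inpatient_stroke"),
            mi_inpatient_days=float(c["mi_inpatient_days"]),
            stroke_inpatient_days=float(c["stroke_inpatient_days"]),
            chronic_mi_year1_rest=costval("chronic_mi_year1_rest"),
            chronic_mi_after=float(c["chronic_mi_after"]),
            chronic_stroke_year1_rest=float(c["chronic_stroke_year1_rest"]),
            chronic_stroke_after=float(c["chronic_stroke_after"]),
            milk_price_per_day=float(c["milk_price_per_day"]),
            discount_rate=float(c["discount_rate"]),
            utility_mi=float(u["mi"]),
            utility_stroke=float(u["stroke"]),
            utility_chronic=float(u["chronic"]),
            utility_well=float(u["well"]),
            utility_death=float(u["death"]),
        )
        s = doc["settings"]
        esc = s.get("annual_mortality_escalation", {}) or {}
        settings = Settings(
            horizon=int(s["horizon"]),
            start_ages=tuple(int(a) for a in s["start_ages"]),
            age_weights=tuple(float(w) for w in s["age_weights"]),
            initial_chronic_fraction=float(s["initial_chronic_fraction"]),
            initial_well_fraction=float(s["initial_well_fraction"]),
            initial_chronic_stroke_share=float(s.get("initial_chronic_stroke_share", 0.5)),
            population_size=float(s["population_size"]),
            wtp_per_qaly=float(s["wtp_per_qaly"]),
            htn_prevalence=float(s["htn_prevalence"]),
            chol_prevalence=float(s["chol_prevalence"]),
            annual_health_expenditure=float(s.get("annual_health_expenditure", 1040.0)),
            escalation_stroke=float(esc.get("stroke", 0.0)),
            escalation_mi=float(esc.get("mi", 0.0)),
            competing_risk_order=str(s.get("competing_risk_order", "death_first")),
            random_seed=int(s.get("random_seed", 12345)),
        )
        iv = doc.get("intervention", {}) or {}
        spec = EffectSpec(
            potassium_delta=float(iv.get("potassium_delta_mg_day", 1050.28)),
            phytosterol_delta=float(iv.get("phytosterol_delta_mg_day", 1200.0)),
            sbp_delta=float(iv.get("sbp_delta_mmhg", -3.68)),
            ldl_delta=float(iv.get("ldl_delta_pct", -4.81)),
            plateau_threshold=float(iv.get("phytosterol_plateau_g_day", 2.5)),
        )
    except KeyError as exc:
        raise ValidationError(f"parameter file: missing field {exc}")
    ps = ParameterSet(well, chronic, effects, costs, settings, spec)
    ps.validate()
    return ps


def parameters_to_dict(ps: ParameterSet) -> dict:
    def epi_row(row: EpiRow, population: str) -> dict:
        d = {"ages": row.band.label,
             "stroke_incidence": row.stroke_incidence,
             "stroke_cf28": row.stroke_cf28,
             "mi_incidence": row.mi_incidence,
             "mi_cf30": row.mi_cf30}
        if population == "well":
            d["noncvd_mortality"] = row.noncvd_mortality
        else:
            d["noncvd_mortality_stroke"] = row.noncvd_mortality_stroke
            d["noncvd_mortality_mi"] = row.noncvd_mortality_mi
        return d

    def costval(cv: CostValue) -> object:
        if cv.low is None:
            return {"value": cv.value}
        return {"value": cv.value, "range": [cv.low, cv.high]}

    c, s, iv = ps.costs, ps.settings, ps.intervention
    return {
        "epidemiology": {
            "well": [epi_row(r, "well") for r in ps.epi_well.rows],
            "chronic": [epi_row(r, "chronic") for r in ps.epi_chronic.rows],
        },
        "effects": [
            {"ages": r.band.label, "endpoint": r.endpoint,
             "rr_reduction_ldl": r.rr_reduction_ldl,
             "rr_reduction_sbp": r.rr_reduction_sbp,
             "rr_reduction_compound": r.rr_reduction_compound,
             "rr_ratio_compound": r.rr_ratio_compound}
            for r in ps.effects
        ],
        "intervention": {
            "potassium_delta_mg_day": iv.potassium_delta,
            "phytosterol_delta_mg_day": iv.phytosterol_delta,
            "sbp_delta_mmhg": iv.sbp_delta,
            "ldl_delta_pct": iv.ldl_delta,
            "phytosterol_plateau_g_day": iv.plateau_threshold,
        },
        "costs": {
            "drug_cost_chol": costval(c.drug_cost_chol),
            "drug_cost_htn": costval(c.drug_cost_htn),
            "screen_cost_chol": costval(c.screen_cost_chol),
            "screen_cost_htn": costval(c.screen_cost_htn),
            "screen_visits_chol": c.screen_visits_chol,
            "screen_visits_htn": c.screen_visits_htn,
            "inpatient_mi": costval(c.inpatient_mi),
            "inpatient_stroke": costval(c.inpatient_stroke),
            "mi_inpatient_days": c.mi_inpatient_days,
            "stroke_inpatient_days": c.stroke_inpatient_days,
            "chronic_mi_year1_rest": costval(c.chronic_mi_year1_rest),
            "chronic_mi_after": c.chronic_mi_after,
            "chronic_stroke_year1_rest": c.chronic_stroke_year1_rest,
            "chronic_stroke_after": c.chronic_stroke_after,
            "milk_price_per_day": c.milk_price_per_day,
            "discount_rate": c.discount_rate,
        },
        "utilities": {
            "mi": c.utility_mi, "stroke": c.utility_stroke,
            "chronic": c.utility_chronic, "well": c.utility_well,
            "death": c.utility_death,
        },
        "settings": {
            "horizon": s.horizon,
            "start_ages": list(s.start_ages),
            "age_weights": list(s.age_weights),
            "initial_chronic_fraction": s.initial_chronic_fraction,
            "initial_well_fraction": s.initial_well_fraction,
            "initial_chronic_stroke_share": s.initial_chronic_stroke_share,
            "population_size": s.population_size,
            "wtp_per_qaly": s.wtp_per_qaly,
            "htn_prevalence": s.htn_prevalence,
            "chol_prevalence": s.chol_prevalence,
            "annual_health_expenditure": s.annual_health_expenditure,
            "annual_mortality_escalation": {"stroke": s.escalation_stroke,
                                            "mi": s.escalation_mi},
            "competing_risk_order": s.competing_risk_order,
            "random_seed": s.random_seed,
        },
    }


def default_parameter_path() -> Path:
    return Path(importlib.resources.files("milkcea") / "data" / "base_case.yaml")


def load_parameters(path: Optional[str] = None) -> ParameterSet:
    """Load and validate a parameter file (the packaged base case by default)."""
    p = Path(path) if path is not None else default_parameter_path()
    with open(p, "r") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValidationError(f"{p}: not a mapping")
    return parameters_from_dict(doc)


def save_parameters(ps: ParameterSet, path: str) -> None:
    """Write a ParameterSet back to YAML (stable key order, lossless)."""
    with open(path, "w") as fh:
        yaml.safe_dump(parameters_to_dict(ps), fh, sort_keys=False)


def export_tables(ps: ParameterSet, outdir: str) -> dict:
    """Dump each table to CSV for inspection; returns {name: path}."""
    import pandas as pd

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    doc = parameters_to_dict(ps)
    for name in ("well", "chronic"):
        df = pd.DataFrame(doc["epidemiology"][name])
        paths[f"epi_{name}"] = str(out / f"epi_{name}.csv")
        df.to_csv(paths[f"epi_{name}"], index=False)
    df = pd.DataFrame(doc["effects"])
    paths["effects"] = str(out / "effects.csv")
    df.to_csv(paths["effects"], index=False)
    flat = []
    for k, v in doc["costs"].items():
        if isinstance(v, dict):
            flat.append({"parameter": k, "value": v["value"],
                         "low": v.get("range", [None, None])[0],
                         "high": v.get("range", [None, None])[1]})
        else:
            flat.append({"parameter": k, "value": v, "low": None, "high": None})
    for k, v in doc["utilities"].items():
        flat.append({"parameter": f"utility_{k}", "value": v, "low": None, "high": None})
    df = pd.DataFrame(flat)
    paths["costs"] = str(out / "costs.csv")
    df.to_csv(paths["costs"], index=False)
    return paths
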