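# milkcea

A Markov cohort cost-effectiveness model of a milk powder fortified with
potassium (+1050.28 mg/day) and phytosterols (+1200 mg/day), offered to the
Malaysian adult population aged 35–75 to lower systolic blood pressure and
LDL cholesterol and, through them, the risk of myocardial infarction (MI)
and stroke. The comparator is a do-nothing option, the perspective
governmental, the horizon 40 one-year cycles, and costs and QALYs are
discounted at 3%/year. The package is aimed at health-economics and
epidemiological-modelling work: every input is a validated, editable
configuration value, and every published table ships as the packaged base
case.

## Model

A cohort starts 96.17% in a *well* state and 3.83% in a *chronic CVD*
state and moves through four aggregate states — well, chronic CVD, CVD
death, other death. MI and stroke are within-cycle branch events: an event
either kills within 30/28 days (case fatality) or leaves the survivor in
the chronic state. Event risks are age-banded annual incidences *I(a)*
(per 100,000); the intervention multiplies them by an age-banded relative
risk

    RR(a) = 1 − [ ΔRR_LDL(a) + ΔRR_SBP(a) ] / 100,

where the SBP-pathway reduction is linearly interpolated from 10 mmHg
reference estimates to the −3.68 mmHg achieved by the potassium dose and
the two pathway reductions compound additively. Per person, the comparison
reports

    ΔC = C_int − C_donothing,   ΔE = Q_int − Q_donothing,   ICER = ΔC / ΔE,

with the WHO GDP-per-capita threshold classifying the result (≤1× GDP per
capita: very cost-effective; ≤3×: cost-effective). A one-way tornado
analysis and a 5000-replicate probabilistic sensitivity analysis (gamma
costs, beta utilities, normal ±5% mortality) quantify parameter
uncertainty, and an individual-level microsimulation oracle validates the
cohort engine. docs/methods.md documents every convention and its
rationale.

## Worked example

```python
from milkcea import load_parameters, compare

params = load_parameters()          # packaged base case
result = compare(params)
print(f"ICER int$ {result.icer:,.2f}/QALY -> {result.who_class}")
print(f"strokes prevented nationwide: {result.events_prevented['stroke']:,.0f}")
```

prints

```
ICER int$ 4,366.63/QALY -> very cost-effective
strokes prevented nationwide: 736,719
```

that is: per person the intervention adds int$1,375.56 of discounted cost
(the milk product, net of treatment savings) and 0.3150 discounted QALYs,
an incremental cost-effectiveness ratio of int$4,367 per QALY gained —
far below a GDP-per-capita willingness to pay — while preventing about
737,000 strokes among the 11.1 million adults over 40 years. The
`analysis/` scripts run the full study end to end and write tables under
`results/`:

```sh
python analysis/01_base_case.py     # traces, ICER, projections, savings
python analysis/02_tornado.py      # one-way sensitivity ranking
python analysis/03_psa.py          # 5000-replicate Monte Carlo
python analysis/04_microsim_validation.py   # engine vs individual-level oracle
```

Note that the headline figures computed from the packaged input tables
differ from the originally published summary estimates; docs/methods.md
("Relation to the published results") quantifies and discusses the
discrepancy.

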