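# Methods

## Model structure

Two strategies — fortified milk powder for every 35–75-year-old versus
doing nothing — are evaluated with the same Markov cohort structure and
different transition probabilities. The cohort occupies four aggregate
states: **well**, **chronic CVD** (survivors of a prior MI or stroke),
**CVD death** and **other death**. Cycles are one year with no half-cycle
correction (full-cycle accounting). MI and stroke are *transient
within-cycle branches*, not persistent states: in the cycle an event
occurs it resolves either to death (30-day MI / 28-day stroke case
fatality) or to membership of the chronic state from the next cycle on.

The chronic compartment is internally split by origin (post-stroke vs
post-MI) because its published non-CVD mortality and maintenance costs are
endpoint-specific, while the public state vector pools the two. Members
keep their first-event origin; a recurrent event does not re-label them
(it incurs the acute cost and the event utility, but its survivor is
already prevalent). The 3.83% of the cohort that starts chronic is split
50/50 between origins — the split is not published — and is configurable.

Within a cycle, competing risks resolve **non-CVD death first**; MI and
stroke then act as independent Bernoulli risks on the survivors, each with
its own case fatality (a joint event kills unless both fatality draws are
survived; the expected-value engine uses the exact factorized survival
`(1 − p_s·cf_s)(1 − p_m·cf_m)`, so occupancy is conserved to machine
precision). The alternative `events_first` ordering is a configuration
switch because the choice is not published and materially affects results
(in the base case it moves the ICER by about 3%).

## Inputs

All inputs are stored exactly as published — incidences and non-CVD
mortality per 100,000 person-years, case fatality in percent, costs in
2016 international dollars — and converted to per-person probabilities
only inside the engine, keeping the configuration diffable against the
source tables. The published epidemiology stops at age 79; because a
cohort starting at 75 reaches age 114 over the 40-year horizon, all rates
clamp at the 75–79 band thereafter (conservative, data-faithful
extrapolation).

Chronic-state case fatality supports the escalation
`P_t = min(1, P_0 (1 + rate)^t)` with `t` the years since chronic entry.
The annual rates were derived by the original analysis from 28-day vs
1-year survival inputs that are not published, so they default to 0 (no
escalation) and must be set explicitly. The cohort engine tracks `t` as
the occupancy-weighted mean years-in-state per origin compartment; the
microsimulator uses each individual's exact clock. The two coincide at
rate 0, which is what the equivalence tests exercise.

## Intervention effectiveness

Two independent pathways: potassium (+1050.28 mg/day) lowers SBP by
3.68 mmHg; phytosterols (+1200 mg/day) lower LDL-c by 4.81%. (The
published effectiveness-table header reads "3.86 mmHg", which contradicts
both the methods text and the table note; 3.86 is treated as a typo for
3.68. The phytosterol effect is implicitly assumed to stay below the
2.5 g/day plateau of the dose-response.) Age-banded relative-risk
reductions quoted for a 10 mmHg SBP decrease are scaled *linearly on the
RR-reduction scale* — `reduction × |ΔSBP| / 10` — the only convention that
reproduces the published SBP column within print rounding (20 pp at 35–44
stroke back-solves to 54.35 pp at the reference, and 54.35 × 0.368 =
20.0008). The LDL column is consumed as given (it is already
prevalence-weighted; the strata needed to recompute it are not published).
The two reductions compound additively and the complement, divided by 100,
is the incidence multiplier. Multipliers apply to event *incidence* —
first-ever and recurrent, in both living states — never to case fatality.
The do-nothing arm uses multiplier 1 everywhere.

## Costs and utilities

Per cycle and per person of the starting cohort:

- **Acute**: each MI costs int$9,491.00 and each stroke int$4,994.96,
  fatal events included (the admission happens either way).
- **Chronic maintenance**: new entrants pay the rest-of-first-year cost
  (MI 305.23, stroke 611.55), prevalent survivors the subsequent-year cost
  (MI 305.23, stroke 166.59), weighted by the compartment's origin mix.
- **Risk-factor management**: drugs plus screening visits weighted by the
  hypertension (30.3%) and hypercholesterolemia (47.7%) prevalences,
  charged to the alive fraction of *both* arms (who incurs them is not
  published; both-arm accrual is conservative, cancelling in the increment
  except through survival differences).
- **Milk**: int$0.5 × 365 per alive person, intervention arm only.

Management and milk costs accrue to the end-of-cycle alive fraction.
Utilities: well 1, chronic 0.64, death 0; members experiencing an event
contribute the event utility that year (MI 0.45, stroke 0.56), overriding
their state utility. Cycle *k* rewards are discounted by 1.03^−k (cycle 0
undiscounted).

## Outputs

The headline comparison weights per-person discounted totals across the
nine 5-year start-age bands 35…75. Only the 11.1 M population total is
published, so the default age weights are uniform (configurable);
per-start-age ICERs are reported alongside. The ICER includes the milk
price as the intervention's cost; excluding it would make the benefits
free by construction. The **annual savings** figure is the opposite
convention by design: (do-nothing − intervention) discounted
*health-system* costs, milk excluded, divided by the 40-year horizon, also
expressed against the int$1,040 annual health expenditure per capita.
Nationwide projections multiply age-weighted per-person cumulative event
and death differences by 11.1 M. WHO threshold classification resolves the
1× and 3× GDP boundaries downward (≤).

## Sensitivity analyses

**Tornado.** Each varied parameter is set to its published range ends, or
mean ± 20% where no range is published, all else fixed, and the full
comparison re-run. The expected-value metric is the incremental net
monetary benefit at the willingness-to-pay threshold (the raw ICER is
unstable under sign changes; the metric is switchable). The default varied
list covers every cost and resource scalar, the three non-degenerate
utilities, the two prevalences, and each epidemiology column as a ±20%
scale factor — 31 bars; the list is user-restrictable. Parameters the
model never reads (the inpatient-day counts, which are descriptive only)
produce exactly zero-width bars.

**PSA.** 5000 replicates; per replicate every distribution-assigned
parameter is drawn independently and both arms re-run. Costs and resource
counts (the milk price included) are gamma; utilities are beta; each
age-banded mortality input (case fatalities and non-CVD rates) is normal
with sd = 5% of its mean, truncated to its legal scale by rejection. All
fits are moment-matched. Standard deviations are not published, so the
documented rule is sd = range/(2×1.96) where a published range exists,
else sd = 20% of the mean. Draws are independent (no correlation structure
is published). A replicate is cost-effective when the intervention
dominates or its ICER is at or below the threshold; the fraction is
reported with its binomial Monte Carlo standard error.

The willingness-to-pay threshold itself (GDP per capita) is not published
with the model inputs; the packaged default is int$27,000 (Malaysia, PPP,
2016) and it is an explicit configuration field.

## Synthetic data and validation

`synthetic.perturb_parameters` jitters every scalar rate, cost and utility
with independent lognormal factors (median 1, sd ≈ the requested relative
sd) — lognormal so positivity survives without rejection loops — clipping
at feasible bounds with a warning tally. It exists for robustness and
recovery tests, not to emulate sampling variability of any real data
source.

`synthetic.microsimulate` draws individual Bernoulli trajectories with
*exactly* the engine's per-cycle probabilities and ordering. Its aggregate
occupancy is a binomial estimate of the cohort trace, which grounds the
package's main structural check: at n = 200,000 per arm, every
(cycle, state) occupancy must match the cohort value within the 3-standard-
error criterion applied *jointly* across the 160 cells (Šidák-corrected
threshold ≈ 4.3; a per-cell 3-SE bound false-alarms on the maximum of 160
comparisons for roughly a third of seeds even when — as replicated
averaging confirms, mean z ≈ 0, mean z² ≈ 1 — the engine is the true
large-n limit).

The cohort is parameter-homogeneous within an age band: no individual
risk-factor covariates, no secular trends in prevalence or incidence, no
treatment lag between risk-factor change and event-risk change. Passing
tests therefore demonstrate internal consistency of the engine, the
accounting and the published-table plumbing — not external validity of
the epidemiology.

## Relation to the published results

The originally published summary of this analysis reports an ICER of
int$22,518.03/QALY, at least 13,400 MIs and 30,500 strokes prevented
(−7% / −20%), more than 10,600 / 17,100 MI- and stroke-related deaths
prevented, annual health-system savings of int$8.1 per person (0.7% of
int$1,040), and a 58.3% cost-effective PSA fraction.

Recomputing from the published input tables under their stated per-annum
reading, this package obtains an ICER of int$4,366.63/QALY, 411,231 MIs
and 736,719 strokes prevented (−11.6% / −11.7%), 212,652 / 162,649 deaths
prevented, savings of int$12.82 per person per year (1.23%), and a PSA
fraction of 100%. The prevented-event bounds are met by a wide margin, but
the ratio-type figures are not reconcilable with the published ones under
any convention this package exposes: the published prevented-event counts
imply baseline event risks roughly 20–40× smaller than the published
incidence tables produce, and no uniform rescaling of the intervention
effect matches the published ICER (which would need ~4.4× smaller
increments) and the published savings (~1.6× smaller) simultaneously. The
structural switches that move the result — competing-risk ordering,
restricting multipliers to first-ever events, excluding management costs,
single-age cohorts — shift the ICER between roughly int$2,000 and
int$6,600/QALY, never near the published value. The package therefore
reports what the published inputs compute, with every convention
documented above and switchable.

## Problem sizes and runtime

The deterministic base case (2 arms × 9 start ages × 40 cycles) runs in
milliseconds; the 31-bar tornado re-runs it 62 times (<1 s); the PSA
re-runs it 5,000 times (~35 s on one CPU); the validation microsimulation
uses 200,000 individuals per arm (<1 s, vectorized). These are the sizes
used throughout the tests and the analysis scripts.

## Known limitations

- The age-band clamp above 79 holds late-life mortality flat at the 75–79
  level, understating it at high ages; with the published rates almost no
  cohort mass survives there, so the effect is negligible.
- Attribution of a joint MI+stroke death (or joint-event chronic entry) is
  split evenly between endpoints; the joint term is second-order
  (< 10⁻³ of events) in every published-parameter scenario.
- The mean-time-in-state approximation for the case-fatality escalation
  clock is exact only at rate 0 (the default); at non-zero rates the
  cohort engine and the microsimulation diverge by design, the
  microsimulation being the reference.
- Uniform age weights are an assumption; the published analysis gives only
  the 11.1 M population total.
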