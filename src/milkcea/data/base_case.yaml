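# Base-case parameterization: Markov cohort model of a potassium- and
# phytosterol-fortified milk powder vs do-nothing, Malaysian adults 35-75.
#
# Rates are stored exactly as published (incidence and non-CVD mortality per
# 100,000 person-years; case fatality in %) and converted to per-person
# probabilities only inside the engine, so this file stays diffable against
# the source tables.
#
# Note on the SBP column of the effectiveness table: the published table
# header reads "3.86 mmHg" but the accompanying note and the methods text
# both state the reductions were interpolated to a 3.68 mmHg SBP decrease
# (the effect of +1050.28 mg/day potassium); 3.86 is treated as a typo and
# 3.68 is the value used throughout.

epidemiology:
  well:
    - {ages: 35-39, stroke_incidence: 425,  stroke_cf28: 17.80, mi_incidence: 11.4,  mi_cf30: 7.10,  noncvd_mortality: 74.6}
    - {ages: 40-44, stroke_incidence: 850,  stroke_cf28: 18.52, mi_incidence: 43.7,  mi_cf30: 12.55, noncvd_mortality: 74.6}
    - {ages: 45-49, stroke_incidence: 850,  stroke_cf28: 19.27, mi_incidence: 43.7,  mi_cf30: 12.55, noncvd_mortality: 2365.2}
    - {ages: 50-54, stroke_incidence: 1700, stroke_cf28: 20.05, mi_incidence: 101.2, mi_cf30: 12.55, noncvd_mortality: 2365.2}
    - {ages: 55-59, stroke_incidence: 1700, stroke_cf28: 20.86, mi_incidence: 101.2, mi_cf30: 12.55, noncvd_mortality: 4655.8}
    - {ages: 60-64, stroke_incidence: 2000, stroke_cf28: 21.70, mi_incidence: 141.8, mi_cf30: 31.35, noncvd_mortality: 4655.8}
    - {ages: 65-69, stroke_incidence: 3000, stroke_cf28: 22.55, mi_incidence: 141.8, mi_cf30: 31.35, noncvd_mortality: 6946.4}
    - {ages: 70-74, stroke_incidence: 3500, stroke_cf28: 23.42, mi_incidence: 173.2, mi_cf30: 31.35, noncvd_mortality: 6946.4}
    - {ages: 75-79, stroke_incidence: 7800, stroke_cf28: 24.33, mi_incidence: 173.2, mi_cf30: 31.35, noncvd_mortality: 6946.4}
  chronic:
    - {ages: 35-39, stroke_incidence: 13000, stroke_cf28: 21.43, mi_incidence: 24400, mi_cf30: 53.00, noncvd_mortality_stroke: 7870.9, noncvd_mortality_mi: 5260}
    - {ages: 40-44, stroke_incidence: 13000, stroke_cf28: 22.30, mi_incidence: 24400, mi_cf30: 54.08, noncvd_mortality_stroke: 7870.9, noncvd_mortality_mi: 5260}
    - {ages: 45-49, stroke_incidence: 14560, stroke_cf28: 23.20, mi_incidence: 24400, mi_cf30: 54.08, noncvd_mortality_stroke: 8107,   noncvd_mortality_mi: 5417.8}
    - {ages: 50-54, stroke_incidence: 16307, stroke_cf28: 24.13, mi_incidence: 24400, mi_cf30: 55.16, noncvd_mortality_stroke: 8107,   noncvd_mortality_mi: 5417.8}
    - {ages: 55-59, stroke_incidence: 18264, stroke_cf28: 25.11, mi_incidence: 24400, mi_cf30: 55.16, noncvd_mortality_stroke: 8350.2, noncvd_mortality_mi: 5580.3}
    - {ages: 60-64, stroke_incidence: 20446, stroke_cf28: 26.13, mi_incidence: 24400, mi_cf30: 56.92, noncvd_mortality_stroke: 8350.2, noncvd_mortality_mi: 5580.9}
    - {ages: 65-69, stroke_incidence: 22910, stroke_cf28: 27.14, mi_incidence: 36700, mi_cf30: 56.92, noncvd_mortality_stroke: 8600.7, noncvd_mortality_mi: 5747.7}
    - {ages: 70-74, stroke_incidence: 25659, stroke_cf28: 28.19, mi_incidence: 36700, mi_cf30: 58.05, noncvd_mortality_stroke: 8600.7, noncvd_mortality_mi: 5747.7}
    - {ages: 75-79, stroke_incidence: 28739, stroke_cf28: 29.29, mi_incidence: 36700, mi_cf30: 58.05, noncvd_mortality_stroke: 8600.7, noncvd_mortality_mi: 5747.7}

# Relative-risk reductions (percentage points) per 10-year age band from the
# LDL-c pathway (phytosterols, prevalence-weighted) and the SBP pathway
# (potassium, interpolated from 10 mmHg estimates to -3.68 mmHg), compounded
# additively; the compounded RR ratio is the complement (100 - reduction).
effects:
  - {ages: 35-44, endpoint: stroke, rr_reduction_ldl: 1.96, rr_reduction_sbp: 20,    rr_reduction_compound: 21.96, rr_ratio_compound: 78.04}
  - {ages: 45-54, endpoint: stroke, rr_reduction_ldl: 2.60, rr_reduction_sbp: 20,    rr_reduction_compound: 22.60, rr_ratio_compound: 77.40}
  - {ages: 55-64, endpoint: stroke, rr_reduction_ldl: 2.61, rr_reduction_sbp: 16.5,  rr_reduction_compound: 19.11, rr_ratio_compound: 80.89}
  - {ages: 65-74, endpoint: stroke, rr_reduction_ldl: 2.46, rr_reduction_sbp: 11.10, rr_reduction_compound: 13.56, rr_ratio_compound: 86.44}
  - {ages: 75+,   endpoint: stroke, rr_reduction_ldl: 2.34, rr_reduction_sbp: 9,     rr_reduction_compound: 11.34, rr_ratio_compound: 88.66}
  - {ages: 35-44, endpoint: mi, rr_reduction_ldl: 1.96, rr_reduction_sbp: 16,   rr_reduction_compound: 17.96, rr_ratio_compound: 82.04}
  - {ages: 45-54, endpoint: mi, rr_reduction_ldl: 2.60, rr_reduction_sbp: 16,   rr_reduction_compound: 18.60, rr_ratio_compound: 81.40}
  - {ages: 55-64, endpoint: mi, rr_reduction_ldl: 2.61, rr_reduction_sbp: 12.5, rr_reduction_compound: 15.11, rr_ratio_compound: 84.89}
  - {ages: 65-74, endpoint: mi, rr_reduction_ldl: 2.46, rr_reduction_sbp: 7.5,  rr_reduction_compound: 9.96,  rr_ratio_compound: 90.04}
  - {ages: 75+,   endpoint: mi, rr_reduction_ldl: 2.34, rr_reduction_sbp: 6,    rr_reduction_compound: 8.34,  rr_ratio_compound: 91.66}

# Intervention definition: nutrient doses and their risk-factor effects.
intervention:
  potassium_delta_mg_day: 1050.28
  phytosterol_delta_mg_day: 1200
  sbp_delta_mmhg: -3.68
  ldl_delta_pct: -4.81
  phytosterol_plateau_g_day: 2.5

# All monetary amounts in 2016 international dollars (int$).
costs:
  drug_cost_chol: {value: 76.86, range: [21.86, 133.86]}
  drug_cost_htn: {value: 174.38, range: [19.38, 329.38]}
  screen_cost_chol: {value: 24.03}
  screen_cost_htn: {value: 7.38, range: [4.68, 10.09]}
  screen_visits_chol: 1
  screen_visits_htn: 3
  inpatient_mi: {value: 9491.00, range: [8395.18, 10586.81]}
  inpatient_stroke: {value: 4994.96, range: [2711.12, 7278.33]}
  mi_inpatient_days: 5.3
  stroke_inpatient_days: 6.4
  chronic_mi_year1_rest: {value: 305.23, range: [293.98, 316.48]}
  chronic_mi_after: 305.23
  chronic_stroke_year1_rest: 611.55
  chronic_stroke_after: 166.59
  milk_price_per_day: 0.5
  discount_rate: 0.03

utilities:
  mi: 0.45
  stroke: 0.56
  chronic: 0.64
  well: 1.0
  death: 0.0

settings:
  horizon: 40
  start_ages: [35, 40, 45, 50, 55, 60, 65, 70, 75]
  # uniform weight per 5-year start-age band (only the 11.1 M total is known)
  age_weights: [0.111111111111111, 0.111111111111111, 0.111111111111111,
                0.111111111111111, 0.111111111111111, 0.111111111111111,
                0.111111111111111, 0.111111111111111, 0.111111111111112]
  initial_chronic_fraction: 0.0383
  initial_well_fraction: 0.9617
  # split of the initially chronic between stroke- and MI-origin (not
  # published; 50/50 default)
  initial_chronic_stroke_share: 0.5
  population_size: 11100000
  # GDP per capita (PPP, 2016) used as the WHO willingness-to-pay threshold;
  # not published with the model inputs, so this is a user-facing choice.
  wtp_per_qaly: 27000
  htn_prevalence: 0.303
  chol_prevalence: 0.477
  annual_health_expenditure: 1040
  # annual escalation of chronic-state case fatality, P_t = P0*(1+rate)^t;
  # the published inputs do not include these rates, so they default to 0
  # (no escalation) and must be set explicitly to activate the mechanism.
  annual_mortality_escalation: {stroke: 0.0, mi: 0.0}
  # within-cycle competing-risk resolution: death_first (non-CVD death, then
  # events among survivors) or events_first
  competing_risk_order: death_first
  random_seed: 12345
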