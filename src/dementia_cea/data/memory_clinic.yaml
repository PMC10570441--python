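# Scenario configuration: initial triage in a memory clinic.
# The modelled cohort is the population referred to the clinic in one year;
# decline_rate plays the role refusal plays in primary care.
schema_version: 1
setting: memory_clinic
cohort_start_age: 77
horizon_end_age: 100
modeled_population: 29226

epidemiology:
  attend_rate: 0.006
  refusal_rate: 0.0                 # refusal happens upstream, at referral
  prev_dem: 0.63
  prev_mci: 0.18
  referral_rate: 0.098
  decline_rate: 0.067

ica_profile:
  name: ICA
  sens_mci: 0.83
  spec_mci: 0.80
  sens_dem: 0.93
  spec_dem: 0.80
  mix_weight: 1.0
  clinician_minutes: 0.0
  nurse_minutes: 10.0
  per_test_fee: 10.00

# Triage battery; nurse time published as a weighted average (16.25 min).
battery:
  - {name: ACE-III, sens_mci: 0.75, spec_mci: 0.89, sens_dem: 0.94, spec_dem: 0.83,
     mix_weight: 0.5, clinician_minutes: 0.0, nurse_minutes: 16.25, per_test_fee: 0.0}
  - {name: MoCA,    sens_mci: 0.80, spec_mci: 0.81, sens_dem: 0.91, spec_dem: 0.81,
     mix_weight: 0.5, clinician_minutes: 0.0, nurse_minutes: 16.25, per_test_fee: 0.0}

transitions:
  rr_death_dementia: 1.82
  rr_death_mci: 1.00
  severity_split_at_test: [0.78, 0.16, 0.06]
  annual_dx_prob: {mild: 0.09, moderate: 0.13, severe: 0.86}
  prog_mild_to_mod: {undiagnosed: 0.259, diagnosed: 0.160}
  prog_mod_to_sev: {undiagnosed: 0.187, diagnosed: 0.116}
  mci_to_mild_undx: 0.049
  mci_to_healthy: 0.160
  healthy_to_mild_undx_by_ageband:
    "<=69": 0.007
    "70-74": 0.011
    "75-79": 0.014
    "80-84": 0.022
    "85+": 0.063
  healthy_to_mci_by_ageband:
    "<=69": 0.012
    "70-74": 0.018
    "75-79": 0.033
    "80-84": 0.032
    "85+": 0.023

economics:
  discount_rate: 0.035
  wtp_threshold: 20000
  state_costs:
    other_healthy: 0.0
    mci: 0.0
    undx_mild: 8973.0
    undx_mod: 31692.0
    undx_sev: 34055.0
    dx_mild: 9699.0
    dx_mod: 32418.0
    dx_sev: 34301.0
    dead: 0.0
  utility_decrements:
    other_healthy: 0.0
    mci: -0.06
    undx_mild: -0.129
    undx_mod: -0.242
    undx_sev: -0.314
    dx_mild: -0.125
    dx_mod: -0.235
    dx_sev: -0.305
  staff_cost_per_minute: {clinician: 3.60, nurse: 1.13}   # band 5-7 nurse mix
  lab_cost: 0.0
  further_assessment_cost: 961.0
  referral_triage_cost: 0.0         # triage is the initial test itself here
  ica_fee_per_test: 10.0
  ica_implementation_fee: 2000.0
  n_trusts: 28.889
  ica_monthly_minimum: 1000.0

pathway:
  assessment_charge: positives_only # only triage-positive patients get the £961 bundle
  healthy_fp_rule: dementia
  event_order: [death, diagnosis, progression, incidence]

life_table:
  anchor_age: 77
  anchor_rate: 0.035
  slope: 0.097

utility_norms:
  value_at_youngest: 0.749
  value_at_oldest: 0.645
  rule: linear
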