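# Base-case configuration: dementia screening in primary care.
# Schema version 1; see docs/methods.md for sources and conventions.
schema_version: 1
setting: primary_care
cohort_start_age: 77
horizon_end_age: 100
modeled_population: 300812          # symptomatic attenders in one year

epidemiology:
  attend_rate: 0.006                # proportion of population attending GP with symptoms
  refusal_rate: 0.0628              # refuse assessment in a GP clinic
  prev_dem: 0.064
  prev_mci: 0.055
  referral_rate: null               # memory-clinic setting only
  decline_rate: null

ica_profile:
  name: ICA
  sens_mci: 0.83
  spec_mci: 0.80
  sens_dem: 0.93
  spec_dem: 0.80
  mix_weight: 1.0
  clinician_minutes: 2.0            # GP time to undertake/interpret
  nurse_minutes: 10.0
  per_test_fee: 10.00

# Standard-care battery; per-test staff time and fees are only published as
# weighted averages (8 GP minutes, 0 nurse minutes, £0.26/test), so every
# profile carries the average resource use and pooling reproduces it.
battery:
  - {name: MMSE,  sens_mci: 0.51, spec_mci: 0.75, sens_dem: 0.59, spec_dem: 0.85,
     mix_weight: 0.26, clinician_minutes: 8.0, nurse_minutes: 0.0, per_test_fee: 0.26}
  - {name: GPCOG, sens_mci: 0.52, spec_mci: 0.82, sens_dem: 0.60, spec_dem: 0.93,
     mix_weight: 0.21, clinician_minutes: 8.0, nurse_minutes: 0.0, per_test_fee: 0.26}
  - {name: 6CIT,  sens_mci: 0.66, spec_mci: 0.70, sens_dem: 0.88, spec_dem: 0.78,
     mix_weight: 0.29, clinician_minutes: 8.0, nurse_minutes: 0.0, per_test_fee: 0.26}
  - {name: AMTS,  sens_mci: 0.66, spec_mci: 0.70, sens_dem: 0.81, spec_dem: 0.84,
     mix_weight: 0.07, clinician_minutes: 8.0, nurse_minutes: 0.0, per_test_fee: 0.26}
  - {name: MoCA,  sens_mci: 0.80, spec_mci: 0.81, sens_dem: 0.91, spec_dem: 0.81,
     mix_weight: 0.06, clinician_minutes: 8.0, nurse_minutes: 0.0, per_test_fee: 0.26}
  - {name: Other, sens_mci: 0.63, spec_mci: 0.76, sens_dem: 0.79, spec_dem: 0.85,
     mix_weight: 0.11, clinician_minutes: 8.0, nurse_minutes: 0.0, per_test_fee: 0.26}

transitions:
  rr_death_dementia: 1.82           # diagnosed or undiagnosed
  rr_death_mci: 1.00
  severity_split_at_test: [0.78, 0.16, 0.06]   # mild / moderate / severe
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
  state_costs:                      # annual, GBP (2019)
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
  staff_cost_per_minute: {clinician: 3.60, nurse: 0.62}
  lab_cost: 8.31
  further_assessment_cost: 961.0    # further tests and scans in a memory clinic
  referral_triage_cost: 18.36       # memory-clinic triage test: 16.25 nurse min x £1.13
  ica_fee_per_test: 10.0
  ica_implementation_fee: 2000.0    # one-off, per trust
  n_trusts: 28.889                  # annuitised fee line = £2,000 x 28.889 = £57,778
  ica_monthly_minimum: 1000.0       # per 100 tests; non-binding at default volumes

pathway:
  assessment_charge: all_referred
  healthy_fp_rule: dementia
  event_order: [death, diagnosis, progression, incidence]

life_table:                         # synthesized Gompertz table, anchored
  anchor_age: 77
  anchor_rate: 0.035
  slope: 0.097

utility_norms:                      # linear in age between published endpoints
  value_at_youngest: 0.749
  value_at_oldest: 0.645
  rule: linear
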