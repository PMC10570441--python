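# Methods

`dementia_cea` implements a health-economic evaluation of replacing the
standard battery of paper-based cognitive tests with a brief computerized
integrated cognitive assessment (ICA), in two UK settings: dementia
screening of symptomatic attenders in primary care, and initial triage of
referred patients in a memory clinic. The comparison is run over a
lifetime horizon from the NHS & Personal Social Services perspective,
with costs and QALYs discounted at 3.5% per annum and a willingness to
pay of £20,000 per QALY.

## Model structure

The model has two stages.

**Decision tree (year 0).** The presenting cohort is cross-classified by
true condition (dementia at prevalence `prev_dem`, MCI at `prev_mci`,
other/healthy) and test result. A person with dementia tests positive
with the test's dementia sensitivity, a person with MCI with the MCI
sensitivity, and a healthy person with `1 − specificity` (the dementia
specificity by default; configurable via `pathway.healthy_fp_rule`).
Test-positive persons are referred for specialist assessment; confirmed
dementia is diagnosed and split over mild/moderate/severe by the severity
mix at testing (0.78/0.16/0.06); false negatives carry the same split but
enter undiagnosed; positive-testing healthy persons are counted as
unnecessary referrals and return to the healthy state. Persons who
refuse testing (primary care, 6.28%) or decline referral (memory clinic,
6.7%) enter the model by true condition, undiagnosed. Standard care is
modelled as a single pooled test profile: the mix-weighted arithmetic
mean of each battery member's accuracy and resource use, the same pooling
the published memory-clinic row uses.

**Markov cohort (annual cycles).** Nine states: other/healthy, MCI,
undiagnosed mild/moderate/severe dementia, diagnosed mild/moderate/severe
dementia, dead (absorbing). Within each cycle, four event layers apply
in a fixed, configurable order — death, then diagnosis of undiagnosed
dementia (annual probabilities 9%/13%/86% by severity), then severity
progression (mild→moderate 25.9% undiagnosed vs 16.0% diagnosed;
moderate→severe 18.7% vs 11.6%), then incidence flows (healthy→mild
undiagnosed and healthy→MCI by age band; MCI→mild undiagnosed 4.9%;
MCI→healthy 16.0%). Each layer is a row-stochastic matrix and the cycle
matrix is their product, so row-stochasticity holds by construction.
Persons diagnosed within a cycle progress at the diagnosed rate that same
cycle. There are no back-transitions out of dementia and no severity
regression. Mortality is the general-population life-table rate times a
relative risk: 1.00 for MCI, 1.82 for all dementia states. An optional
`rr_death_dementia_undx` override lets sensitivity analyses vary the
undiagnosed-dementia RR alone; in the base case it is unset and the
shared RR applies, so diagnosed and undiagnosed dementia die at the same
rate.

The event ordering inside a cycle is a genuine modelling choice (the
published description does not fix one). Death-first is conservative —
no one both dies and is diagnosed in the same year — and the
sequential-event oracle in the test suite pins the chosen semantics.
Alternative orderings can be explored through `pathway.event_order`.
No half-cycle correction is applied; occupancy at the start of each cycle
accrues that cycle's costs and utilities.

## Economics

Per cycle `t` (0-based, so year 0 is undiscounted), each state's
occupancy accrues its annual care cost (undiagnosed mild/mod/severe
£8,973/£31,692/£34,055; diagnosed £9,699/£32,418/£34,301 — the diagnosed
excess is treatment cost; MCI and healthy £0) and its utility, the
age-specific population norm plus a state decrement (MCI −0.06;
diagnosed mild/mod/severe −0.125/−0.235/−0.305; undiagnosed
−0.129/−0.242/−0.314), floored at 0, all discounted by `(1.035)^-t`.
Year-0 testing, triage and assessment costs are undiscounted;
assessments triggered by diagnoses in later cycles cost £961 each and
are discounted at the cycle in which they occur (this makes the
further-assessment cost line scale with cumulative referrals).
Referral and diagnosis counts are reported both as year-0 and as
cumulative-over-horizon figures, since the published counts are not
labelled.

Testing cost per administered test is built from unit costs — staff
minutes times per-minute rates (GP £3.60, practice nurse £0.62, memory
clinic nurse £1.13), laboratory work-up £8.31 in primary care, and the
per-test fee (£10 for the ICA; £0.26 weighted for standard care). The
published "total cost per test" figures (£31.67 / £36.72) are not exactly
reproducible from the published rounded unit costs (they imply unrounded
staff rates); the packaged defaults keep the published unit costs, so the
computed totals (£31.71 / £37.37) differ from the published totals by
under 2%. The ICA's one-off £2,000-per-trust implementation fee is
annuitised; because an annuity at the model's own discount rate
re-discounts to its principal, it is booked at year 0 as
`£2,000 × n_trusts`, with `n_trusts = 28.889` chosen to reproduce the
published £57,778 implementation line. The £1,000-per-100-tests monthly
minimum is carried in the configuration but is not binding at the default
volumes (well over 1,200 tests per trust-year), so the effective
marginal fee is £10 per test.

Incremental results are per-person: `ΔC`, `ΔQ`, ICER `ΔC/ΔQ` (replaced
by "dominant" when `ΔC<0, ΔQ>0` and "dominated" in the mirror case, and
undefined when `ΔQ=0`), `NMB = λΔQ − ΔC` and `NHB = NMB/λ`. Printed
tables round half-up at render time only (so a pooled sensitivity of
92.5% renders as the published 93%); internal arithmetic is unrounded.

## Synthesized inputs

Two inputs are used by the published analysis but not printed in full;
the `synthetic` module generates them, anchored to the values that are
printed.

- **Life table.** Gompertz form `q(a) = min(1, 0.035·e^{0.097(a−77)})`:
  the anchor pins the published 3.5% death rate at age 77 exactly, and
  the default slope 0.097 doubles the hazard roughly every seven years,
  the standard adult-mortality pattern. A user-supplied `age,qx` table
  overrides the generator.
- **Utility norms.** Linear interpolation in age between the published
  endpoints 0.749 (at the cohort start age, 77) and 0.645 (at the
  horizon end, 100).

Because these schedules are synthesized rather than the original national
data, the package reproduces the published comparison *directionally*
(dominance, more referrals, more diagnoses, sign-flip drivers) but not
its exact magnitudes: with packaged defaults the primary-care cohort
accrues ~6.11 QALYs/person versus the published 5.56, and the per-person
saving is ~£89 versus the published £123. Passing tests therefore show
the mechanism and arithmetic are right, not that the original life table
and utility schedule have been recovered.

`perturb_fixture` jitters every numeric input multiplicatively
(`1 + scale·z`, `z~N(0,1)`), renormalizes simplices, re-validates, and is
used for robustness property tests.

## Sensitivity analyses

**One-way DSA.** Each parameter is set to its low and high bound with
everything else at base, the full two-arm pipeline is re-run, and bars
are sorted by NMB swing. No usable confidence intervals are printed for
the packaged inputs, so defaults are ±20% (probabilities capped at 1),
with two substantive exceptions: the undiagnosed mild→moderate
progression is varied down to the diagnosed rate (the "treatment makes no
difference to progression" scenario) and symmetrically up, i.e.
[0.160, 0.358]; and the undiagnosed-dementia mortality RR is varied alone
over [1, 3], the span of published dementia-mortality relative risks,
holding the diagnosed RR at 1.82. Both flip the NMB sign in both
settings with packaged defaults, as does the ICA dementia sensitivity at
±20% in the memory clinic.

**PSA.** Every uncertain table input is drawn each iteration:
probabilities as method-of-moments betas, costs and rates as gammas,
risk ratios as lognormals, and the severity split, battery weights and
the (dementia, MCI, healthy) prevalence simplex as Dirichlets. With no
printed CIs, the standard error is 25% of the mean throughout; Dirichlet
concentrations are set so the anchor component's marginal SD equals 25%
of its mean (the largest component by default; the dementia component
for prevalence, which also keeps `prev_dem + prev_mci ≤ 1` by
construction). A zero SE collapses a parameter to a point mass. Each
draw is re-validated; the run aborts if more than 1% of iterations fail
validation. The default 5,000 iterations satisfy the stability
criterion used in the tests: the split-half difference of the mean
per-arm per-person costs and QALYs is below 1% of their overall means.
Utility-norm and life-table schedules are held at their population values
in the PSA. The CEAC reports, on a £0–£50,000 grid (step £1,000), the
fraction of iterations with positive NMB. With packaged defaults the
probability of cost-effectiveness at £20,000/QALY is ~63% in primary
care and ~44% in the memory clinic (2,000 iterations) — in a wide band
around the published 72%/63%, with the same caveat about synthesized
schedules as above.

## Problem sizes and numerics

The packaged cohorts are 300,812 modelled persons (primary care) and
29,226 (memory clinic), recovered from the published totals divided by
the published per-patient figures; the cohort ages from 77 to 100 (24
annual cycles). Acceptance reporting uses 2,000 PSA iterations;
the test suite validates microsimulation equivalence at 10^5 individuals
within 3 Monte-Carlo standard errors and stability at 5,000 iterations.
Probability sums are validated to 1e-9, transition-matrix rows to 1e-12;
cost breakdowns must sum to totals within £1. Ties and degenerate
inputs: utilities are floored at 0 after decrement; death probabilities
are capped at 1; the dead state has zero cost and utility by invariant.

## Known limitations

- The life table and utility-norm schedule are synthesized (see above);
  absolute costs and QALYs shift accordingly.
- No waiting-time, capacity or societal-perspective (informal care,
  productivity) effects; no dementia-subtype or sex stratification.
- Test accuracy is pooled across severity bands; the yearly diagnosis
  rates 9%/13%/86% are taken as direct inputs.
- Persons who refuse year-0 testing remain eligible for later diagnosis
  at the standard annual rates (they join the undiagnosed pool).
- Year-0 costs are undiscounted by convention; the convention is
  switchable only by editing the accrual, not a config key.
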