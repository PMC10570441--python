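# dementia-cea

A cost-effectiveness model of cognitive-assessment pathways for dementia,
for health economists and analysts evaluating diagnostic technology in
the UK NHS. It compares a brief computerized integrated cognitive
assessment (ICA) against the pooled battery of standard cognitive tests
(MMSE, GPCOG, 6CIT, AMTS, MoCA, …) in two settings: screening
symptomatic attenders in primary care, and triaging referred patients in
a memory clinic.

The model couples a year-0 **diagnostic decision tree** (true condition ×
test result, driven by each test's sensitivity/specificity for dementia
and MCI) to a nine-state annual **Markov cohort model** (other/healthy,
MCI, un/diagnosed mild–moderate–severe dementia, dead). Earlier
diagnosis slows severity progression (mild→moderate 16.0%/yr diagnosed
vs 25.9% undiagnosed), which trades higher testing and referral costs
against savings in dementia care. Outputs are discounted (3.5%/yr)
costs and QALYs per arm and the incremental comparison:

- ICER = ΔC/ΔQ (or a dominance label),
- NMB = λ·ΔQ − ΔC and NHB = NMB/λ at λ = £20,000/QALY,

plus one-way deterministic sensitivity analysis (tornado), probabilistic
sensitivity analysis with beta/gamma/lognormal/Dirichlet parameter
distributions, and cost-effectiveness acceptability curves.
See `docs/methods.md` for the full model description.

## Worked example

```python
from dementia_cea import load_parameters, evaluate

params = load_parameters(setting="primary_care")   # packaged defaults
result = evaluate(params)
inc = result.incremental
print(f"delta cost/person : £{inc.delta_cost:.2f}")
print(f"delta QALYs/person: {inc.delta_qalys:.6f}")
print(f"NMB  : £{inc.nmb:.2f}   ICER: {inc.label}")
```

prints

```
delta cost/person : £-89.15
delta QALYs/person: 0.001447
NMB  : £118.08   ICER: dominant
```

i.e. with the packaged primary-care inputs the ICA arm saves about £89
per presenting person over the cohort's lifetime and gains ~0.0014
QALYs, so it *dominates* the standard battery (cheaper and more
effective), with a net monetary benefit of ~£118 per person. The same
comparison in the memory clinic (`setting="memory_clinic"`) also comes
out dominant.

The same run is available from the shell, along with the sensitivity
analyses:

```bash
dementia-cea run  --setting primary_care --out results/
dementia-cea dsa  --setting primary_care --out results/tornado.csv
dementia-cea psa  --setting primary_care --iterations 5000 --seed 7 --out results/
dementia-cea synth --out results/        # synthesized life table & utility norms
dementia-cea validate --setting memory_clinic
```

`run` writes a summary table (per-arm totals, per-patient figures,
referral/diagnosis counts) and a detailed cost breakdown by line item and
health state, as CSV and JSON, with a run manifest.

Configurations are YAML (`src/dementia_cea/data/*.yaml`); any parameter
can be overridden by pointing `--config` at an edited copy. Unprinted
population inputs — the general-population life table (Gompertz,
anchored at a 3.5% death rate at age 77) and the age schedule of utility
norms (0.749→0.645) — are synthesized by `dementia_cea.synthetic` and can
be replaced by user-supplied tables.

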