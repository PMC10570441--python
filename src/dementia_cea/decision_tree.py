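"""Year-0 testing stage of the pathway model.

The presenting cohort is cross-classified by true condition (dementia,
MCI, other/healthy) and test result; positives are referred for
specialist assessment, true-positive dementia is diagnosed and split
across severities, false negatives remain undiagnosed, and testing and
triage costs accrue.  The output seeds the Markov engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import Epidemiology, ParameterSet, TestProfile, weighted_test_profile
from .states import N_STATES, HealthState

_TOL = 1e-9

CONDITIONS = ("dementia", "mci", "other")
RESULTS = ("positive", "negative")


@dataclass(frozen=True)
class ClassificationTable:
    """Joint probabilities P(condition, test result) over the presenting
    cohort, plus the probability mass that refused testing."""

    joint: dict[tuple[str, str], float]
    refused: float

    def p(self, condition: str, result: str) -> float:
        return self.joint[(condition, result)]

    @property
    def p_positive(self) -> float:
        return sum(v for (c, r), v in self.joint.items() if r == "positive")

    def total(self) -> float:
        return sum(self.joint.values()) + self.refused


@dataclass
class InitialOutcome:
    """Counts (persons), year-0 costs (GBP) and the initial Markov state
    vector produced by the testing stage of one arm."""

    arm: str
    tested: float
    refused: float
    referred: float
    diagnosed_dementia: float
    diagnosed_mci: float
    false_negative_dementia: float
    false_negative_mci: float
    unnecessary_referrals: float
    initial_cost: float
    cost_breakdown: dict[str, float] = field(default_factory=dict)
    initial_state_vector: np.ndarray = field(default_factory=lambda: np.zeros(N_STATES))


def _healthy_fp_prob(test: TestProfile, rule: str) -> float:
    """Probability a healthy person tests positive, under the configured
    referral rule."""
    if rule == "dementia":
        return 1.0 - test.spec_dem
    if rule == "mci":
        return 1.0 - test.spec_mci
    if rule == "either":
        return 1.0 - test.spec_dem * test.spec_mci
    raise ValueError(f"unknown healthy_fp_rule {rule!r}")


def classify(epi: Epidemiology, test: TestProfile,
             healthy_fp_rule: str = "dementia",
             nonparticipation: float | None = None) -> ClassificationTable:
    """Cross-classify the presenting cohort by condition and test result.

    ``nonparticipation`` overrides the epidemiology refusal rate (used in
    the memory-clinic setting where the analogous quantity is the
    referral decline rate).
    """
    if epi.prev_dem + epi.prev_mci > 1 + _TOL:
        raise ValueError("prev_dem + prev_mci must be <= 1")
    r = epi.refusal_rate if nonparticipation is None else nonparticipation
    take = 1.0 - r
    p_other = 1.0 - epi.prev_dem - epi.prev_mci
    fp = _healthy_fp_prob(test, healthy_fp_rule)
    joint = {
        ("dementia", "positive"): take * epi.prev_dem * test.sens_dem,
        ("dementia", "negative"): take * epi.prev_dem * (1.0 - test.sens_dem),
        ("mci", "positive"): take * epi.prev_mci * test.sens_mci,
        ("mci", "negative"): take * epi.prev_mci * (1.0 - test.sens_mci),
        ("other", "positive"): take * p_other * fp,
        ("other", "negative"): take * p_other * (1.0 - fp),
    }
    table = ClassificationTable(joint=joint, refused=r)
    assert abs(table.total() - 1.0) < 1e-9
    return table


def arm_profile(params: ParameterSet, arm: str) -> TestProfile:
    """The single test profile used by an arm: the computerized test, or
    the battery pooled into one weighted profile."""
    if arm == "ica":
        return params.ica_profile
    if arm == "standard_care":
        return weighted_test_profile(params.battery)
    raise ValueError(f"unknown arm {arm!r}; expected 'ica' or 'standard_care'")


def testing_cost_per_person(test: TestProfile, params: ParameterSet) -> float:
    """Staff time, laboratory work-up and per-test fee for one administered
    test."""
    econ = params.economics
    rates = econ.staff_cost_per_minute
    return (test.clinician_minutes * rates.get("clinician", 0.0)
            + test.nurse_minutes * rates.get("nurse", 0.0)
            + econ.lab_cost
            + test.per_test_fee)


def run_initial_stage(params: ParameterSet, arm: str) -> InitialOutcome:
    """Scale the classification table to the modelled population, accrue
    year-0 costs and assemble the initial Markov state vector.

    Persons who refuse (or decline referral) enter the model by true
    condition, undiagnosed.  Test-positive persons are referred;
    true-positive dementia is confirmed at the memory clinic and split
    over severities; false negatives carry the same split, undiagnosed.
    """
    test = arm_profile(params, arm)
    epi = params.epidemiology
    memory_clinic = params.setting == "memory_clinic"
    nonpart = (epi.decline_rate or 0.0) if memory_clinic else epi.refusal_rate
    table = classify(epi, test, params.pathway.healthy_fp_rule, nonparticipation=nonpart)

    n = params.modeled_population
    tested = n * (1.0 - nonpart)
    refused = n * nonpart

    tp_dem = n * table.p("dementia", "positive")
    fn_dem = n * table.p("dementia", "negative")
    tp_mci = n * table.p("mci", "positive")
    fn_mci = n * table.p("mci", "negative")
    fp_other = n * table.p("other", "positive")
    referred = tp_dem + tp_mci + fp_other

    econ = params.economics
    implementation = econ.ica_implementation_fee * econ.n_trusts if arm == "ica" else 0.0
    initial_testing = tested * testing_cost_per_person(test, params)
    referral_triage = referred * econ.referral_triage_cost
    # In primary care only positives are referred onward, so "all referred"
    # and "positives only" coincide; in the memory clinic the whole tested
    # cohort is already present and the switch decides who gets the bundle.
    if memory_clinic and params.pathway.assessment_charge == "all_referred":
        assessed = tested
    else:
        assessed = referred
    further = assessed * econ.further_assessment_cost

    breakdown = {
        "implementation": implementation,
        "initial_testing": initial_testing,
        "referral_triage": referral_triage,
        "further_assessment": further,
    }

    split = np.asarray(params.transitions.severity_split_at_test, dtype=float)
    vec = np.zeros(N_STATES)
    # refused/declined persons enter by true condition, undiagnosed
    vec[HealthState.OTHER_HEALTHY] += nonpart * (1.0 - epi.prev_dem - epi.prev_mci)
    vec[HealthState.MCI] += nonpart * epi.prev_mci
    for s, w in zip((HealthState.UNDX_MILD, HealthState.UNDX_MOD, HealthState.UNDX_SEV), split):
        vec[s] += nonpart * epi.prev_dem * w
    # tested persons by classification cell
    for s, w in zip((HealthState.DX_MILD, HealthState.DX_MOD, HealthState.DX_SEV), split):
        vec[s] += table.p("dementia", "positive") * w
    for s, w in zip((HealthState.UNDX_MILD, HealthState.UNDX_MOD, HealthState.UNDX_SEV), split):
        vec[s] += table.p("dementia", "negative") * w
    vec[HealthState.MCI] += table.p("mci", "positive") + table.p("mci", "negative")
    vec[HealthState.OTHER_HEALTHY] += table.p("other", "positive") + table.p("other", "negative")
    assert abs(vec.sum() - 1.0) < 1e-9

    return InitialOutcome(
        arm=arm,
        tested=tested,
        refused=refused,
        referred=referred,
        diagnosed_dementia=tp_dem,
        diagnosed_mci=tp_mci,
        false_negative_dementia=fn_dem,
        false_negative_mci=fn_mci,
        unnecessary_referrals=fp_other,
        initial_cost=sum(breakdown.values()),
        cost_breakdown=breakdown,
        initial_state_vector=vec,
    )
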