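"""Costing and QALY accrual over a cohort trace, and incremental
cost-effectiveness summaries (ICER, NMB, NHB, dominance).

Conventions: year-0 decision-tree costs are undiscounted; care costs and
QALYs accrue per cycle on start-of-cycle occupancy with discount factor
(1+r)^-t, so cycle 0 is undiscounted; memory-clinic assessments triggered
by later diagnoses are discounted at the cycle in which they occur.
Utilities are the age norm plus a state decrement, floored at 0; the dead
state contributes neither costs nor QALYs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decision_tree import InitialOutcome
from .markov import CohortTrace
from .parameters import EconomicParams, ParameterSet
from .states import HealthState

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


@dataclass
class ArmResult:
    """Discounted totals, per-person figures, cost breakdown and pathway
    counts for one testing arm."""

    arm: str
    total_cost: float
    total_qalys: float
    per_person_cost: float
    per_person_qalys: float
    cost_breakdown: dict[str, float] = field(default_factory=dict)
    counts: dict[str, float] = field(default_factory=dict)


@dataclass
class IncrementalResult:
    """Per-person between-arm deltas (intervention minus comparator) with
    ICER, dominance label, net monetary and net health benefit."""

    delta_cost: float
    delta_qalys: float
    icer: float | None
    label: str
    nmb: float
    nhb: float
    delta_cost_total: float = 0.0
    delta_qalys_total: float = 0.0


def discount_factor(cycle: int, rate: float) -> float:
    """(1+rate)^-cycle; cycle 0 is undiscounted."""
    if cycle < 0:
        raise ValueError(f"cycle must be >= 0, got {cycle}")
    return (1.0 + rate) ** (-cycle)


def utility(state: HealthState, age: int, params: ParameterSet) -> float:
    """State utility at an age: population norm plus decrement, floored at
    0; the dead state has utility 0."""
    if state is HealthState.DEAD:
        return 0.0
    try:
        norm = params.utility_norm_by_age[age]
    except KeyError:
        raise ValueError(f"utility norm missing for age {age}") from None
    return max(0.0, norm + params.economics.utility_decrements[state.key])


def accrue(trace: CohortTrace, initial: InitialOutcome, params: ParameterSet) -> ArmResult:
    """Convert a cohort trace plus the year-0 outcome into a discounted
    ArmResult with the full cost breakdown."""
    econ = params.economics
    n = params.modeled_population
    n_points = trace.occupancy.shape[0]
    df = np.array([discount_factor(t, econ.discount_rate) for t in range(n_points)])

    state_cost_vec = np.array([econ.state_costs[s.key] for s in HealthState])
    util_mat = np.array([[utility(s, int(trace.ages[t]), params) for s in HealthState]
                         for t in range(n_points)])

    care_by_state = {}
    for s in HealthState:
        if s is HealthState.DEAD:
            continue
        care_by_state[f"care_{s.key}"] = float(
            n * np.sum(df * trace.occupancy[:, s] * state_cost_vec[s]))
    total_qalys = float(n * np.sum(df * np.sum(trace.occupancy * util_mat, axis=1)))

    # assessments triggered by diagnoses made in later cycles
    later_dx = n * trace.new_diagnoses                      # persons per cycle
    later_dx_cost = float(np.sum(later_dx * df[1:]) * econ.further_assessment_cost)

    breakdown = dict(initial.cost_breakdown)
    breakdown["further_assessment"] = breakdown.get("further_assessment", 0.0) + later_dx_cost
    breakdown.update(care_by_state)
    total_cost = float(sum(breakdown.values()))

    counts = {
        "tested": initial.tested,
        "refused": initial.refused,
        "referrals_year0": initial.referred,
        "referrals_cumulative": initial.referred + float(later_dx.sum()),
        "diagnoses_year0": initial.diagnosed_dementia,
        "diagnoses_cumulative": initial.diagnosed_dementia + float(later_dx.sum()),
        "diagnosed_mci": initial.diagnosed_mci,
        "unnecessary_referrals": initial.unnecessary_referrals,
        "assessments_cumulative": (breakdown_assessments(initial, econ)
                                   + float(later_dx.sum())),
    }

    return ArmResult(
        arm=initial.arm,
        total_cost=total_cost,
        total_qalys=total_qalys,
        per_person_cost=total_cost / n,
        per_person_qalys=total_qalys / n,
        cost_breakdown=breakdown,
        counts=counts,
    )


def breakdown_assessments(initial: InitialOutcome, econ: EconomicParams) -> float:
    """Number of year-0 memory-clinic assessment bundles implied by the
    further-assessment cost line."""
    if econ.further_assessment_cost == 0:
        return 0.0
    return initial.cost_breakdown.get("further_assessment", 0.0) / econ.further_assessment_cost


def incremental_summary(ica: ArmResult, soc: ArmResult,
                        econ: EconomicParams) -> IncrementalResult:
    """Per-person incremental comparison of the intervention arm against
    standard care: deltas, ICER (or a dominance label), NMB and NHB."""
    dc = ica.per_person_cost - soc.per_person_cost
    dq = ica.per_person_qalys - soc.per_person_qalys
    wtp = econ.wtp_threshold
    nmb = wtp * dq - dc
    nhb = nmb / wtp if wtp > 0 else float("nan")

    if dq == 0:
        icer, label = None, UNDEFINED
    elif dc < 0 and dq > 0:
        icer, label = None, DOMINANT
    elif dc > 0 and dq < 0:
        icer, label = None, DOMINATED
    else:
        icer, label = dc / dq, "icer"

    return IncrementalResult(
        delta_cost=dc,
        delta_qalys=dq,
        icer=icer,
        label=label,
        nmb=nmb,
        nhb=nhb,
        delta_cost_total=ica.total_cost - soc.total_cost,
        delta_qalys_total=ica.total_qalys - soc.total_qalys,
    )
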