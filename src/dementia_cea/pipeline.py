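"""End-to-end evaluation: decision tree -> Markov cohort -> economics,
for one arm or for the full two-arm comparison of a setting."""

from __future__ import annotations

from dataclasses import dataclass

from .decision_tree import run_initial_stage
from .economics import ArmResult, IncrementalResult, accrue, incremental_summary
from .markov import run_cohort
from .parameters import ParameterSet

ARMS = ("ica", "standard_care")


@dataclass
class SettingResult:
    """Both arm results plus the incremental comparison for one setting."""

    setting: str
    ica: ArmResult
    standard_care: ArmResult
    incremental: IncrementalResult


def evaluate_arm(params: ParameterSet, arm: str) -> ArmResult:
    """Run the full pipeline for one testing arm."""
    initial = run_initial_stage(params, arm)
    trace = run_cohort(initial.initial_state_vector, params)
    return accrue(trace, initial, params)


def evaluate(params: ParameterSet) -> SettingResult:
    """Run both arms on a shared parameter set and compare them."""
    ica = evaluate_arm(params, "ica")
    soc = evaluate_arm(params, "standard_care")
    return SettingResult(
        setting=params.setting,
        ica=ica,
        standard_care=soc,
        incremental=incremental_summary(ica, soc, params.economics),
    )
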