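"""Health-state space of the cohort model.

Nine states: cognitively healthy ("other/healthy"), mild cognitive
impairment (MCI), undiagnosed dementia at three severities, diagnosed
dementia at three severities, and dead (absorbing).
"""

from __future__ import annotations

from enum import IntEnum


class HealthState(IntEnum):
    OTHER_HEALTHY = 0
    MCI = 1
    UNDX_MILD = 2
    UNDX_MOD = 3
    UNDX_SEV = 4
    DX_MILD = 5
    DX_MOD = 6
    DX_SEV = 7
    DEAD = 8

    @property
    def key(self) -> str:
        """Lower-case name used in configuration files and reports."""
        return self.name.lower()


N_STATES = len(HealthState)

#: states carrying a dementia mortality relative risk
DEMENTIA_STATES = (
    HealthState.UNDX_MILD,
    HealthState.UNDX_MOD,
    HealthState.UNDX_SEV,
    HealthState.DX_MILD,
    HealthState.DX_MOD,
    HealthState.DX_SEV,
)

UNDIAGNOSED_STATES = (
    HealthState.UNDX_MILD,
    HealthState.UNDX_MOD,
    HealthState.UNDX_SEV,
)

DIAGNOSED_STATES = (
    HealthState.DX_MILD,
    HealthState.DX_MOD,
    HealthState.DX_SEV,
)

ALIVE_STATES = tuple(s for s in HealthState if s is not HealthState.DEAD)

STATE_BY_KEY = {s.key: s for s in HealthState}


def state_from_key(key: str) -> HealthState:
    try:
        return STATE_BY_KEY[key]
    except KeyError:
        raise KeyError(f"unknown health state {key!r}; expected one of {sorted(STATE_BY_KEY)}") from None
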