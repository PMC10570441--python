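"""Annual-cycle Markov cohort engine over the nine health states.

Within a cycle, events are layered in a fixed order (configurable):
death first, then diagnosis of undiagnosed dementia, then severity
progression (newly diagnosed persons progress at the diagnosed rate the
same cycle), then incidence flows between healthy, MCI and mild
undiagnosed dementia.  Each layer is a row-stochastic matrix and the
cycle matrix is their product, so row-stochasticity is preserved by
construction.  There are no back-transitions out of dementia and no
severity regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ParameterSet
from .states import (
    DEMENTIA_STATES,
    N_STATES,
    UNDIAGNOSED_STATES,
    HealthState,
)

_LAYERS = ("death", "diagnosis", "progression", "incidence")


@dataclass
class CohortTrace:
    """State occupancy per annual cycle, with cohort age and the per-cycle
    flow of new dementia diagnoses (fraction of the cohort)."""

    occupancy: np.ndarray        # shape (n_cycles + 1, 9); rows sum to 1
    ages: np.ndarray             # shape (n_cycles + 1,)
    new_diagnoses: np.ndarray    # shape (n_cycles,); flow during cycle t -> t+1

    def __post_init__(self) -> None:
        assert self.occupancy.shape[0] == self.ages.shape[0]

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: cycle, age, state, occupancy."""
        records = [
            {"cycle": t, "age": int(self.ages[t]), "state": s.key,
             "occupancy": float(self.occupancy[t, s])}
            for t in range(self.occupancy.shape[0])
            for s in HealthState
        ]
        return pd.DataFrame.from_records(records)


def age_band(age: int) -> str:
    if age <= 69:
        return "<=69"
    if age <= 74:
        return "70-74"
    if age <= 79:
        return "75-79"
    if age <= 84:
        return "80-84"
    return "85+"


def mortality_rate(age: int, state: HealthState, params: ParameterSet) -> float:
    """Annual death probability for a state at an age: the general-population
    life-table rate, scaled by the MCI or dementia relative risk and capped
    at 1."""
    if state is HealthState.DEAD:
        raise ValueError("mortality is undefined for the dead state")
    try:
        q = params.life_table[age]
    except KeyError:
        raise ValueError(f"age {age} outside the life table") from None
    tr = params.transitions
    if state is HealthState.MCI:
        q *= tr.rr_death_mci
    elif state in UNDIAGNOSED_STATES:
        rr = tr.rr_death_dementia_undx
        q *= tr.rr_death_dementia if rr is None else rr
    elif state in DEMENTIA_STATES:
        q *= tr.rr_death_dementia
    return min(1.0, q)


def _death_layer(age: int, params: ParameterSet) -> np.ndarray:
    m = np.zeros((N_STATES, N_STATES))
    for s in HealthState:
        if s is HealthState.DEAD:
            m[s, s] = 1.0
            continue
        d = mortality_rate(age, s, params)
        m[s, s] = 1.0 - d
        m[s, HealthState.DEAD] = d
    return m


def _diagnosis_layer(params: ParameterSet) -> np.ndarray:
    dx = params.transitions.annual_dx_prob
    m = np.eye(N_STATES)
    pairs = ((HealthState.UNDX_MILD, HealthState.DX_MILD, dx["mild"]),
             (HealthState.UNDX_MOD, HealthState.DX_MOD, dx["moderate"]),
             (HealthState.UNDX_SEV, HealthState.DX_SEV, dx["severe"]))
    for src, dst, p in pairs:
        m[src, src] = 1.0 - p
        m[src, dst] = p
    return m


def _progression_layer(params: ParameterSet) -> np.ndarray:
    tr = params.transitions
    m = np.eye(N_STATES)
    moves = ((HealthState.UNDX_MILD, HealthState.UNDX_MOD, tr.prog_mild_to_mod["undiagnosed"]),
             (HealthState.UNDX_MOD, HealthState.UNDX_SEV, tr.prog_mod_to_sev["undiagnosed"]),
             (HealthState.DX_MILD, HealthState.DX_MOD, tr.prog_mild_to_mod["diagnosed"]),
             (HealthState.DX_MOD, HealthState.DX_SEV, tr.prog_mod_to_sev["diagnosed"]))
    for src, dst, p in moves:
        m[src, src] = 1.0 - p
        m[src, dst] = p
    return m


def _incidence_layer(age: int, params: ParameterSet) -> np.ndarray:
    tr = params.transitions
    band = age_band(age)
    m = np.eye(N_STATES)
    h2d = tr.healthy_to_mild_undx_by_ageband[band]
    h2m = tr.healthy_to_mci_by_ageband[band]
    m[HealthState.OTHER_HEALTHY, HealthState.OTHER_HEALTHY] = 1.0 - h2d - h2m
    m[HealthState.OTHER_HEALTHY, HealthState.UNDX_MILD] = h2d
    m[HealthState.OTHER_HEALTHY, HealthState.MCI] = h2m
    m[HealthState.MCI, HealthState.MCI] = 1.0 - tr.mci_to_mild_undx - tr.mci_to_healthy
    m[HealthState.MCI, HealthState.UNDX_MILD] = tr.mci_to_mild_undx
    m[HealthState.MCI, HealthState.OTHER_HEALTHY] = tr.mci_to_healthy
    return m


def _layer(name: str, age: int, params: ParameterSet) -> np.ndarray:
    if name == "death":
        return _death_layer(age, params)
    if name == "diagnosis":
        return _diagnosis_layer(params)
    if name == "progression":
        return _progression_layer(params)
    if name == "incidence":
        return _incidence_layer(age, params)
    raise ValueError(f"unknown event layer {name!r}")


def build_transition_matrix(age: int, params: ParameterSet) -> np.ndarray:
    """Row-stochastic annual transition matrix at a given cohort age,
    composed from the four event layers in the configured order."""
    m = np.eye(N_STATES)
    for name in params.pathway.event_order:
        m = m @ _layer(name, age, params)
    _check_stochastic(m)
    return m


def _check_stochastic(m: np.ndarray) -> None:
    if (m < -1e-12).any() or (m > 1 + 1e-12).any():
        bad = int(np.argwhere((m < -1e-12) | (m > 1 + 1e-12))[0][0])
        raise ValueError(f"transition entry outside [0, 1] in row {HealthState(bad).key}")
    rows = m.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-12):
        bad = int(np.argmax(np.abs(rows - 1.0)))
        raise ValueError(f"row {HealthState(bad).key} sums to {rows[bad]}, not 1")


def run_cohort(initial: np.ndarray, params: ParameterSet) -> CohortTrace:
    """Propagate an initial occupancy vector annually from the cohort start
    age to the horizon end age, recording occupancy and the per-cycle flow
    of new dementia diagnoses."""
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (N_STATES,):
        raise ValueError(f"initial vector must have length {N_STATES}")
    if abs(initial.sum() - 1.0) > 1e-9:
        raise ValueError("initial occupancy must sum to 1")

    n_cycles = params.n_cycles
    occupancy = np.zeros((n_cycles + 1, N_STATES))
    occupancy[0] = initial
    ages = np.arange(params.cohort_start_age, params.horizon_end_age + 1)
    new_dx = np.zeros(n_cycles)

    for t in range(n_cycles):
        age = int(ages[t])
        v = occupancy[t]
        flow = 0.0
        for name in params.pathway.event_order:
            layer = _layer(name, age, params)
            if name == "diagnosis":
                dx = params.transitions.annual_dx_prob
                flow = (v[HealthState.UNDX_MILD] * dx["mild"]
                        + v[HealthState.UNDX_MOD] * dx["moderate"]
                        + v[HealthState.UNDX_SEV] * dx["severe"])
            v = v @ layer
        occupancy[t + 1] = v
        new_dx[t] = flow

    return CohortTrace(occupancy=occupancy, ages=ages, new_diagnoses=new_dx)
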