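"""Independent Monte-Carlo oracles used by the test suite.

Both simulators work at the individual level with per-event probabilities
taken straight from the parameter objects, deliberately sharing no code
with the cohort engine or the decision tree.
"""

from __future__ import annotations

import numpy as np

from dementia_cea.parameters import Epidemiology, ParameterSet, TestProfile
from dementia_cea.states import HealthState

H = HealthState


def simulate_classification(epi: Epidemiology, test: TestProfile, n: int, seed: int,
                            healthy_fp_rule: str = "dementia",
                            nonparticipation: float | None = None) -> dict:
    """Per-person enumeration of the testing stage: draw refusal, true
    condition and test result independently for n simulated persons and
    return observed cell fractions."""
    rng = np.random.default_rng(seed)
    refusal = epi.refusal_rate if nonparticipation is None else nonparticipation
    refused = rng.random(n) < refusal
    u = rng.random(n)
    condition = np.where(u < epi.prev_dem, 0, np.where(u < epi.prev_dem + epi.prev_mci, 1, 2))
    if healthy_fp_rule == "dementia":
        p_fp = 1 - test.spec_dem
    elif healthy_fp_rule == "mci":
        p_fp = 1 - test.spec_mci
    else:
        p_fp = 1 - test.spec_dem * test.spec_mci
    p_pos = np.choose(condition, [test.sens_dem, test.sens_mci, p_fp])
    positive = rng.random(n) < p_pos

    cells = {}
    active = ~refused
    for ci, cname in enumerate(("dementia", "mci", "other")):
        for pos, rname in ((True, "positive"), (False, "negative")):
            mask = active & (condition == ci) & (positive == pos)
            cells[(cname, rname)] = mask.sum() / n
    cells["refused"] = refused.sum() / n
    return cells


def simulate_cohort(initial: np.ndarray, params: ParameterSet, n: int, cycles: int,
                    seed: int) -> np.ndarray:
    """Individual-level simulation of the Markov cohort: applies the four
    event layers (death, diagnosis, progression, incidence) person by
    person each year.  Returns occupancy fractions, shape (cycles+1, 9)."""
    rng = np.random.default_rng(seed)
    tr = params.transitions
    states = rng.choice(len(H), size=n, p=np.asarray(initial))
    occ = np.zeros((cycles + 1, len(H)))
    occ[0] = np.bincount(states, minlength=len(H)) / n

    rr_undx = tr.rr_death_dementia_undx
    rr_undx = tr.rr_death_dementia if rr_undx is None else rr_undx

    for t in range(cycles):
        age = params.cohort_start_age + t
        q = params.life_table[age]
        death_p = np.zeros(len(H))
        death_p[H.OTHER_HEALTHY] = q
        death_p[H.MCI] = min(1.0, q * tr.rr_death_mci)
        for s in (H.UNDX_MILD, H.UNDX_MOD, H.UNDX_SEV):
            death_p[s] = min(1.0, q * rr_undx)
        for s in (H.DX_MILD, H.DX_MOD, H.DX_SEV):
            death_p[s] = min(1.0, q * tr.rr_death_dementia)

        # death
        dies = rng.random(n) < death_p[states]
        states = np.where(dies & (states != H.DEAD), H.DEAD, states)
        # diagnosis
        for src, dst, p in ((H.UNDX_MILD, H.DX_MILD, tr.annual_dx_prob["mild"]),
                            (H.UNDX_MOD, H.DX_MOD, tr.annual_dx_prob["moderate"]),
                            (H.UNDX_SEV, H.DX_SEV, tr.annual_dx_prob["severe"])):
            move = (states == src) & (rng.random(n) < p)
            states = np.where(move, dst, states)
        # progression: masks are taken on the pre-progression states so one
        # person cannot advance two severities in a single cycle
        draws = rng.random(n)
        prog_moves = ((H.UNDX_MILD, H.UNDX_MOD, tr.prog_mild_to_mod["undiagnosed"]),
                      (H.UNDX_MOD, H.UNDX_SEV, tr.prog_mod_to_sev["undiagnosed"]),
                      (H.DX_MILD, H.DX_MOD, tr.prog_mild_to_mod["diagnosed"]),
                      (H.DX_MOD, H.DX_SEV, tr.prog_mod_to_sev["diagnosed"]))
        masks = [(states == src) & (draws < p) for src, _, p in prog_moves]
        for mask, (_, dst, _) in zip(masks, prog_moves):
            states = np.where(mask, dst, states)
        # incidence
        from dementia_cea.markov import age_band
        band = age_band(age)
        h2d = tr.healthy_to_mild_undx_by_ageband[band]
        h2m = tr.healthy_to_mci_by_ageband[band]
        u = rng.random(n)
        healthy = states == H.OTHER_HEALTHY
        mci = states == H.MCI
        states = np.where(healthy & (u < h2d), H.UNDX_MILD,
                          np.where(healthy & (u < h2d + h2m), H.MCI, states))
        states = np.where(mci & (u < tr.mci_to_mild_undx), H.UNDX_MILD,
                          np.where(mci & (u < tr.mci_to_mild_undx + tr.mci_to_healthy),
                                   H.OTHER_HEALTHY, states))
        occ[t + 1] = np.bincount(states, minlength=len(H)) / n
    return occ
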