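"""Generators for model inputs that are anchored to published values but
not available as full tables: the general-population life table, the age
schedule of population utility norms, and perturbed parameter fixtures
for robustness testing.

The life table follows a Gompertz form ``q(a) = min(1, q0 * exp(b*(a - a0)))``
anchored so that the annual death probability at the anchor age is exact
(default: 3.5% at age 77).  The default slope ``b = 0.097`` doubles the
hazard roughly every seven years, the classic adult-mortality pattern.
A user-supplied two-column table overrides the generator entirely.

Utility norms interpolate linearly between the published endpoints
(0.749 at the youngest modelled age, 0.645 at the oldest).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np


@dataclass(frozen=True)
class LifeTableSpec:
    """Gompertz life-table generator specification.

    Parameters
    ----------
    anchor_age : int
        Age at which the death probability is pinned exactly.
    anchor_rate : float
        Annual death probability at ``anchor_age``.
    slope : float
        Log-hazard slope per year of age; must be nonnegative.
    """

    anchor_age: int = 77
    anchor_rate: float = 0.035
    slope: float = 0.097

    def __post_init__(self) -> None:
        if self.slope < 0:
            raise ValueError(f"life-table slope must be >= 0, got {self.slope}")
        if not 0.0 < self.anchor_rate <= 1.0:
            raise ValueError(f"anchor_rate must be in (0, 1], got {self.anchor_rate}")


@dataclass(frozen=True)
class UtilityNormSpec:
    """Population utility-norm schedule: two endpoint values and an
    interpolation rule (only ``linear`` is implemented)."""

    value_at_youngest: float = 0.749
    value_at_oldest: float = 0.645
    rule: str = "linear"

    def __post_init__(self) -> None:
        if self.rule != "linear":
            raise ValueError(f"unsupported interpolation rule {self.rule!r}")
        if self.value_at_oldest > self.value_at_youngest:
            raise ValueError("utility norms must be nonincreasing with age")


def synth_life_table(spec: LifeTableSpec, ages: Iterable[int]) -> dict[int, float]:
    """Materialize an age -> annual death probability map.

    The anchor constraint holds exactly and the table is nondecreasing
    in age (slope >= 0), capped at 1.
    """
    ages = list(ages)
    if spec.anchor_age not in ages:
        raise ValueError(
            f"anchor age {spec.anchor_age} outside requested range "
            f"[{min(ages)}, {max(ages)}]"
        )
    return {
        a: min(1.0, spec.anchor_rate * math.exp(spec.slope * (a - spec.anchor_age)))
        for a in ages
    }


def synth_utility_norms(spec: UtilityNormSpec, ages: Iterable[int]) -> dict[int, float]:
    """Materialize an age -> utility norm map hitting both endpoints."""
    ages = sorted(ages)
    lo, hi = ages[0], ages[-1]
    if hi == lo:
        return {lo: spec.value_at_youngest}
    span = hi - lo
    return {
        a: spec.value_at_youngest
        + (spec.value_at_oldest - spec.value_at_youngest) * (a - lo) / span
        for a in ages
    }


def perturb_fixture(params, seed: int, scale: float, max_attempts: int = 100):
    """Return a jittered but still-valid copy of a parameter set.

    Every probability, rate, cost and duration is multiplied by
    ``1 + scale * z`` with ``z ~ N(0, 1)``; probabilities are clipped to
    [0, 1] and probability simplices (severity split, battery weights)
    renormalized.  Redraws up to ``max_attempts`` times if validation
    fails.  ``scale = 0`` returns an identical copy.
    """
    from .parameters import ParameterSet  # local import to avoid a cycle

    if scale < 0:
        raise ValueError("scale must be >= 0")
    if not isinstance(params, ParameterSet):
        raise TypeError("params must be a ParameterSet")
    if scale == 0:
        return copy.deepcopy(params)
    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    for _ in range(max_attempts):
        cand = copy.deepcopy(params)
        _jitter_inplace(cand, rng, scale)
        try:
            cand.validate()
        except Exception as err:  # keep drawing
            last_err = err
            continue
        return cand
    raise RuntimeError(
        f"no valid fixture after {max_attempts} attempts (last error: {last_err})"
    )


_PROB_CLIP = ("sens_", "spec_", "rate", "prev_", "prob", "prog_", "mci_to", "split")


def _jitter_scalar(value: float, rng: np.random.Generator, scale: float, clip01: bool) -> float:
    out = value * (1.0 + scale * rng.standard_normal())
    if value >= 0:
        out = max(0.0, out)
    if clip01:
        out = min(1.0, out)
    return out


def _jitter_inplace(params, rng: np.random.Generator, scale: float) -> None:
    epi = params.epidemiology
    for name in ("attend_rate", "refusal_rate", "prev_dem", "prev_mci",
                 "referral_rate", "decline_rate"):
        v = getattr(epi, name)
        if v is not None:
            setattr(epi, name, _jitter_scalar(v, rng, scale, clip01=True))

    for prof in list(params.battery) + [params.ica_profile]:
        for name in ("sens_mci", "spec_mci", "sens_dem", "spec_dem"):
            setattr(prof, name, _jitter_scalar(getattr(prof, name), rng, scale, True))
        for name in ("clinician_minutes", "nurse_minutes", "per_test_fee"):
            setattr(prof, name, _jitter_scalar(getattr(prof, name), rng, scale, False))
    weights = np.array([p.mix_weight for p in params.battery], dtype=float)
    weights = np.clip(weights * (1.0 + scale * rng.standard_normal(weights.size)), 1e-12, None)
    weights /= weights.sum()
    for prof, w in zip(params.battery, weights):
        prof.mix_weight = float(w)

    tr = params.transitions
    tr.rr_death_dementia = _jitter_scalar(tr.rr_death_dementia, rng, scale, False)
    tr.rr_death_mci = _jitter_scalar(tr.rr_death_mci, rng, scale, False)
    split = np.clip(np.array(tr.severity_split_at_test) * (1.0 + scale * rng.standard_normal(3)), 1e-12, None)
    tr.severity_split_at_test = [float(x) for x in split / split.sum()]
    for key in list(tr.annual_dx_prob):
        tr.annual_dx_prob[key] = _jitter_scalar(tr.annual_dx_prob[key], rng, scale, True)
    for d in (tr.prog_mild_to_mod, tr.prog_mod_to_sev):
        for key in list(d):
            d[key] = _jitter_scalar(d[key], rng, scale, True)
    # keep the packaged diagnosed <= undiagnosed ordering intact
    for d in (tr.prog_mild_to_mod, tr.prog_mod_to_sev):
        if d["diagnosed"] > d["undiagnosed"]:
            d["diagnosed"], d["undiagnosed"] = d["undiagnosed"], d["diagnosed"]
    tr.mci_to_mild_undx = _jitter_scalar(tr.mci_to_mild_undx, rng, scale, True)
    tr.mci_to_healthy = _jitter_scalar(tr.mci_to_healthy, rng, scale, True)
    for d in (tr.healthy_to_mild_undx_by_ageband, tr.healthy_to_mci_by_ageband):
        for key in list(d):
            d[key] = _jitter_scalar(d[key], rng, scale, True)

    econ = params.economics
    for key in list(econ.state_costs):
        econ.state_costs[key] = _jitter_scalar(econ.state_costs[key], rng, scale, False)
    econ.state_costs["dead"] = 0.0
    for key in list(econ.utility_decrements):
        mag = _jitter_scalar(abs(econ.utility_decrements[key]), rng, scale, True)
        econ.utility_decrements[key] = -mag if econ.utility_decrements[key] < 0 else 0.0
    for key in list(econ.staff_cost_per_minute):
        econ.staff_cost_per_minute[key] = _jitter_scalar(econ.staff_cost_per_minute[key], rng, scale, False)
    for name in ("lab_cost", "further_assessment_cost", "referral_triage_cost",
                 "ica_fee_per_test", "ica_implementation_fee", "ica_monthly_minimum"):
        setattr(econ, name, _jitter_scalar(getattr(econ, name), rng, scale, False))
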