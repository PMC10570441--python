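"""Sensitivity analyses: one-way deterministic (tornado) re-runs,
probabilistic sensitivity analysis with method-of-moments distribution
fitting (beta, gamma, lognormal, Dirichlet), and cost-effectiveness
acceptability curves.

Where a source reports no uncertainty interval, the standard error
defaults to 25% of the mean.  Dirichlet concentrations are set so the
largest component's marginal SD equals 25% of its mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .parameters import ParameterSet, get_by_path, set_by_path
from .pipeline import evaluate
from .states import HealthState

_Z95 = 1.959963984540054

#: special PSA path: the mixing weights of the standard-care battery
BATTERY_WEIGHTS = "battery.mix_weights"
#: special PSA path: joint (dementia, MCI, healthy) prevalence simplex
PREVALENCE = "epidemiology.prevalence"


# ---------------------------------------------------------------------
# deterministic (one-way) sensitivity analysis
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class DsaSpec:
    """One tornado bar: a dotted parameter path and its low/high bounds."""

    path: str
    low: float
    high: float

    def check(self, base: float) -> None:
        if not (self.low <= base <= self.high):
            raise ValueError(
                f"{self.path}: base value {base} outside [{self.low}, {self.high}]")


def one_way_dsa(params: ParameterSet, specs: Sequence[DsaSpec]) -> pd.DataFrame:
    """Re-run the full two-arm pipeline at each bound of each spec, holding
    everything else at base, and tabulate the per-person NMB swing.

    Rows are sorted by |nmb_high - nmb_low| descending (tornado order).
    """
    base_nmb = evaluate(params).incremental.nmb
    rows = []
    for spec in specs:
        raw = get_by_path(params, spec.path)
        if raw is None and spec.path == "transitions.rr_death_dementia_undx":
            raw = params.transitions.rr_death_dementia  # tied to the shared RR
        base = float(raw)
        spec.check(base)
        nmbs = {}
        for side, value in (("low", spec.low), ("high", spec.high)):
            cand = params.copy()
            set_by_path(cand, spec.path, value)
            cand.validate()
            nmbs[side] = evaluate(cand).incremental.nmb
        rows.append({
            "parameter": spec.path,
            "base": base,
            "low": spec.low,
            "high": spec.high,
            "nmb_base": base_nmb,
            "nmb_low": nmbs["low"],
            "nmb_high": nmbs["high"],
            "range": abs(nmbs["high"] - nmbs["low"]),
        })
    out = pd.DataFrame(rows)
    return out.sort_values("range", ascending=False, ignore_index=True)


def default_dsa_specs(params: ParameterSet, rel: float = 0.20) -> list[DsaSpec]:
    """Default tornado ranges.

    Most drivers get ±20% bounds (probabilities capped at 1) since no
    source in the input tables prints a usable CI.  Two parameters carry
    substantive ranges instead: the undiagnosed mild->moderate
    progression is varied down to the diagnosed rate (treatment making
    no difference to progression) and symmetrically up; the
    undiagnosed-dementia mortality RR is varied alone over [1, 3], the
    span of published dementia-mortality relative risks, with the
    diagnosed RR held at base.
    """
    tr = params.transitions
    specs = [
        DsaSpec("transitions.prog_mild_to_mod.undiagnosed",
                low=tr.prog_mild_to_mod["diagnosed"],
                high=min(1.0, 2 * tr.prog_mild_to_mod["undiagnosed"]
                         - tr.prog_mild_to_mod["diagnosed"])),
        DsaSpec("transitions.rr_death_dementia_undx", low=1.0, high=3.0),
    ]
    paths = [
        "ica_profile.sens_dem", "ica_profile.spec_dem",
        "epidemiology.prev_dem", "epidemiology.prev_mci",
        "transitions.rr_death_dementia",
        "transitions.prog_mild_to_mod.diagnosed",
        "transitions.prog_mod_to_sev.undiagnosed",
        "transitions.prog_mod_to_sev.diagnosed",
        "transitions.annual_dx_prob.mild",
        "transitions.annual_dx_prob.moderate",
        "transitions.mci_to_mild_undx",
        "economics.state_costs.undx_mild",
        "economics.state_costs.dx_mild",
        "economics.state_costs.undx_mod",
        "economics.state_costs.dx_mod",
        "economics.further_assessment_cost",
        "economics.lab_cost",
    ]
    probability_like = {p for p in paths if p.split(".")[0] in ("ica_profile", "epidemiology")
                        or p.startswith("transitions.prog")
                        or p.startswith("transitions.annual")
                        or p.startswith("transitions.mci")}
    for path in paths:
        base = float(get_by_path(params, path))
        if base == 0:
            continue
        low, high = base * (1 - rel), base * (1 + rel)
        if path in probability_like:
            high = min(1.0, high)
        specs.append(DsaSpec(path=path, low=low, high=high))
    return specs


# ---------------------------------------------------------------------
# distribution fitting for PSA
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class PsaSpec:
    """One uncertain parameter: dotted path, distribution family and
    moments.  ``mean`` is the base-case value (a vector for Dirichlet);
    ``se`` defaults to 25% of the mean; a lognormal may instead be given
    a 95% CI.  ``negate`` samples the magnitude and flips the sign
    (utility decrements)."""

    path: str
    family: str
    mean: float | tuple[float, ...]
    se: float | None = None
    ci: tuple[float, float] | None = None
    negate: bool = False
    #: Dirichlet only: component whose marginal SD is matched to 25% of its
    #: mean when setting the concentration (default: the largest component)
    anchor_index: int | None = None


class Sampler:
    """A fitted sampling distribution; draws through a shared Generator so
    a fixed seed gives an identical stream."""

    def __init__(self, spec: PsaSpec):
        self.spec = spec
        self.kind = spec.family
        mean = spec.mean
        if self.kind == "dirichlet":
            m = np.asarray(mean, dtype=float)
            if (m <= 0).any() or abs(m.sum() - 1.0) > 1e-9:
                raise ValueError(f"{spec.path}: dirichlet mean must be a probability vector")
            anchor = int(np.argmax(m)) if spec.anchor_index is None else spec.anchor_index
            mmax = float(m[anchor])
            conc = (1.0 - mmax) / (0.25**2 * mmax) - 1.0
            if conc <= 0:
                raise ValueError(f"{spec.path}: dirichlet concentration infeasible")
            self.alpha = conc * m
            self.mean = m
            return
        mean = float(mean)
        se = spec.se
        if se is None and spec.ci is None:
            se = 0.25 * abs(mean)
        self.mean = mean
        self.se = se
        if se is not None and se == 0:
            self.kind = "degenerate"
            return
        if self.kind == "beta":
            if not 0 < mean < 1:
                raise ValueError(f"{spec.path}: beta mean must be in (0, 1)")
            v = se * se
            if v >= mean * (1 - mean):
                raise ValueError(
                    f"{spec.path}: beta moments infeasible (SE^2 >= mean*(1-mean)); "
                    "use a narrower SE")
            k = mean * (1 - mean) / v - 1.0
            self.a, self.b = mean * k, (1 - mean) * k
        elif self.kind == "gamma":
            if mean <= 0:
                raise ValueError(f"{spec.path}: gamma mean must be positive")
            self.shape = mean * mean / (se * se)
            self.scale = se * se / mean
        elif self.kind == "lognormal":
            if spec.ci is not None:
                lo, hi = spec.ci
                if not 0 < lo < hi:
                    raise ValueError(f"{spec.path}: invalid lognormal CI")
                self.mu = 0.5 * (math.log(lo) + math.log(hi))
                self.sigma = (math.log(hi) - math.log(lo)) / (2 * _Z95)
            else:
                if mean <= 0:
                    raise ValueError(f"{spec.path}: lognormal mean must be positive")
                s2 = math.log(1.0 + (se * se) / (mean * mean))
                self.sigma = math.sqrt(s2)
                self.mu = math.log(mean) - 0.5 * s2
        else:
            raise ValueError(f"unknown distribution family {spec.family!r}")

    def sample(self, rng: np.random.Generator):
        if self.kind == "degenerate":
            value = self.mean
        elif self.kind == "beta":
            value = rng.beta(self.a, self.b)
        elif self.kind == "gamma":
            value = rng.gamma(self.shape, self.scale)
        elif self.kind == "lognormal":
            value = rng.lognormal(self.mu, self.sigma)
        elif self.kind == "dirichlet":
            value = rng.dirichlet(self.alpha)
        else:  # pragma: no cover
            raise AssertionError(self.kind)
        if self.spec.negate:
            value = -value
        return value


def fit_distribution(spec: PsaSpec) -> Sampler:
    """Fit the requested family to the spec's moments (method of moments;
    lognormal optionally from a 95% CI) and return a sampler."""
    return Sampler(spec)


# ---------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------

def default_psa_specs(params: ParameterSet) -> list[PsaSpec]:
    """Every uncertain input in the packaged tables: probabilities as beta,
    costs and rates as gamma, risk ratios as lognormal, the severity split
    and battery weights as Dirichlet, utility decrements as negated betas.
    The SE is 25% of the mean throughout (no printed CIs)."""
    specs: list[PsaSpec] = []

    def beta(path):
        value = float(get_by_path(params, path))
        if 0 < value < 1:
            specs.append(PsaSpec(path, "beta", value))

    def gamma(path):
        value = float(get_by_path(params, path))
        if value > 0:
            specs.append(PsaSpec(path, "gamma", value))

    epi = params.epidemiology
    for name in ("refusal_rate", "decline_rate"):
        if getattr(epi, name):
            beta(f"epidemiology.{name}")
    # joint prevalence simplex keeps prev_dem + prev_mci <= 1 by construction;
    # concentration anchored on the dementia component (the driver of interest)
    specs.append(PsaSpec(PREVALENCE, "dirichlet",
                         (epi.prev_dem, epi.prev_mci, 1.0 - epi.prev_dem - epi.prev_mci),
                         anchor_index=0))
    for name in ("sens_mci", "spec_mci", "sens_dem", "spec_dem"):
        beta(f"ica_profile.{name}")
    for i in range(len(params.battery)):
        for name in ("sens_mci", "spec_mci", "sens_dem", "spec_dem"):
            beta(f"battery[{i}].{name}")
    if len(params.battery) > 1:
        specs.append(PsaSpec(BATTERY_WEIGHTS, "dirichlet",
                             tuple(p.mix_weight for p in params.battery)))

    tr = params.transitions
    specs.append(PsaSpec("transitions.rr_death_dementia", "lognormal", tr.rr_death_dementia))
    specs.append(PsaSpec("transitions.rr_death_mci", "lognormal", tr.rr_death_mci))
    specs.append(PsaSpec("transitions.severity_split_at_test", "dirichlet",
                         tuple(tr.severity_split_at_test)))
    for sev in ("mild", "moderate", "severe"):
        beta(f"transitions.annual_dx_prob.{sev}")
    for which in ("prog_mild_to_mod", "prog_mod_to_sev"):
        for status in ("undiagnosed", "diagnosed"):
            beta(f"transitions.{which}.{status}")
    beta("transitions.mci_to_mild_undx")
    beta("transitions.mci_to_healthy")
    for which in ("healthy_to_mild_undx_by_ageband", "healthy_to_mci_by_ageband"):
        for band in tr.healthy_to_mild_undx_by_ageband:
            beta(f"transitions.{which}.{band}")

    econ = params.economics
    for key, value in econ.state_costs.items():
        if value > 0:
            gamma(f"economics.state_costs.{key}")
    for key, value in econ.utility_decrements.items():
        if value < 0:
            specs.append(PsaSpec(f"economics.utility_decrements.{key}", "beta",
                                 abs(value), negate=True))
    for role in econ.staff_cost_per_minute:
        gamma(f"economics.staff_cost_per_minute.{role}")
    for name in ("lab_cost", "further_assessment_cost", "referral_triage_cost",
                 "ica_fee_per_test", "ica_implementation_fee"):
        gamma(f"economics.{name}")
    return specs


def _apply_draw(cand: ParameterSet, spec: PsaSpec, value) -> None:
    if spec.path == BATTERY_WEIGHTS:
        for prof, w in zip(cand.battery, value):
            prof.mix_weight = float(w)
    elif spec.path == PREVALENCE:
        cand.epidemiology.prev_dem = float(value[0])
        cand.epidemiology.prev_mci = float(value[1])
    elif spec.family == "dirichlet":
        set_by_path(cand, spec.path, [float(v) for v in value])
    else:
        set_by_path(cand, spec.path, float(value))


def run_psa(params: ParameterSet, specs: Sequence[PsaSpec] | None = None,
            n_iter: int = 5000, seed: int = 0) -> pd.DataFrame:
    """Monte-Carlo re-evaluation of the two-arm comparison.

    Each iteration draws every uncertain parameter, re-validates the set
    (Dirichlet draws are simplices by construction), runs both arms and
    records the per-person deltas and NMB.  Reproducible given the seed.
    Aborts if more than 1% of iterations fail validation.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if specs is None:
        specs = default_psa_specs(params)
    samplers = [fit_distribution(s) for s in specs]
    rng = np.random.default_rng(seed)
    wtp = params.economics.wtp_threshold

    rows = []
    failures: list[str] = []
    for it in range(n_iter):
        cand = params.copy()
        for spec, sampler in zip(specs, samplers):
            _apply_draw(cand, spec, sampler.sample(rng))
        try:
            cand.validate()
        except Exception as err:
            failures.append(f"iteration {it}: {err}")
            continue
        res = evaluate(cand)
        rows.append({
            "iteration": it,
            "delta_cost": res.incremental.delta_cost,
            "delta_qalys": res.incremental.delta_qalys,
            "nmb": res.incremental.nmb,
            "cost_ica": res.ica.per_person_cost,
            "cost_soc": res.standard_care.per_person_cost,
            "qalys_ica": res.ica.per_person_qalys,
            "qalys_soc": res.standard_care.per_person_qalys,
        })
    if len(failures) > max(1, 0.01 * n_iter):
        detail = "\n".join(failures[:10])
        raise RuntimeError(
            f"{len(failures)}/{n_iter} PSA iterations failed validation:\n{detail}")
    out = pd.DataFrame(rows)
    out.attrs["seed"] = seed
    out.attrs["wtp_threshold"] = wtp
    out.attrs["n_failures"] = len(failures)
    return out


def ceac(psa_output: pd.DataFrame,
         thresholds: Sequence[float] | None = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve: at each threshold, the
    fraction of PSA iterations with positive net monetary benefit."""
    if len(psa_output) == 0:
        raise ValueError("empty PSA output")
    if thresholds is None:
        thresholds = np.arange(0, 50001, 1000)
    dq = psa_output["delta_qalys"].to_numpy()
    dc = psa_output["delta_cost"].to_numpy()
    rows = [{"threshold": float(lam),
             "probability_cost_effective": float(np.mean(lam * dq - dc > 0))}
            for lam in thresholds]
    return pd.DataFrame(rows)


def probability_cost_effective(psa_output: pd.DataFrame, threshold: float) -> float:
    """Fraction of PSA iterations cost-effective at one threshold."""
    return float(ceac(psa_output, [threshold])["probability_cost_effective"].iloc[0])
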