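"""Typed model parameters, validation, YAML (de)serialization and packaged
defaults for the two care settings, plus pooling of a test battery into a
single weighted test profile.

The configuration schema (version 1) is one YAML document for both
settings; setting-specific keys (referral and decline rates) are nullable.
The life table and the utility-norm schedule may be given either as an
explicit ``table: {age: value}`` map or as a generator spec that is
materialized through :mod:`dementia_cea.synthetic` at load time.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Sequence

import yaml

from .states import HealthState
from .synthetic import LifeTableSpec, UtilityNormSpec, synth_life_table, synth_utility_norms

SCHEMA_VERSION = 1
_TOL = 1e-9

SETTINGS = ("primary_care", "memory_clinic")
AGE_BANDS = ("<=69", "70-74", "75-79", "80-84", "85+")
SEVERITIES = ("mild", "moderate", "severe")


class ConfigurationError(Exception):
    """A required configuration key is missing or the file is malformed."""


class ValidationError(ValueError):
    """A parameter value violates an invariant; the message names the key path."""


def _require(mapping: dict, key: str, path: str) -> Any:
    if key not in mapping:
        raise ConfigurationError(f"missing configuration key: {path}.{key}".lstrip("."))
    return mapping[key]


def _check_prob(value: float, path: str, errors: list[str]) -> None:
    if value is None or not (0.0 <= value <= 1.0):
        errors.append(f"{path}: probability must be in [0, 1], got {value}")


def _check_nonneg(value: float, path: str, errors: list[str]) -> None:
    if value is None or value < 0:
        errors.append(f"{path}: must be nonnegative, got {value}")


@dataclass
class TestProfile:
    """Diagnostic accuracy and administration resource use of one cognitive
    test (or a weighted mixture of tests)."""

    name: str
    sens_mci: float
    spec_mci: float
    sens_dem: float
    spec_dem: float
    mix_weight: float = 1.0
    clinician_minutes: float = 0.0
    nurse_minutes: float = 0.0
    per_test_fee: float = 0.0

    def collect_errors(self, path: str) -> list[str]:
        errors: list[str] = []
        for name in ("sens_mci", "spec_mci", "sens_dem", "spec_dem", "mix_weight"):
            _check_prob(getattr(self, name), f"{path}.{name}", errors)
        for name in ("clinician_minutes", "nurse_minutes", "per_test_fee"):
            _check_nonneg(getattr(self, name), f"{path}.{name}", errors)
        return errors


@dataclass
class Epidemiology:
    """Who presents, who refuses, and the prevalence of dementia and MCI
    in the presenting cohort.  Referral/decline rates apply only to the
    memory-clinic setting and stay ``None`` otherwise."""

    attend_rate: float
    refusal_rate: float
    prev_dem: float
    prev_mci: float
    referral_rate: float | None = None
    decline_rate: float | None = None

    def collect_errors(self, path: str = "epidemiology") -> list[str]:
        errors: list[str] = []
        for name in ("attend_rate", "refusal_rate", "prev_dem", "prev_mci"):
            _check_prob(getattr(self, name), f"{path}.{name}", errors)
        for name in ("referral_rate", "decline_rate"):
            v = getattr(self, name)
            if v is not None:
                _check_prob(v, f"{path}.{name}", errors)
        if (self.prev_dem or 0) + (self.prev_mci or 0) > 1 + _TOL:
            errors.append(f"{path}: prev_dem + prev_mci must be <= 1")
        return errors


@dataclass
class TransitionParams:
    """Annual transition inputs: mortality relative risks, dementia severity
    mix at testing, yearly diagnosis probabilities for undiagnosed dementia,
    severity progression by diagnosis status, and incidence flows by age band."""

    rr_death_dementia: float
    rr_death_mci: float
    #: override for the undiagnosed states; when None the shared dementia RR
    #: applies to diagnosed and undiagnosed alike (the base-case assumption)
    rr_death_dementia_undx: float | None
    severity_split_at_test: list[float]
    annual_dx_prob: dict[str, float]
    prog_mild_to_mod: dict[str, float]
    prog_mod_to_sev: dict[str, float]
    mci_to_mild_undx: float
    mci_to_healthy: float
    healthy_to_mild_undx_by_ageband: dict[str, float]
    healthy_to_mci_by_ageband: dict[str, float]

    def collect_errors(self, path: str = "transitions") -> list[str]:
        errors: list[str] = []
        if self.rr_death_dementia <= 0:
            errors.append(f"{path}.rr_death_dementia: must be positive")
        if self.rr_death_mci <= 0:
            errors.append(f"{path}.rr_death_mci: must be positive")
        if self.rr_death_dementia_undx is not None and self.rr_death_dementia_undx <= 0:
            errors.append(f"{path}.rr_death_dementia_undx: must be positive")
        if len(self.severity_split_at_test) != 3:
            errors.append(f"{path}.severity_split_at_test: need 3 entries")
        else:
            for i, v in enumerate(self.severity_split_at_test):
                _check_prob(v, f"{path}.severity_split_at_test[{i}]", errors)
            if abs(sum(self.severity_split_at_test) - 1.0) > _TOL:
                errors.append(f"{path}.severity_split_at_test: must sum to 1")
        for sev in SEVERITIES:
            if sev not in self.annual_dx_prob:
                errors.append(f"{path}.annual_dx_prob.{sev}: missing")
            else:
                _check_prob(self.annual_dx_prob[sev], f"{path}.annual_dx_prob.{sev}", errors)
        for name, d in (("prog_mild_to_mod", self.prog_mild_to_mod),
                        ("prog_mod_to_sev", self.prog_mod_to_sev)):
            for status in ("undiagnosed", "diagnosed"):
                if status not in d:
                    errors.append(f"{path}.{name}.{status}: missing")
                else:
                    _check_prob(d[status], f"{path}.{name}.{status}", errors)
        _check_prob(self.mci_to_mild_undx, f"{path}.mci_to_mild_undx", errors)
        _check_prob(self.mci_to_healthy, f"{path}.mci_to_healthy", errors)
        if self.mci_to_mild_undx + self.mci_to_healthy > 1 + _TOL:
            errors.append(f"{path}: mci_to_mild_undx + mci_to_healthy must be <= 1")
        for name, d in (("healthy_to_mild_undx_by_ageband", self.healthy_to_mild_undx_by_ageband),
                        ("healthy_to_mci_by_ageband", self.healthy_to_mci_by_ageband)):
            for band in AGE_BANDS:
                if band not in d:
                    errors.append(f"{path}.{name}.{band}: missing")
                else:
                    _check_prob(d[band], f"{path}.{name}.{band}", errors)
        for band in AGE_BANDS:
            a = self.healthy_to_mild_undx_by_ageband.get(band, 0)
            b = self.healthy_to_mci_by_ageband.get(band, 0)
            if a + b > 1 + _TOL:
                errors.append(f"{path}: healthy outflows for band {band} exceed 1")
        return errors


@dataclass
class EconomicParams:
    """Discounting, the willingness-to-pay threshold, annual health-state
    costs, utility decrements, unit costs of testing and triage, and the
    commercial terms of the computerized test."""

    discount_rate: float
    wtp_threshold: float
    state_costs: dict[str, float]
    utility_decrements: dict[str, float]
    staff_cost_per_minute: dict[str, float]
    lab_cost: float
    further_assessment_cost: float
    referral_triage_cost: float
    ica_fee_per_test: float
    ica_implementation_fee: float
    n_trusts: float
    ica_monthly_minimum: float

    def collect_errors(self, path: str = "economics") -> list[str]:
        errors: list[str] = []
        if self.discount_rate < 0:
            errors.append(f"{path}.discount_rate: must be >= 0")
        _check_nonneg(self.wtp_threshold, f"{path}.wtp_threshold", errors)
        for s in HealthState:
            if s.key not in self.state_costs:
                errors.append(f"{path}.state_costs.{s.key}: missing")
            else:
                _check_nonneg(self.state_costs[s.key], f"{path}.state_costs.{s.key}", errors)
        if self.state_costs.get("dead", 0.0) != 0.0:
            errors.append(f"{path}.state_costs.dead: must be 0")
        for s in HealthState:
            if s is HealthState.DEAD:
                continue
            if s.key not in self.utility_decrements:
                errors.append(f"{path}.utility_decrements.{s.key}: missing")
            elif self.utility_decrements[s.key] > 0:
                errors.append(f"{path}.utility_decrements.{s.key}: must be <= 0")
        for role, rate in self.staff_cost_per_minute.items():
            _check_nonneg(rate, f"{path}.staff_cost_per_minute.{role}", errors)
        for name in ("lab_cost", "further_assessment_cost", "referral_triage_cost",
                     "ica_fee_per_test", "ica_implementation_fee", "n_trusts",
                     "ica_monthly_minimum"):
            _check_nonneg(getattr(self, name), f"{path}.{name}", errors)
        return errors


@dataclass
class PathwayOptions:
    """Structural switches left open by the care-pathway description."""

    #: charge the memory-clinic assessment bundle to every referred person
    #: ("all_referred") or only to triage-positive persons ("positives_only")
    assessment_charge: str = "all_referred"
    #: which specificity drives false-positive referral of healthy persons
    healthy_fp_rule: str = "dementia"
    #: within-cycle event ordering in the Markov engine
    event_order: list[str] = field(
        default_factory=lambda: ["death", "diagnosis", "progression", "incidence"]
    )

    def collect_errors(self, path: str = "pathway") -> list[str]:
        errors: list[str] = []
        if self.assessment_charge not in ("all_referred", "positives_only"):
            errors.append(f"{path}.assessment_charge: unknown value {self.assessment_charge!r}")
        if self.healthy_fp_rule not in ("dementia", "mci", "either"):
            errors.append(f"{path}.healthy_fp_rule: unknown value {self.healthy_fp_rule!r}")
        if sorted(self.event_order) != ["death", "diagnosis", "incidence", "progression"]:
            errors.append(f"{path}.event_order: must be a permutation of the four event layers")
        return errors


@dataclass
class ParameterSet:
    """Complete, validated input bundle for one care setting."""

    setting: str
    cohort_start_age: int
    horizon_end_age: int
    modeled_population: float
    battery: list[TestProfile]
    ica_profile: TestProfile
    epidemiology: Epidemiology
    transitions: TransitionParams
    economics: EconomicParams
    life_table: dict[int, float]
    utility_norm_by_age: dict[int, float]
    pathway: PathwayOptions = field(default_factory=PathwayOptions)

    # -- validation ----------------------------------------------------
    def collect_errors(self) -> list[str]:
        errors: list[str] = []
        if self.setting not in SETTINGS:
            errors.append(f"setting: must be one of {SETTINGS}, got {self.setting!r}")
        if self.horizon_end_age < self.cohort_start_age:
            errors.append("horizon_end_age: must be >= cohort_start_age")
        _check_nonneg(self.modeled_population, "modeled_population", errors)
        if not self.battery:
            errors.append("battery: must contain at least one test profile")
        else:
            for i, prof in enumerate(self.battery):
                errors.extend(prof.collect_errors(f"battery[{i}]"))
            total = sum(p.mix_weight for p in self.battery)
            if abs(total - 1.0) > _TOL:
                errors.append(f"battery: mix weights must sum to 1, got {total}")
        errors.extend(self.ica_profile.collect_errors("ica_profile"))
        errors.extend(self.epidemiology.collect_errors())
        errors.extend(self.transitions.collect_errors())
        errors.extend(self.economics.collect_errors())
        errors.extend(self.pathway.collect_errors())
        for age in range(self.cohort_start_age, self.horizon_end_age + 1):
            if age not in self.life_table:
                errors.append(f"life_table[{age}]: missing")
            elif not (0.0 <= self.life_table[age] <= 1.0):
                errors.append(f"life_table[{age}]: probability out of [0, 1]")
            if age not in self.utility_norm_by_age:
                errors.append(f"utility_norm_by_age[{age}]: missing")
        return errors

    def validate(self) -> "ParameterSet":
        errors = self.collect_errors()
        if errors:
            raise ValidationError("invalid parameter set:\n  " + "\n  ".join(errors))
        return self

    @property
    def n_cycles(self) -> int:
        """Number of annual cycles after the initial one."""
        return self.horizon_end_age - self.cohort_start_age

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    # -- (de)serialization ---------------------------------------------
    def to_dict(self) -> dict:
        def profile_dict(p: TestProfile) -> dict:
            return {f.name: getattr(p, f.name) for f in fields(TestProfile)}

        return {
            "schema_version": SCHEMA_VERSION,
            "setting": self.setting,
            "cohort_start_age": self.cohort_start_age,
            "horizon_end_age": self.horizon_end_age,
            "modeled_population": self.modeled_population,
            "epidemiology": {f.name: getattr(self.epidemiology, f.name)
                             for f in fields(Epidemiology)},
            "ica_profile": profile_dict(self.ica_profile),
            "battery": [profile_dict(p) for p in self.battery],
            "transitions": {f.name: copy.deepcopy(getattr(self.transitions, f.name))
                            for f in fields(TransitionParams)},
            "economics": {f.name: copy.deepcopy(getattr(self.economics, f.name))
                          for f in fields(EconomicParams)},
            "pathway": {f.name: copy.deepcopy(getattr(self.pathway, f.name))
                        for f in fields(PathwayOptions)},
            "life_table": {"table": {int(a): float(q) for a, q in sorted(self.life_table.items())}},
            "utility_norms": {"table": {int(a): float(u) for a, u in sorted(self.utility_norm_by_age.items())}},
        }


def weighted_test_profile(profiles: Sequence[TestProfile], name: str = "pooled") -> TestProfile:
    """Pool a battery of test profiles into one profile by mix-weighted
    arithmetic averaging of every accuracy and resource field.

    The result carries weight 1.  Raises on an empty list or when the
    weights do not sum to 1.
    """
    if not profiles:
        raise ValueError("cannot pool an empty list of test profiles")
    total = sum(p.mix_weight for p in profiles)
    if abs(total - 1.0) > _TOL:
        raise ValueError(f"mix weights must sum to 1, got {total}")

    def avg(attr: str) -> float:
        return sum(p.mix_weight * getattr(p, attr) for p in profiles)

    return TestProfile(
        name=name if len(profiles) > 1 else profiles[0].name,
        sens_mci=avg("sens_mci"),
        spec_mci=avg("spec_mci"),
        sens_dem=avg("sens_dem"),
        spec_dem=avg("spec_dem"),
        mix_weight=1.0,
        clinician_minutes=avg("clinician_minutes"),
        nurse_minutes=avg("nurse_minutes"),
        per_test_fee=avg("per_test_fee"),
    )


# ---------------------------------------------------------------------
# loading / saving
# ---------------------------------------------------------------------

def default_config_path(setting: str) -> Path:
    """Path of the packaged YAML configuration for a setting."""
    if setting not in SETTINGS:
        raise ConfigurationError(f"unknown setting {setting!r}; expected one of {SETTINGS}")
    return Path(str(resources.files("dementia_cea").joinpath(f"data/{setting}.yaml")))


def _profile_from_dict(d: dict, path: str) -> TestProfile:
    return TestProfile(
        name=_require(d, "name", path),
        sens_mci=_require(d, "sens_mci", path),
        spec_mci=_require(d, "spec_mci", path),
        sens_dem=_require(d, "sens_dem", path),
        spec_dem=_require(d, "spec_dem", path),
        mix_weight=d.get("mix_weight", 1.0),
        clinician_minutes=d.get("clinician_minutes", 0.0),
        nurse_minutes=d.get("nurse_minutes", 0.0),
        per_test_fee=d.get("per_test_fee", 0.0),
    )


def _materialize_life_table(block: dict, ages: Iterable[int]) -> dict[int, float]:
    if "table" in block and block["table"] is not None:
        return {int(a): float(q) for a, q in block["table"].items()}
    spec = LifeTableSpec(
        anchor_age=block.get("anchor_age", 77),
        anchor_rate=block.get("anchor_rate", 0.035),
        slope=block.get("slope", 0.097),
    )
    return synth_life_table(spec, ages)


def _materialize_utility_norms(block: dict, ages: Iterable[int]) -> dict[int, float]:
    if "table" in block and block["table"] is not None:
        return {int(a): float(u) for a, u in block["table"].items()}
    spec = UtilityNormSpec(
        value_at_youngest=block.get("value_at_youngest", 0.749),
        value_at_oldest=block.get("value_at_oldest", 0.645),
        rule=block.get("rule", "linear"),
    )
    return synth_utility_norms(spec, ages)


def parameters_from_dict(raw: dict) -> ParameterSet:
    """Build and validate a :class:`ParameterSet` from a parsed mapping."""
    if not isinstance(raw, dict):
        raise ConfigurationError("configuration root must be a mapping")
    setting = _require(raw, "setting", "")
    start = int(_require(raw, "cohort_start_age", ""))
    end = int(_require(raw, "horizon_end_age", ""))
    ages = range(start, end + 1)

    epi_raw = _require(raw, "epidemiology", "")
    epi = Epidemiology(
        attend_rate=_require(epi_raw, "attend_rate", "epidemiology"),
        refusal_rate=_require(epi_raw, "refusal_rate", "epidemiology"),
        prev_dem=_require(epi_raw, "prev_dem", "epidemiology"),
        prev_mci=_require(epi_raw, "prev_mci", "epidemiology"),
        referral_rate=epi_raw.get("referral_rate"),
        decline_rate=epi_raw.get("decline_rate"),
    )

    tr_raw = _require(raw, "transitions", "")
    tr = TransitionParams(
        rr_death_dementia=_require(tr_raw, "rr_death_dementia", "transitions"),
        rr_death_mci=_require(tr_raw, "rr_death_mci", "transitions"),
        rr_death_dementia_undx=tr_raw.get("rr_death_dementia_undx"),
        severity_split_at_test=list(_require(tr_raw, "severity_split_at_test", "transitions")),
        annual_dx_prob=dict(_require(tr_raw, "annual_dx_prob", "transitions")),
        prog_mild_to_mod=dict(_require(tr_raw, "prog_mild_to_mod", "transitions")),
        prog_mod_to_sev=dict(_require(tr_raw, "prog_mod_to_sev", "transitions")),
        mci_to_mild_undx=_require(tr_raw, "mci_to_mild_undx", "transitions"),
        mci_to_healthy=_require(tr_raw, "mci_to_healthy", "transitions"),
        healthy_to_mild_undx_by_ageband=dict(_require(tr_raw, "healthy_to_mild_undx_by_ageband", "transitions")),
        healthy_to_mci_by_ageband=dict(_require(tr_raw, "healthy_to_mci_by_ageband", "transitions")),
    )

    ec_raw = _require(raw, "economics", "")
    econ = EconomicParams(
        discount_rate=_require(ec_raw, "discount_rate", "economics"),
        wtp_threshold=_require(ec_raw, "wtp_threshold", "economics"),
        state_costs=dict(_require(ec_raw, "state_costs", "economics")),
        utility_decrements=dict(_require(ec_raw, "utility_decrements", "economics")),
        staff_cost_per_minute=dict(_require(ec_raw, "staff_cost_per_minute", "economics")),
        lab_cost=_require(ec_raw, "lab_cost", "economics"),
        further_assessment_cost=_require(ec_raw, "further_assessment_cost", "economics"),
        referral_triage_cost=ec_raw.get("referral_triage_cost", 0.0),
        ica_fee_per_test=_require(ec_raw, "ica_fee_per_test", "economics"),
        ica_implementation_fee=_require(ec_raw, "ica_implementation_fee", "economics"),
        n_trusts=_require(ec_raw, "n_trusts", "economics"),
        ica_monthly_minimum=_require(ec_raw, "ica_monthly_minimum", "economics"),
    )

    pw_raw = raw.get("pathway") or {}
    pathway = PathwayOptions(
        assessment_charge=pw_raw.get("assessment_charge", "all_referred"),
        healthy_fp_rule=pw_raw.get("healthy_fp_rule", "dementia"),
        event_order=list(pw_raw.get("event_order",
                                    ["death", "diagnosis", "progression", "incidence"])),
    )

    params = ParameterSet(
        setting=setting,
        cohort_start_age=start,
        horizon_end_age=end,
        modeled_population=float(_require(raw, "modeled_population", "")),
        battery=[_profile_from_dict(p, f"battery[{i}]")
                 for i, p in enumerate(_require(raw, "battery", ""))],
        ica_profile=_profile_from_dict(_require(raw, "ica_profile", ""), "ica_profile"),
        epidemiology=epi,
        transitions=tr,
        economics=econ,
        life_table=_materialize_life_table(raw.get("life_table") or {}, ages),
        utility_norm_by_age=_materialize_utility_norms(raw.get("utility_norms") or {}, ages),
        pathway=pathway,
    )
    return params.validate()


def load_parameters(config_path: str | Path | None = None,
                    setting: str | None = None) -> ParameterSet:
    """Load and validate a parameter set.

    With ``config_path=None`` the packaged default configuration for
    ``setting`` is used.  When both are given, the file's own ``setting``
    key must agree with the requested one.
    """
    if config_path is None:
        if setting is None:
            raise ConfigurationError("either a config path or a setting is required")
        config_path = default_config_path(setting)
    config_path = Path(config_path)
    if not config_path.exists():
        raise ConfigurationError(f"configuration file not found: {config_path}")
    try:
        raw = yaml.safe_load(config_path.read_text())
    except yaml.YAMLError as err:
        raise ConfigurationError(f"cannot parse {config_path}: {err}") from err
    params = parameters_from_dict(raw)
    if setting is not None and params.setting != setting:
        raise ConfigurationError(
            f"config file declares setting {params.setting!r}, requested {setting!r}")
    return params


def save_parameters(params: ParameterSet, path: str | Path) -> Path:
    """Serialize a parameter set to YAML with fully materialized tables,
    such that reloading reproduces the object field-by-field."""
    path = Path(path)
    path.write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))
    return path


# ---------------------------------------------------------------------
# dotted-path access (used by the sensitivity analyses)
# ---------------------------------------------------------------------

def get_by_path(params: ParameterSet, path: str) -> Any:
    """Resolve a dotted parameter path, e.g.
    ``transitions.prog_mild_to_mod.undiagnosed`` or ``battery[2].sens_dem``."""
    obj: Any = params
    for part in _split_path(path):
        obj = _step(obj, part, path)
    return obj


def set_by_path(params: ParameterSet, path: str, value: Any) -> None:
    """Assign through a dotted parameter path (in place)."""
    parts = _split_path(path)
    obj: Any = params
    for part in parts[:-1]:
        obj = _step(obj, part, path)
    last = parts[-1]
    if isinstance(obj, dict):
        if last not in obj and not _coerce_key(obj, last):
            raise KeyError(f"cannot resolve {path!r}: no key {last!r}")
        obj[_coerce_key(obj, last) or last] = value
    elif isinstance(obj, list):
        obj[int(last)] = value
    else:
        if not hasattr(obj, last):
            raise KeyError(f"cannot resolve {path!r}: no attribute {last!r}")
        setattr(obj, last, value)


def _split_path(path: str) -> list[str]:
    parts: list[str] = []
    for chunk in path.split("."):
        while "[" in chunk:
            head, rest = chunk.split("[", 1)
            idx, chunk = rest.split("]", 1)
            if head:
                parts.append(head)
            parts.append(idx)
        if chunk:
            parts.append(chunk)
    return parts


def _coerce_key(d: dict, key: str):
    if key in d:
        return key
    try:
        ik = int(key)
    except ValueError:
        return None
    return ik if ik in d else None


def _step(obj: Any, part: str, full: str) -> Any:
    if isinstance(obj, dict):
        key = _coerce_key(obj, part)
        if key is None:
            raise KeyError(f"cannot resolve {full!r}: no key {part!r}")
        return obj[key]
    if isinstance(obj, list):
        return obj[int(part)]
    if hasattr(obj, part):
        return getattr(obj, part)
    raise KeyError(f"cannot resolve {full!r}: no attribute {part!r}")
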