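"""Rendering of results tables (summary and cost breakdown), run
manifests, and CSV/JSON export.  Rendering only rounds; every number
comes straight from an ArmResult/IncrementalResult field.

Rounding is half-up at the published precision (costs to whole pounds,
per-person QALYs to 4 decimal places); internal arithmetic is never
rounded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .pipeline import SettingResult
from .states import HealthState


def round_half_up(value: float, decimals: int = 0) -> float:
    """Decimal round-half-up (so 92.5 -> 93 at 0 decimals), as used for
    printed tables; float banker's rounding would give 92."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def summary_table(result: SettingResult) -> pd.DataFrame:
    """Per-arm totals, per-person figures and pathway counts with the
    incremental column (the published summary-table layout)."""
    ica, soc, inc = result.ica, result.standard_care, result.incremental
    icer_cell = inc.label if inc.icer is None else f"{round_half_up(inc.icer):,.0f}"
    rows = [
        ("total_costs_gbp", round_half_up(ica.total_cost), round_half_up(soc.total_cost),
         round_half_up(inc.delta_cost_total)),
        ("cost_per_patient_gbp", round_half_up(ica.per_person_cost),
         round_half_up(soc.per_person_cost), round_half_up(inc.delta_cost, 2)),
        ("total_qalys", round_half_up(ica.total_qalys, 2), round_half_up(soc.total_qalys, 2),
         round_half_up(inc.delta_qalys_total, 2)),
        ("qalys_per_patient", round_half_up(ica.per_person_qalys, 4),
         round_half_up(soc.per_person_qalys, 4), round_half_up(inc.delta_qalys, 4)),
        ("icer", "", "", icer_cell),
        ("nmb_per_patient_gbp", "", "", round_half_up(inc.nmb, 2)),
        ("nhb_per_patient_qalys", "", "", round_half_up(inc.nhb, 4)),
        ("referrals_year0", round_half_up(ica.counts["referrals_year0"]),
         round_half_up(soc.counts["referrals_year0"]),
         round_half_up(ica.counts["referrals_year0"] - soc.counts["referrals_year0"])),
        ("referrals_cumulative", round_half_up(ica.counts["referrals_cumulative"]),
         round_half_up(soc.counts["referrals_cumulative"]),
         round_half_up(ica.counts["referrals_cumulative"] - soc.counts["referrals_cumulative"])),
        ("diagnoses_year0", round_half_up(ica.counts["diagnoses_year0"]),
         round_half_up(soc.counts["diagnoses_year0"]),
         round_half_up(ica.counts["diagnoses_year0"] - soc.counts["diagnoses_year0"])),
        ("diagnoses_cumulative", round_half_up(ica.counts["diagnoses_cumulative"]),
         round_half_up(soc.counts["diagnoses_cumulative"]),
         round_half_up(ica.counts["diagnoses_cumulative"] - soc.counts["diagnoses_cumulative"])),
        ("unnecessary_referrals", round_half_up(ica.counts["unnecessary_referrals"]),
         round_half_up(soc.counts["unnecessary_referrals"]),
         round_half_up(ica.counts["unnecessary_referrals"] - soc.counts["unnecessary_referrals"])),
    ]
    return pd.DataFrame(rows, columns=["quantity", "ica_tool", "standard_care", "incremental"])


def breakdown_table(result: SettingResult) -> pd.DataFrame:
    """Total-cost breakdown per arm by line item (the published detailed
    cost-breakdown layout)."""
    order = ["implementation", "initial_testing", "referral_triage", "further_assessment"]
    order += [f"care_{s.key}" for s in HealthState if s is not HealthState.DEAD]
    rows = []
    for item in order:
        a = result.ica.cost_breakdown.get(item, 0.0)
        b = result.standard_care.cost_breakdown.get(item, 0.0)
        rows.append((item, round_half_up(a), round_half_up(b), round_half_up(a - b)))
    rows.append(("total", round_half_up(result.ica.total_cost),
                 round_half_up(result.standard_care.total_cost),
                 round_half_up(result.ica.total_cost - result.standard_care.total_cost)))
    return pd.DataFrame(rows, columns=["cost_item", "ica_tool", "standard_care", "incremental"])


def result_to_dict(result: SettingResult) -> dict:
    """JSON-ready nested dict of the full setting result (unrounded)."""
    def arm(a):
        return {"arm": a.arm, "total_cost": a.total_cost, "total_qalys": a.total_qalys,
                "per_person_cost": a.per_person_cost, "per_person_qalys": a.per_person_qalys,
                "cost_breakdown": a.cost_breakdown, "counts": a.counts}

    return {
        "setting": result.setting,
        "ica": arm(result.ica),
        "standard_care": arm(result.standard_care),
        "incremental": dataclasses.asdict(result.incremental),
    }


def config_hash(config: dict) -> str:
    """Stable sha256 of a canonicalized configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    """Provenance of one run: setting, config hash, seeds, version, time
    and every file written."""

    setting: str
    config_hash: str
    seeds: list[int] = field(default_factory=list)
    package_version: str = __version__
    timestamp: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())
    outputs: list[str] = field(default_factory=list)

    def write(self, path: Path) -> Path:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path


def write_base_case(result: SettingResult, config: dict, out_dir: str | Path,
                    seeds: list[int] | None = None) -> RunManifest:
    """Write summary and breakdown tables (CSV), the full result (JSON)
    and a run manifest into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(setting=result.setting, config_hash=config_hash(config),
                           seeds=seeds or [])
    targets = {
        f"summary_{result.setting}.csv": summary_table(result),
        f"cost_breakdown_{result.setting}.csv": breakdown_table(result),
    }
    for name, frame in targets.items():
        frame.to_csv(out / name, index=False)
        manifest.outputs.append(name)
    json_name = f"result_{result.setting}.json"
    (out / json_name).write_text(json.dumps(result_to_dict(result), indent=2) + "\n")
    manifest.outputs.append(json_name)
    manifest.write(out / f"manifest_{result.setting}.json")
    return manifest


def write_frame(frame: pd.DataFrame, path: Path, seed: int | None = None) -> Path:
    """CSV export with the seed recorded in a header comment."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        frame.to_csv(fh, index=False)
    return path


def load_config_dict(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
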