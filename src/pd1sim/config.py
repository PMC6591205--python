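"""Run configuration: schema-checked JSON/YAML loading and file IO.

A run configuration has the top-level blocks ``model`` (mechanistic
parameter overrides), ``pk`` (antibody transport overrides), ``scenario``
(dosing/resection/horizon), ``sampling`` (n, seed, gsd), ``map``
(TMB x K_d grids), ``output_dir`` and ``verbosity``.  Unknown keys are
rejected with the offending key path, and every override must name an
existing parameter.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .engine import Scenario, SimulationResult
from .parameters import ModelParameters, PKParameters, ParameterError
from .pk import build_regimen, merge_regimens
from .trial import PatientRecord

__all__ = ["ConfigError", "RunConfig", "load_config", "load_patient_table",
           "write_patient_table", "result_to_frame", "write_result",
           "config_hash"]


class ConfigError(ValueError):
    """Configuration schema violation; message carries the key path."""


_TOP_KEYS = {"model", "pk", "scenario", "sampling", "map", "output_dir",
             "verbosity", "initial_diameter_mm", "n_reps"}
_SCENARIO_KEYS = {"label", "regimen", "resection_day", "residual_volume",
                  "adjuvant_regimen", "horizon", "metastasis", "met_volume",
                  "output_grid_step"}
_REGIMEN_KEYS = {"amount_mg_per_kg", "interval_days", "start_day", "n_doses"}
_SAMPLING_KEYS = {"n", "seed", "gsd"}
_MAP_KEYS = {"tmb_grid", "kd_grid", "n_reps", "seed"}


def _check_keys(block: dict, allowed: set, path: str) -> None:
    if not isinstance(block, dict):
        raise ConfigError(f"{path}: expected a mapping")
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")


def _build_regimen_block(block: dict | None, path: str):
    if block is None:
        return []
    _check_keys(block, _REGIMEN_KEYS, path)
    missing = _REGIMEN_KEYS - set(block)
    if missing:
        raise ConfigError(f"{path}: missing key(s) {sorted(missing)}")
    return build_regimen(block["amount_mg_per_kg"], block["interval_days"],
                         block["start_day"], block["n_doses"])


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration."""

    params: ModelParameters
    pk: PKParameters
    scenario: Scenario
    sampling: dict | None
    map_block: dict | None
    output_dir: Path
    verbosity: str
    initial_diameter_mm: float
    n_reps: int
    raw: dict


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON or YAML run configuration."""
    path = Path(path)
    text = path.read_text()
    raw = (json.loads(text) if path.suffix == ".json"
           else yaml.safe_load(text))
    if raw is None:
        raw = {}
    _check_keys(raw, _TOP_KEYS, "config")
    try:
        params = ModelParameters().replace(**raw.get("model", {}))
        pk = PKParameters().replace(**raw.get("pk", {}))
    except ParameterError as e:
        raise ConfigError(str(e)) from e

    sc_block = dict(raw.get("scenario", {}))
    _check_keys(sc_block, _SCENARIO_KEYS, "scenario")
    regimen = _build_regimen_block(sc_block.get("regimen"),
                                   "scenario.regimen")
    adjuvant = _build_regimen_block(sc_block.get("adjuvant_regimen"),
                                    "scenario.adjuvant_regimen")
    horizon = float(sc_block.get("horizon", 365.0))
    step = float(sc_block.get("output_grid_step", 1.0))
    try:
        scenario = Scenario(
            label=sc_block.get("label", "scenario"),
            regimen=regimen,
            resection_day=sc_block.get("resection_day"),
            residual_volume=float(sc_block.get("residual_volume", 1.0)),
            adjuvant_regimen=adjuvant,
            horizon=horizon,
            output_grid=np.arange(0.0, horizon + step / 2, step),
            metastasis=bool(sc_block.get("metastasis", False)),
            met_volume=float(sc_block.get("met_volume", 1.0)),
        )
    except ValueError as e:
        raise ConfigError(f"scenario: {e}") from e

    sampling = raw.get("sampling")
    if sampling is not None:
        _check_keys(sampling, _SAMPLING_KEYS, "sampling")
        if "seed" not in sampling:
            raise ConfigError("sampling.seed is mandatory for sampling runs")
    map_block = raw.get("map")
    if map_block is not None:
        _check_keys(map_block, _MAP_KEYS, "map")
        if "seed" not in map_block:
            raise ConfigError("map.seed is mandatory")

    return RunConfig(
        params=params, pk=pk, scenario=scenario, sampling=sampling,
        map_block=map_block,
        output_dir=Path(raw.get("output_dir", "pd1sim_out")),
        verbosity=str(raw.get("verbosity", "info")),
        initial_diameter_mm=float(raw.get("initial_diameter_mm", 30.0)),
        n_reps=int(raw.get("n_reps", 200)),
        raw=raw,
    )


def config_hash(raw: dict) -> str:
    """Stable SHA-256 of the configuration contents (provenance)."""
    return hashlib.sha256(
        json.dumps(raw, sort_keys=True, default=str).encode()).hexdigest()


# ---------------------------------------------------------------------------
# Patient tables
# ---------------------------------------------------------------------------

def load_patient_table(path: str | Path) -> list[PatientRecord]:
    """Read a patient CSV with columns patient_id, tmb, kd_nM."""
    df = pd.read_csv(path)
    required = {"patient_id", "tmb", "kd_nM"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"patient table missing column(s) {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(PatientRecord(patient_id=str(row["patient_id"]),
                                         tmb=int(row["tmb"]),
                                         kd_ag=float(row["kd_nM"])))
        except (ValueError, TypeError) as e:
            raise ConfigError(f"patient table row {i + 2}: {e}") from e
    return records


def write_patient_table(patients: list[PatientRecord],
                        path: str | Path) -> None:
    pd.DataFrame([{"patient_id": p.patient_id, "tmb": p.tmb,
                   "kd_nM": p.kd_ag} for p in patients]).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# Result files
# ---------------------------------------------------------------------------

def result_to_frame(res: SimulationResult) -> pd.DataFrame:
    """Long-format trajectory table: time, variable, value."""
    long = res.states.melt(id_vars="time", var_name="variable",
                           value_name="value")
    extra = pd.DataFrame({
        "time": np.tile(res.times, 3),
        "variable": (["diameter_mm"] * len(res.times)
                     + ["pct_change"] * len(res.times)
                     + ["inhibition"] * len(res.times)),
        "value": np.concatenate([res.diameter, res.pct_change,
                                 res.occupancy["inhibition"].to_numpy()]),
    })
    return pd.concat([long, extra], ignore_index=True)


def write_result(res: SimulationResult, out_dir: str | Path,
                 provenance: dict | None = None) -> dict:
    """Write trajectory CSV + summary JSON; returns the summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result_to_frame(res).to_csv(out / "trajectory.csv", index=False)
    summary = {
        "scenario": res.scenario_label,
        "recist": res.recist,
        "pseudo_progression": res.pseudo_progression,
        "cancer_free": res.cancer_free,
        "final_diameter_mm": res.final_diameter,
        "final_pct_change": res.final_pct_change,
        "events": res.event_log,
        "provenance": provenance or {},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
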