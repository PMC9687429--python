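"""Scenario configuration files, trace/report serialization, manifests.

Scenarios are YAML (or JSON, a YAML subset) mappings mirroring
:class:`~aidsim.simulate.ScenarioConfig`, with ``controller`` and
``modulation`` as nested mappings.  An empty file yields the
full-default scratch protocol.  Unknown keys are rejected by name so a
typo cannot silently fall back to a default.

Run outputs are one CSV per patient, a metrics JSON and a manifest JSON
listing every written file with its SHA-256 checksum, so any published
result directory can be verified and regenerated from its seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .controller import ControllerConfig
from .errors import ConfigError, ManifestError
from .metrics import GlycemicReport, cohort_extremes
from .patient import ParameterModulation
from .simulate import ScenarioConfig, SimulationTrace

_SCENARIO_KEYS = {
    "protocol", "n_patients", "days", "dt_ode", "sample_period",
    "basal_rate", "basal_days", "G0", "seed", "sd_fraction",
    "random_phases", "glucose_ceiling", "controller", "modulation",
}
_CONTROLLER_KEYS = {
    "x_d", "lam", "theta_bound", "sample_period", "eta_schedule",
    "f_hat", "literal_gain_sign", "u_min", "u_max",
}
_MODULATION_KEYS = {"amplitude", "period", "phases"}

MANIFEST_NAME = "manifest.json"


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown {where} key(s): {sorted(unknown)!r}")


def scenario_to_dict(config: ScenarioConfig) -> dict:
    """Plain-python mapping suitable for YAML/JSON round-trips."""
    out = dataclasses.asdict(config)
    ctrl = out["controller"]
    if ctrl["eta_schedule"] is not None:
        ctrl["eta_schedule"] = [list(p) for p in ctrl["eta_schedule"]]
    out["modulation"]["phases"] = list(out["modulation"]["phases"])
    return out


def scenario_from_dict(data: dict | None) -> ScenarioConfig:
    """Build a validated scenario from a (possibly partial) mapping."""
    data = dict(data or {})
    _check_keys(data, _SCENARIO_KEYS, "scenario")
    kwargs = dict(data)
    ctrl_data = kwargs.pop("controller", None)
    mod_data = kwargs.pop("modulation", None)
    try:
        if ctrl_data is not None:
            _check_keys(ctrl_data, _CONTROLLER_KEYS, "controller")
            if ctrl_data.get("eta_schedule") is not None:
                ctrl_data = dict(ctrl_data)
                ctrl_data["eta_schedule"] = tuple(
                    (int(d), float(r)) for d, r in ctrl_data["eta_schedule"])
            kwargs["controller"] = ControllerConfig(**ctrl_data)
        if mod_data is not None:
            _check_keys(mod_data, _MODULATION_KEYS, "modulation")
            mod_data = dict(mod_data)
            if "phases" in mod_data:
                mod_data["phases"] = tuple(float(p) for p in mod_data["phases"])
            kwargs["modulation"] = ParameterModulation(**mod_data)
        return ScenarioConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"invalid scenario configuration: {exc}") from exc


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Load and validate a scenario file (YAML or JSON).

    Missing keys take their defaults (population-mean patient, standard
    meal protocol, consensus controller constants); an empty file is the
    default scratch scenario.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"scenario file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if data is not None and not isinstance(data, dict):
        raise ConfigError(f"scenario file {path} must contain a mapping")
    return scenario_from_dict(data)


def save_scenario(config: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(config), sort_keys=False))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(
    traces: Sequence[SimulationTrace],
    reports: Sequence[GlycemicReport],
    scenario: ScenarioConfig,
    out_dir: str | Path,
) -> dict:
    """Write per-patient trace CSVs, a metrics JSON and a manifest.

    Returns the manifest mapping.  Floats are written at full
    round-trippable precision so re-reading a CSV reproduces the arrays
    bit-exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    for trace in traces:
        name = f"patient_{trace.metadata.get('patient_index', 0):03d}.csv"
        trace.to_frame().to_csv(out_dir / name, index=False)
        files.append(name)

    metrics: dict = {
        "per_patient": [r.to_dict() for r in reports],
    }
    if len(reports) > 0:
        metrics["cohort_mean"] = {
            k: float(np.mean([getattr(r, k) for r in reports]))
            for k in ("tir_pct", "tar_pct", "tar_level2_pct", "tbr_pct",
                      "tbr_level2_pct", "mean_bg", "sd_bg", "cv_pct")}
        metrics["extremes"] = json.loads(
            cohort_extremes(reports).to_json(orient="index"))
    (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))
    files.append("metrics.json")

    manifest = {
        "software": f"aidsim {__version__}",
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "scenario": scenario_to_dict(config=scenario),
        "files": {name: _sha256(out_dir / name) for name in files},
    }
    (out_dir / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2))
    return manifest


def verify_manifest(out_dir: str | Path) -> dict:
    """Check every file listed in a run manifest against its checksum.

    Returns the manifest on success; raises :class:`ManifestError` on a
    missing file or checksum mismatch.
    """
    out_dir = Path(out_dir)
    manifest_path = out_dir / MANIFEST_NAME
    if not manifest_path.exists():
        raise ManifestError(f"no {MANIFEST_NAME} in {out_dir}")
    manifest = json.loads(manifest_path.read_text())
    for name, digest in manifest.get("files", {}).items():
        path = out_dir / name
        if not path.exists():
            raise ManifestError(f"manifest lists missing file {name!r}")
        actual = _sha256(path)
        if actual != digest:
            raise ManifestError(
                f"checksum mismatch for {name!r}: manifest {digest[:12]}..., "
                f"found {actual[:12]}...")
    return manifest


def read_trace_csv(path: str | Path) -> pd.DataFrame:
    """Read a per-patient trace CSV back into a DataFrame.

    Uses the exact float parser so written traces round-trip bit-exactly.
    """
    return pd.read_csv(path, float_precision="round_trip")
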