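"""YAML run-configuration loading and result serialisation helpers."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .cohort import PatientRecord, generate_cohort, generate_patient
from .errors import ConfigError
from .geometry import FemurParams, StemType
from .meshing import default_materials
from .pipeline import SimulationSettings
from .remodeling import ThresholdPair

__all__ = [
    "load_yaml",
    "settings_from_config",
    "patient_from_config",
    "cohort_from_config",
    "dump_json",
]


def load_yaml(path) -> dict:
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except FileNotFoundError as exc:
        raise ConfigError(f"config file not found: {path}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping: {path}")
    return data


def settings_from_config(cfg: dict) -> SimulationSettings:
    sim = cfg.get("simulation", {}) or {}
    thresholds = sim.pop("thresholds", None)
    materials_cfg = cfg.get("materials", {}) or {}
    kwargs = {}
    valid = {f.name for f in dataclasses.fields(SimulationSettings)}
    for key, value in sim.items():
        if key not in valid:
            raise ConfigError(f"unknown simulation option {key!r}")
        kwargs[key] = value
    if thresholds is not None:
        kwargs["thresholds"] = ThresholdPair(
            low=float(thresholds.get("low", 2.0)), high=float(thresholds.get("high", 12.0))
        )
    if materials_cfg:
        kwargs["materials"] = default_materials().with_overrides(materials_cfg)
    try:
        return SimulationSettings(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bad simulation settings: {exc}") from exc


def _geometry_params(cfg: dict) -> FemurParams | None:
    geo = cfg.get("geometry")
    if not geo:
        return None
    valid = {f.name for f in dataclasses.fields(FemurParams)}
    bad = set(geo) - valid
    if bad:
        raise ConfigError(f"unknown geometry parameters: {sorted(bad)}")
    return FemurParams(**geo)


def patient_from_config(cfg: dict) -> PatientRecord:
    pat = cfg.get("patient")
    if pat is None:
        raise ConfigError("config needs a 'patient' section")
    seed = pat.get("seed", cfg.get("seed"))
    stem = pat.get("stem_type", "minima")
    try:
        stem = StemType[stem.upper()] if isinstance(stem, str) else stem
    except KeyError as exc:
        raise ConfigError(f"unknown stem_type {stem!r}") from exc

    if seed is not None:
        record = generate_patient(int(seed), stem)
    else:
        record = generate_patient(0, stem)
    overrides = {}
    for key in ("body_weight", "pauwels_angle", "alignment_angle", "height"):
        if key in pat:
            overrides[key] = float(pat[key])
    if "id" in pat:
        overrides["patient_id"] = str(pat["id"])
    overrides["stem_type"] = stem
    params = _geometry_params(cfg)
    if params is not None:
        overrides["geometry_params"] = params
    try:
        return dataclasses.replace(record, **overrides)
    except ValueError as exc:
        raise ConfigError(f"bad patient record: {exc}") from exc


def cohort_from_config(cfg: dict) -> list[PatientRecord]:
    co = cfg.get("cohort")
    if co is None:
        raise ConfigError("config needs a 'cohort' section")
    if "seed" not in co:
        raise ConfigError("cohort config must set an explicit seed")
    n = int(co.get("n", 15))
    mix = co.get("stem_mix")
    stem_mix = None
    if mix:
        try:
            stem_mix = {StemType[k.upper()]: float(v) for k, v in mix.items()}
        except KeyError as exc:
            raise ConfigError(f"unknown stem type in stem_mix: {exc}") from exc
    return generate_cohort(n, int(co["seed"]), stem_mix)


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if hasattr(o, "value"):
            return o.value
        return super().default(o)


def dump_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, cls=_Encoder)
        fh.write("\n")
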