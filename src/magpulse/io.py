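"""Configuration files, bird-record CSV I/O, reports and run manifests.

External unit conventions: angles in degrees, times in seconds, magnetic
fields in mT.  Circuit configs are flat key-value (YAML) files with a fixed
vocabulary; unknown keys are rejected so typos cannot silently fall back to
defaults.  Every CLI run writes a manifest recording the subcommand, the
config snapshot, the seed and the output paths, which is enough to reproduce
the run exactly.
"""

from __future__ import annotations

import csv
import datetime
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .circuit import CIRCUIT_PROFILES, PulseCircuit
from .errors import ConfigurationError, SchemaError
from .stats import BirdRecord

# keys accepted in a circuit config file, mapped to PulseCircuit fields
CIRCUIT_KEYS = {
    "u0_volts": "u0",
    "capacitance_farads": "capacitance",
    "inductance_henries": "inductance",
    "r_total_ohms": "r_total",
    "r_on_ohms": "r_on",
    "k_mt_per_a": "k_field",
    "shutoff": "shutoff_model",
    "fall_time_s": "fall_time",
    "t_d_s": "t_d",
    "profile": None,
    "mode": None,
}

_SHUTOFF_ALIASES = {"ramp": "linear_ramp", "linear_ramp": "linear_ramp",
                    "flyback": "flyback_exponential",
                    "flyback_exponential": "flyback_exponential"}

BIRD_CSV_HEADER = [
    "bird_id", "year", "age", "group", "departed_first_night",
    "stopover_nights", "night_fraction", "departure_bearing_deg",
    "coast_bearing_deg", "fuel_load",
]


def parse_circuit_config(path: str | Path) -> PulseCircuit:
    """Build a :class:`PulseCircuit` from a flat key-value config file.

    A ``profile`` key (``mp09_2020`` or ``custom_2021``, with optional
    ``mode: treatment|sham``) selects a built-in device; explicit keys
    override the profile's values.  An empty file yields the default
    first-generation treatment circuit.  Unknown keys are an error.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("circuit config must be a flat mapping")
    unknown = set(raw) - set(CIRCUIT_KEYS)
    if unknown:
        raise ConfigurationError(
            f"unknown config keys: {', '.join(sorted(unknown))}")

    profile = raw.get("profile", "mp09_2020")
    mode = raw.get("mode", "treatment")
    if profile not in CIRCUIT_PROFILES:
        raise ConfigurationError(
            f"unknown profile {profile!r}; choose from "
            f"{sorted(CIRCUIT_PROFILES)}")
    base = CIRCUIT_PROFILES[profile](mode)

    overrides = {}
    for key, value in raw.items():
        attr = CIRCUIT_KEYS[key]
        if attr is None:
            continue
        if key == "shutoff":
            if value not in _SHUTOFF_ALIASES:
                raise ConfigurationError(
                    f"shutoff must be one of {sorted(set(_SHUTOFF_ALIASES))}")
            value = _SHUTOFF_ALIASES[value]
        elif not isinstance(value, (int, float)):
            raise ConfigurationError(
                f"config key {key!r} must be numeric, got {value!r}")
        overrides[attr] = value
    if not overrides:
        return base
    params = {f: getattr(base, f) for f in (
        "u0", "capacitance", "inductance", "r_total", "k_field", "t_d",
        "shutoff_model", "fall_time", "r_on")}
    params.update(overrides)
    return PulseCircuit(**params)


# ---------------------------------------------------------------------------
# Bird records CSV
# ---------------------------------------------------------------------------

def _parse_field(name: str, text: str, lineno: int):
    if text == "":
        return None
    try:
        if name == "year":
            return int(text)
        if name == "stopover_nights":
            return int(text)
        if name == "departed_first_night":
            low = text.strip().lower()
            if low in ("true", "1", "yes"):
                return True
            if low in ("false", "0", "no"):
                return False
            raise ValueError(text)
        if name in ("night_fraction", "departure_bearing_deg",
                    "coast_bearing_deg", "fuel_load"):
            return float(text)
        return text
    except ValueError as exc:
        raise SchemaError(
            f"line {lineno}: cannot parse {name}={text!r}") from exc


def read_birds_csv(path: str | Path) -> list[BirdRecord]:
    """Read per-bird records; strict schema with line-numbered errors."""
    path = Path(path)
    records = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != BIRD_CSV_HEADER:
            raise SchemaError(
                f"header must be {','.join(BIRD_CSV_HEADER)}, "
                f"got {','.join(reader.fieldnames or [])}")
        for lineno, row in enumerate(reader, start=2):
            parsed = {name: _parse_field(name, (row[name] or "").strip(), lineno)
                      for name in BIRD_CSV_HEADER}
            try:
                records.append(BirdRecord(
                    bird_id=parsed["bird_id"] or "",
                    year=parsed["year"],
                    age=parsed["age"],
                    group=parsed["group"],
                    departed_first_night=parsed["departed_first_night"],
                    stopover_nights=parsed["stopover_nights"],
                    night_fraction=parsed["night_fraction"],
                    departure_bearing=parsed["departure_bearing_deg"],
                    coast_bearing=parsed["coast_bearing_deg"],
                    fuel_load=parsed["fuel_load"],
                ))
            except SchemaError as exc:
                raise SchemaError(f"line {lineno}: {exc}") from exc
    return records


def write_birds_csv(records: list[BirdRecord], path: str | Path) -> None:
    """Write per-bird records in the canonical column order."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(BIRD_CSV_HEADER)
        for r in records:
            writer.writerow([
                r.bird_id, r.year, r.age, r.group,
                "" if r.departed_first_night is None
                else str(r.departed_first_night).lower(),
                "" if r.stopover_nights is None else r.stopover_nights,
                "" if r.night_fraction is None else f"{r.night_fraction:.9g}",
                "" if r.departure_bearing is None
                else f"{r.departure_bearing:.9g}",
                "" if r.coast_bearing is None else f"{r.coast_bearing:.9g}",
                "" if r.fuel_load is None else f"{r.fuel_load:.9g}",
            ])


# ---------------------------------------------------------------------------
# Reports and manifests
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Record of one CLI run, sufficient to reproduce its outputs."""

    subcommand: str
    seed: int | None = None
    config: dict = field(default_factory=dict)
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    version: str = __version__
    timestamp: str = field(default_factory=lambda: datetime.datetime.now(
        datetime.timezone.utc).isoformat(timespec="seconds"))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and obj != obj:  # NaN
        return None
    return obj


def write_report(results, path: str | Path, fmt: str = "json",
                 manifest: RunManifest | None = None) -> list[Path]:
    """Write a result object as JSON (sorted keys) or CSV, plus a manifest.

    Returns the list of written paths.  JSON reports round-trip through
    :func:`json.loads`; CSV expects a DataFrame-convertible payload.
    """
    path = Path(path)
    written = []
    if fmt == "json":
        path.write_text(
            json.dumps(_jsonable(results), indent=2, sort_keys=True) + "\n")
    elif fmt == "csv":
        df = results if isinstance(results, pd.DataFrame) else pd.DataFrame(results)
        df.to_csv(path, index=isinstance(df.index, pd.MultiIndex)
                  or df.index.name is not None or df.index.dtype == object)
    else:
        raise ConfigurationError(f"unknown report format {fmt!r}")
    written.append(path)
    if manifest is not None:
        manifest.outputs = [str(p) for p in written]
        mpath = path.with_suffix(path.suffix + ".manifest.json")
        manifest.write(mpath)
        written.append(mpath)
    return written
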