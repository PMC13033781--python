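"""File I/O: long-format time-series CSV, biomass CSV, scenario configs, reports.

All files are UTF-8 text with '.' decimals. Time-series CSV has the header
``vial_id,run,replicate,day,variable,value,unit``; lines starting with '#'
are metadata comments. Variables outside the controlled vocabulary are
rejected with the offending line numbers. Scenario configs are YAML with a
``schema_version`` field; unknown keys are errors, not warnings.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .simulate import RunScenario
from .species import VOCABULARY
from .timeseries import COLUMNS, TimeSeries
from .vial_gas import GasState, VialConfig

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_biomass_table",
    "read_scenario",
    "write_scenario",
    "scenario_to_dict",
    "scenario_from_dict",
    "write_report",
    "read_report",
    "scenario_hash",
    "TimeSeriesFormatError",
]

SCHEMA_VERSION = 1


class TimeSeriesFormatError(ValueError):
    """Malformed time-series file; message lists offending line numbers."""


def read_timeseries(path: str | Path) -> TimeSeries:
    """Read and validate a long-format time-series CSV."""
    path = Path(path)
    rows: list[dict] = []
    errors: list[str] = []
    with path.open(newline="", encoding="utf-8") as fh:
        lineno = 0
        header: list[str] | None = None
        for raw in csv.reader(fh):
            lineno += 1
            if not raw or raw[0].startswith("#"):
                continue
            if header is None:
                header = [c.strip() for c in raw]
                if header != list(COLUMNS):
                    raise TimeSeriesFormatError(
                        f"{path}: line {lineno}: expected header {','.join(COLUMNS)}"
                    )
                continue
            if len(raw) != len(COLUMNS):
                errors.append(f"line {lineno}: expected {len(COLUMNS)} fields, got {len(raw)}")
                continue
            rec = dict(zip(COLUMNS, raw))
            if rec["variable"] not in VOCABULARY:
                errors.append(f"line {lineno}: unknown variable {rec['variable']!r}")
                continue
            try:
                rec["replicate"] = int(rec["replicate"])
                rec["day"] = float(rec["day"])
                rec["value"] = float(rec["value"])
            except ValueError:
                errors.append(f"line {lineno}: non-numeric replicate/day/value")
                continue
            rows.append(rec)
    if header is None:
        raise TimeSeriesFormatError(f"{path}: empty file")
    if errors:
        raise TimeSeriesFormatError(f"{path}: " + "; ".join(errors))
    if not rows:
        raise TimeSeriesFormatError(f"{path}: no data rows")
    return TimeSeries(pd.DataFrame(rows, columns=list(COLUMNS)))


def write_timeseries(
    ts: TimeSeries, path: str | Path, metadata: dict[str, Any] | None = None
) -> None:
    """Write a time series as CSV, with metadata as leading '#' comments."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        ts.data.to_csv(fh, index=False, float_format="%.12g")


def read_biomass_table(path: str | Path) -> pd.DataFrame:
    """Read an end-point biomass measurement CSV.

    Expected columns: vial_id, run, replicate, day, total_N_ug, atom15_fraction.
    """
    expected = ["vial_id", "run", "replicate", "day", "total_N_ug", "atom15_fraction"]
    df = pd.read_csv(path, comment="#")
    missing = set(expected) - set(df.columns)
    if missing:
        raise TimeSeriesFormatError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Scenario configs

_SCENARIO_SIMPLE_FIELDS = (
    "name",
    "initial_biomass_g",
    "biomass_n_fraction",
    "initial_atom15",
    "growth_rate",
    "light_duty_cycle",
    "diel_switching",
    "rate_law_mode",
    "k_red",
    "vmax_red",
    "k_n2o",
    "km_n2",
    "ks_c2h2",
    "vmax_fix",
    "vmax_ara",
    "o2_yield",
    "o2_inhibition_k",
    "sink_fraction",
    "atom15_bias",
    "replicates",
    "seed",
)

_VIAL_FIELDS = ("total_volume_ml", "liquid_volume_ml", "temperature_k", "pressure_atm")


def scenario_to_dict(scenario: RunScenario) -> dict:
    d: dict[str, Any] = {"schema_version": SCHEMA_VERSION}
    for f in _SCENARIO_SIMPLE_FIELDS:
        d[f] = getattr(scenario, f)
    d["vial"] = {f: getattr(scenario.vial, f) for f in _VIAL_FIELDS}
    d["initial_gas"] = dict(scenario.initial_gas.fractions)
    d["noise_sd"] = dict(scenario.noise_sd)
    d["sampling_days"] = list(scenario.sampling_days)
    return d


def scenario_from_dict(d: dict) -> RunScenario:
    d = dict(d)
    version = d.pop("schema_version", None)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version: {version!r} (expected {SCHEMA_VERSION})")
    allowed = set(_SCENARIO_SIMPLE_FIELDS) | {"vial", "initial_gas", "noise_sd", "sampling_days"}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    vial_cfg = d.pop("vial", {})
    bad_vial = set(vial_cfg) - set(_VIAL_FIELDS)
    if bad_vial:
        raise ValueError(f"unknown vial keys: {sorted(bad_vial)}")
    kwargs: dict[str, Any] = {k: v for k, v in d.items() if k in _SCENARIO_SIMPLE_FIELDS}
    kwargs["vial"] = VialConfig(**vial_cfg)
    kwargs["initial_gas"] = GasState(d.get("initial_gas", {}))
    if "noise_sd" in d:
        kwargs["noise_sd"] = dict(d["noise_sd"])
    if "sampling_days" in d:
        kwargs["sampling_days"] = tuple(float(x) for x in d["sampling_days"])
    return RunScenario(**kwargs)


def read_scenario(path: str | Path) -> RunScenario:
    with Path(path).open(encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: scenario file must be a mapping")
    return scenario_from_dict(data)


def write_scenario(scenario: RunScenario, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(scenario_to_dict(scenario), fh, sort_keys=False)


def scenario_hash(scenario: RunScenario) -> str:
    """Stable short hash of a scenario's full parameterization."""
    payload = json.dumps(scenario_to_dict(scenario), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Reports


def write_report(report: dict, path: str | Path) -> None:
    """Serialize a run report (nested dict; every number carries a unit string)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    if isinstance(obj, (tuple, set)):
        return list(obj)
    return str(obj)


def read_report(path: str | Path) -> dict:
    with Path(path).open(encoding="utf-8") as fh:
        return json.load(fh)
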