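"""CSV formats and the thresholds/phenology configuration.

Sensor CSV: columns ``timestamp,sensor_id,temp_c,rh_pct`` (optionally
``vpd_kpa``), ISO-8601 naive local timestamps, empty field = missing,
UTF-8, '.' decimal separator.  Daily external weather CSV: columns
``date,tmean_c,tmin_c,tmax_c,rhmean_pct,precip_lm2,wind_kmh,rad_wm2``.

The thresholds configuration is a YAML file mirroring the suitability
table cell-for-cell (18 stage x period x variable cells) together with
the phenology calendar; the packaged default carries the tomato
values.
"""

from __future__ import annotations

import datetime as _dt
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .suitability import (PhenologyCalendar, Stage, ThresholdEntry,
                          ThresholdTable)

__all__ = ["read_sensor_csv", "write_sensor_csv", "read_weather_csv",
           "write_weather_csv", "read_thresholds_config",
           "default_thresholds_path", "load_default_config"]

SENSOR_COLUMNS = ["timestamp", "sensor_id", "temp_c", "rh_pct"]
WEATHER_COLUMNS = ["date", "tmean_c", "tmin_c", "tmax_c", "rhmean_pct",
                   "precip_lm2", "wind_kmh", "rad_wm2"]

_RH_RANGE = (0.0, 100.0)
_T_RANGE = (-40.0, 60.0)  # plausibility guard, not a physical bound


class SensorCsvError(ValueError):
    """Malformed or invalid sensor CSV content."""


def read_sensor_csv(path) -> dict[str, pd.DataFrame]:
    """Read and validate a sensor CSV; returns one time-sorted frame
    per sensor id.

    Rejects: missing/garbled header, unparseable timestamps or
    numbers (with the offending line number), duplicate
    (sensor, timestamp) pairs, out-of-range T or RH, empty files.
    """
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SensorCsvError(f"{path}: empty file") from None
    if list(raw.columns)[:4] != SENSOR_COLUMNS:
        raise SensorCsvError(
            f"{path}: header must start with {','.join(SENSOR_COLUMNS)}, "
            f"got {','.join(raw.columns)}")
    if len(raw) == 0:
        raise SensorCsvError(f"{path}: no data rows")

    ts = pd.to_datetime(raw["timestamp"], errors="coerce",
                        format="ISO8601")
    bad = np.nonzero(ts.isna().to_numpy())[0]
    if bad.size:
        raise SensorCsvError(
            f"{path}: unparseable timestamp on line {bad[0] + 2}")

    def _num(col, lo, hi):
        s = raw[col].replace("", np.nan)
        vals = pd.to_numeric(s, errors="coerce")
        bad = np.nonzero((s.notna() & vals.isna()).to_numpy())[0]
        if bad.size:
            raise SensorCsvError(
                f"{path}: unparseable {col} on line {bad[0] + 2}")
        out_of_range = np.nonzero(
            (vals.notna() & ((vals < lo) | (vals > hi))).to_numpy())[0]
        if out_of_range.size:
            i = out_of_range[0]
            raise SensorCsvError(
                f"{path}: {col}={vals.iloc[i]} out of [{lo}, {hi}] on "
                f"line {i + 2} (sensor {raw['sensor_id'].iloc[i]}, "
                f"{raw['timestamp'].iloc[i]})")
        return vals.astype(float)

    frame = pd.DataFrame({
        "timestamp": ts,
        "sensor_id": raw["sensor_id"],
        "temp_c": _num("temp_c", *_T_RANGE),
        "rh_pct": _num("rh_pct", *_RH_RANGE),
    })
    if "vpd_kpa" in raw.columns:
        frame["vpd_kpa"] = pd.to_numeric(
            raw["vpd_kpa"].replace("", np.nan), errors="coerce")

    if frame.duplicated(["sensor_id", "timestamp"]).any():
        dup = frame[frame.duplicated(["sensor_id", "timestamp"])].iloc[0]
        raise SensorCsvError(
            f"{path}: duplicate record for sensor {dup['sensor_id']} at "
            f"{dup['timestamp']}")

    return {sensor: grp.sort_values("timestamp").reset_index(drop=True)
            for sensor, grp in frame.groupby("sensor_id")}


def write_sensor_csv(frames, path, float_format: str = "%.3f") -> None:
    """Write sensor frames (dict of per-sensor frames, or one combined
    frame) in the canonical CSV layout; NaN becomes an empty field."""
    if isinstance(frames, dict):
        combined = pd.concat(frames.values(), ignore_index=True)
    else:
        combined = frames.copy()
    combined = combined.copy()
    combined["timestamp"] = pd.to_datetime(
        combined["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    cols = SENSOR_COLUMNS + (["vpd_kpa"] if "vpd_kpa" in combined else [])
    combined[cols].to_csv(path, index=False, float_format=float_format,
                          na_rep="")


def read_weather_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise SensorCsvError(f"{path}: weather CSV missing columns "
                             f"{missing}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def write_weather_csv(frame: pd.DataFrame, path) -> None:
    frame[WEATHER_COLUMNS].to_csv(path, index=False, float_format="%.2f")


# ---------------------------------------------------------------------------
# thresholds / phenology configuration

_EXPECTED_PERIODS = ("day", "night")
_EXPECTED_VARS = ("T", "RH", "VPD")


def default_thresholds_path():
    """Path to the packaged tomato thresholds + calendar YAML."""
    return resources.files("microclim.data") / "thresholds.yaml"


def read_thresholds_config(path=None
                           ) -> tuple[ThresholdTable, PhenologyCalendar]:
    """Parse and validate a thresholds/phenology YAML.

    Every (stage, period, variable) combination declared by the
    calendar must be present with consistent bounds; offending keys are
    listed in the error.
    """
    if path is None:
        path = default_thresholds_path()
    with open(path) if not hasattr(path, "read_text") else path.open() as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "phenology" not in doc \
            or "thresholds" not in doc:
        raise ValueError(f"{path}: config needs 'phenology' and "
                         "'thresholds' sections")

    ph = doc["phenology"]
    date = ph["transplant_date"]
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    stages = tuple(
        Stage(name=s["name"], start_dat=int(s["start_dat"]),
              end_dat=int(s["end_dat"]),
              duration_days=int(s["duration_days"]))
        for s in ph["stages"])
    calendar = PhenologyCalendar(transplant_date=date, stages=stages)

    entries = {}
    problems = []
    for stage in (s.name for s in stages):
        block = doc["thresholds"].get(stage, {})
        for period in _EXPECTED_PERIODS:
            pblock = block.get(period, {})
            for var in _EXPECTED_VARS:
                key = (stage, period, var)
                cell = pblock.get(var)
                if cell is None:
                    problems.append(f"missing {'/'.join(key)}")
                    continue
                try:
                    lo, hi = cell["optimal"]
                    entries[key] = ThresholdEntry(
                        optimal_lo=float(lo), optimal_hi=float(hi),
                        critical_below=float(cell["critical_below"]),
                        critical_above=float(cell["critical_above"]))
                except (KeyError, ValueError, TypeError) as exc:
                    problems.append(f"invalid {'/'.join(key)}: {exc}")
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))
    return ThresholdTable(entries=entries), calendar


def load_default_config() -> tuple[ThresholdTable, PhenologyCalendar]:
    """Packaged tomato defaults."""
    return read_thresholds_config(default_thresholds_path())
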