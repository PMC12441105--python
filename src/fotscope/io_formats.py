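"""Readers and writers for external artifacts.

Timestamped frame sequences, the weather logger CSV, detection tables (CSV
with a JSON metadata sidecar), and observed flower-opening-time tables.
Timestamps are naive local time throughout (the logger and camera both
record local time); time-of-day is carried internally as decimal hours so
that errors come out directly in hours.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from datetime import datetime, date
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .filterchain import DETECTION_COLUMNS

__all__ = [
    "FormatError",
    "FrameRef",
    "WEATHER_COLUMNS",
    "hhmm_to_hours",
    "hours_to_hhmm",
    "load_frame_sequence",
    "load_weather_csv",
    "write_weather_csv",
    "write_detections",
    "load_detections",
    "load_observed_fot",
    "write_observed_fot",
]

log = logging.getLogger(__name__)

#: Weather table schema: naive local timestamps at a nominal 10-min cadence.
WEATHER_COLUMNS = ["timestamp", "temp_c", "rh_pct", "radiation"]

OBSERVED_FOT_COLUMNS = ["date", "side", "hhmm"]


class FormatError(ValueError):
    """Malformed or inconsistent external file."""


@dataclass(frozen=True)
class FrameRef:
    """A single time-lapse frame on disk."""

    path: Path
    timestamp: datetime
    width: int | None = None
    height: int | None = None


def hhmm_to_hours(value: str) -> float:
    """Parse ``"11:41"`` or ``"1141"`` into decimal hours (11.6833...)."""
    s = str(value).strip()
    if ":" in s:
        hh, mm = s.split(":")
    elif len(s) in (3, 4) and s.isdigit():
        hh, mm = s[:-2], s[-2:]
    else:
        raise FormatError(f"cannot parse time-of-day {value!r}")
    h, m = int(hh), int(mm)
    if not (0 <= h < 24 and 0 <= m < 60):
        raise FormatError(f"time-of-day {value!r} out of range")
    return h + m / 60.0


def hours_to_hhmm(hours: float) -> str:
    """Render decimal hours as ``HH:MM`` (minutes rounded)."""
    total = int(round(hours * 60.0))
    return f"{(total // 60) % 24:02d}:{total % 60:02d}"


def load_frame_sequence(
    directory: str | Path,
    timestamp_pattern: str = "%Y%m%d_%H%M",
    extensions: tuple[str, ...] = (".jpg", ".jpeg", ".png"),
) -> list[FrameRef]:
    """List frames in ``directory``, ordered by timestamp parsed from filenames.

    Files whose stem does not match ``timestamp_pattern`` (strptime syntax)
    are skipped with a warning.  Duplicate timestamps or an empty result are
    errors: analysis assumes a strict total order on frame times.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FormatError(f"frame directory {directory} does not exist")
    refs: list[FrameRef] = []
    for p in sorted(directory.iterdir()):
        if p.suffix.lower() not in extensions:
            continue
        try:
            ts = datetime.strptime(p.stem, timestamp_pattern)
        except ValueError:
            log.warning("skipping frame %s: stem does not match %r", p.name, timestamp_pattern)
            continue
        refs.append(FrameRef(path=p, timestamp=ts))
    if not refs:
        raise FormatError(f"no frames matching {timestamp_pattern!r} in {directory}")
    refs.sort(key=lambda r: r.timestamp)
    for a, b in zip(refs, refs[1:]):
        if a.timestamp == b.timestamp:
            raise FormatError(
                f"duplicate frame timestamp {a.timestamp}: {a.path.name} and {b.path.name}"
            )
    return refs


def load_weather_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    timestamp_format: str | None = None,
    cadence_min: int = 10,
) -> pd.DataFrame:
    """Load the weather logger table.

    ``column_map`` maps canonical names (``timestamp``, ``temp_c``,
    ``rh_pct``, ``radiation``) to the file's headers when they differ.
    Records are sorted by time; humidity outside [0, 100] is an error; gaps
    in the nominal cadence are kept as gaps (never imputed) and logged.
    """
    path = Path(path)
    raw = pd.read_csv(path)
    column_map = dict(column_map or {})
    rename = {column_map.get(c, c): c for c in WEATHER_COLUMNS}
    missing = [src for src in rename if src not in raw.columns]
    if missing:
        raise FormatError(
            f"weather file {path} lacks columns {missing}; available: {list(raw.columns)}"
        )
    df = raw.rename(columns=rename)[WEATHER_COLUMNS].copy()
    if timestamp_format:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format=timestamp_format)
    else:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    df = df.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
    if df["timestamp"].duplicated().any():
        dup = df.loc[df["timestamp"].duplicated(), "timestamp"].iloc[0]
        raise FormatError(f"duplicate weather timestamp {dup}")
    bad_h = df[(df["rh_pct"] < 0) | (df["rh_pct"] > 100)]
    if len(bad_h):
        raise FormatError(
            f"relative humidity outside [0, 100] at {bad_h['timestamp'].iloc[0]} "
            f"(value {bad_h['rh_pct'].iloc[0]})"
        )
    steps = df["timestamp"].diff().dropna()
    gaps = steps[steps > pd.Timedelta(minutes=cadence_min)]
    for idx in gaps.index:
        log.warning(
            "weather gap of %s before %s (nominal cadence %d min)",
            steps.loc[idx],
            df.loc[idx, "timestamp"],
            cadence_min,
        )
    return df


def write_weather_csv(weather: pd.DataFrame, path: str | Path) -> None:
    weather.to_csv(path, index=False, columns=WEATHER_COLUMNS)


def write_detections(
    detections: pd.DataFrame, path: str | Path, meta: dict | None = None
) -> None:
    """Write a detection table to CSV plus a ``.meta.json`` sidecar.

    The sidecar records run metadata (thresholds, crop origin, seeds) so a
    detection table is auditable without re-running the detector.
    """
    path = Path(path)
    df = detections.copy()
    if len(df) == 0:
        df = pd.DataFrame(columns=DETECTION_COLUMNS)
    df.to_csv(path, index=False, columns=DETECTION_COLUMNS)
    if meta is not None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_detections(path: str | Path) -> pd.DataFrame:
    """Load a detection table; lossless inverse of :func:`write_detections`."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise FormatError(f"malformed detection table {path}: {exc}") from exc
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"detection table {path} lacks columns {missing}")
    if len(df) == 0:
        return df[DETECTION_COLUMNS]
    incomplete = df[DETECTION_COLUMNS].drop(columns=["mean_b"]).isna().any(axis=1)
    if incomplete.any():
        rownum = int(np.flatnonzero(incomplete.to_numpy())[0]) + 2  # 1-based + header
        raise FormatError(f"detection table {path}: truncated or incomplete row at line {rownum}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    for c in ("x_min", "y_min", "x_max", "y_max", "area_px", "height_px"):
        df[c] = df[c].astype(int)
    return df[DETECTION_COLUMNS]


def load_observed_fot(path: str | Path) -> pd.DataFrame:
    """Load manually observed flower-opening times.

    Columns ``date, side, hhmm``; returns a frame with ``fot_observed`` in
    decimal hours.  At most one record per (date, side).
    """
    df = pd.read_csv(path, dtype={"hhmm": str})
    missing = [c for c in OBSERVED_FOT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"observed-FOT table {path} lacks columns {missing}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    if df.duplicated(subset=["date", "side"]).any():
        dup = df[df.duplicated(subset=["date", "side"])].iloc[0]
        raise FormatError(f"duplicate observed FOT for ({dup['date']}, {dup['side']})")
    df["fot_observed"] = df["hhmm"].map(hhmm_to_hours)
    return df[["date", "side", "fot_observed"]]


def write_observed_fot(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["hhmm"] = out["fot_observed"].map(hours_to_hhmm)
    out[["date", "side", "hhmm"]].to_csv(path, index=False)
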