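"""Meter CSV ingestion, resampling to 15-min slots, day segmentation, reports.

Input CSVs carry a header with a timestamp column (ISO-8601, labelling the
start of the interval) and an energy column in Wh (or kWh via config).
Internally everything is watt-hours per 15-minute slot; a complete day is 96
slots indexed 0-95 from local midnight.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import IOConfig
from .types import SLOTS_PER_DAY, SLOT_SECONDS, DailyAssessment, DayTrace, MeterSeries

logger = logging.getLogger(__name__)


def read_meter_series(
    path: str | Path,
    config: IOConfig | None = None,
    household_id: str | None = None,
) -> MeterSeries:
    """Parse a meter CSV into a sorted, validated :class:`MeterSeries`.

    Malformed rows raise with their 1-based line number (header = line 1).
    Duplicate timestamps and negative energies are errors; kWh columns are
    converted to Wh on ingest.  The native resolution is the median spacing
    between consecutive readings (900 s for a single reading or empty file).
    """
    cfg = config or IOConfig()
    path = Path(path)
    df = pd.read_csv(path)
    for col in (cfg.timestamp_column, cfg.energy_column):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")

    ts = pd.to_datetime(df[cfg.timestamp_column], errors="coerce", format="ISO8601")
    bad = ts.isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ValueError(f"{path}:{line}: unparseable timestamp "
                         f"{df[cfg.timestamp_column].iloc[bad.idxmax()]!r}")
    energy = pd.to_numeric(df[cfg.energy_column], errors="coerce")
    bad = energy.isna() | ~np.isfinite(energy)
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise ValueError(f"{path}:{line}: unparseable energy "
                         f"{df[cfg.energy_column].iloc[bad.idxmax()]!r}")
    if (energy < 0).any():
        line = int((energy < 0).idxmax()) + 2
        raise ValueError(f"{path}:{line}: negative energy {energy[(energy < 0).idxmax()]}")
    if cfg.energy_unit == "kwh":
        energy = energy * 1000.0

    dup = ts.duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicate timestamp {ts[dup].iloc[0]}")

    frame = (
        pd.DataFrame({"timestamp": ts, "energy_wh": energy.astype(float)})
        .sort_values("timestamp", kind="stable")
        .reset_index(drop=True)
    )
    if len(frame) >= 2:
        resolution = int(frame["timestamp"].diff().dropna().median().total_seconds())
    else:
        resolution = SLOT_SECONDS
    logger.info("%s: read %d rows (native resolution %d s)", path, len(frame), resolution)
    return MeterSeries(
        household_id=household_id or path.stem,
        frame=frame,
        native_resolution=resolution,
    )


def resample_to_slots(series: MeterSeries) -> MeterSeries:
    """Sum energies into 15-min slots by timestamp membership.

    Each reading is assigned to the slot containing its (interval-start)
    timestamp, so total energy is conserved exactly.  Series already at
    15-min resolution pass through with timestamps floored to slot starts;
    coarser series cannot be refined and raise.
    """
    if series.native_resolution > SLOT_SECONDS:
        raise ValueError(
            f"cannot resample {series.native_resolution} s resolution to "
            f"{SLOT_SECONDS} s slots: data are coarser than the target"
        )
    frame = series.frame
    if frame.empty:
        return MeterSeries(series.household_id, frame.copy(), SLOT_SECONDS)
    grouped = (
        frame.groupby(frame["timestamp"].dt.floor("15min"))["energy_wh"]
        .sum()
        .rename_axis("timestamp")
        .reset_index()
    )
    return MeterSeries(series.household_id, grouped, SLOT_SECONDS)


def split_complete_days(
    series: MeterSeries,
) -> tuple[list[DayTrace], list[tuple[dt.date, list[int]]]]:
    """Segment a 15-min series into complete 96-slot days.

    Days missing any slot are rejected (returned with the missing slot
    indices) rather than imputed: thresholds and scores assume 96 points.
    """
    if series.native_resolution != SLOT_SECONDS:
        raise ValueError("series must be at 15-min resolution; resample first")
    days: list[DayTrace] = []
    rejects: list[tuple[dt.date, list[int]]] = []
    frame = series.frame
    if frame.empty:
        return days, rejects
    ts = frame["timestamp"]
    slot_idx = (ts.dt.hour * 4 + ts.dt.minute // 15).to_numpy()
    for date, grp in frame.groupby(ts.dt.date, sort=True):
        idx = slot_idx[grp.index.to_numpy()]
        slots = np.full(SLOTS_PER_DAY, np.nan)
        slots[idx] = grp["energy_wh"].to_numpy()
        missing = np.flatnonzero(np.isnan(slots))
        if missing.size:
            rejects.append((date, [int(i) for i in missing]))
        else:
            days.append(DayTrace(date, slots))
    return days, rejects


def write_report(assessments: list[DailyAssessment], path: str | Path) -> None:
    """Write daily assessments as a JSON report (one object per assessed day).

    The record schema mirrors the dashboard's indices: active score, CC,
    low/norm/high norms, tier labels and status color.
    """
    if not assessments:
        raise ValueError("cannot write an empty report")
    payload = {
        "schema": "meterwatch-daily-assessment/1",
        "days": [a.to_dict() for a in assessments],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_report(path: str | Path) -> list[dict]:
    """Read back a report written by :func:`write_report`."""
    payload = json.loads(Path(path).read_text())
    return payload["days"]


def series_to_csv(series: MeterSeries, path: str | Path) -> None:
    """Write a series in the canonical input schema (timestamp, energy_wh)."""
    series.frame.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")
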