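"""Domain containers for interval meter data and derived assessment objects.

The canonical internal unit is watt-hours per 15-minute slot.  A day is 96
slots; slot ``i`` covers minutes ``[15*i, 15*(i+1))`` from local midnight, and
timestamps label the *start* of their interval.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SLOTS_PER_DAY = 96
SLOT_MINUTES = 15
SLOT_SECONDS = SLOT_MINUTES * 60


@dataclass(frozen=True)
class MeterReading:
    """A single meter report: energy (Wh) consumed since the previous reading."""

    timestamp: dt.datetime
    energy_wh: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.energy_wh) or self.energy_wh < 0:
            raise ValueError(f"energy must be finite and >= 0, got {self.energy_wh}")


@dataclass
class MeterSeries:
    """An ordered household energy series at a fixed native resolution.

    ``frame`` has columns ``timestamp`` (datetime64) and ``energy_wh`` (float),
    sorted by timestamp with no duplicates.  ``native_resolution`` is the
    spacing between readings in seconds.
    """

    household_id: str
    frame: pd.DataFrame
    native_resolution: int

    def __post_init__(self) -> None:
        ts = self.frame["timestamp"]
        if ts.duplicated().any():
            dup = ts[ts.duplicated()].iloc[0]
            raise ValueError(f"duplicate timestamp in series: {dup}")
        if not ts.is_monotonic_increasing:
            raise ValueError("timestamps must be strictly increasing")
        energy = self.frame["energy_wh"].to_numpy()
        if len(energy) and (not np.all(np.isfinite(energy)) or (energy < 0).any()):
            raise ValueError("energies must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def readings(self) -> list[MeterReading]:
        return [
            MeterReading(ts.to_pydatetime(), float(e))
            for ts, e in zip(self.frame["timestamp"], self.frame["energy_wh"])
        ]


@dataclass
class DayTrace:
    """One calendar day as 96 slot energies (Wh per 15-min slot)."""

    date: dt.date
    slots: np.ndarray

    def __post_init__(self) -> None:
        self.slots = np.asarray(self.slots, dtype=float)
        if self.slots.shape != (SLOTS_PER_DAY,):
            raise ValueError(
                f"a day has exactly {SLOTS_PER_DAY} slots, got {self.slots.shape}"
            )
        if not np.all(np.isfinite(self.slots)) or (self.slots < 0).any():
            raise ValueError("slot energies must be finite and non-negative")


@dataclass
class ThresholdEstimate:
    """Background-power threshold with valley provenance.

    For a single-day estimate, ``value`` is the mean slot energy over
    ``valley_indices`` unless ``fallback_used`` is set; for a rolling estimate
    ``value`` averages per-day thresholds and ``valley_indices`` is empty.
    """

    value: float
    valley_indices: tuple[int, ...] = ()
    fallback_used: bool = False
    source: str = ""


@dataclass
class UsageVector:
    """Binary appliance-usage flags for one day: 1 = active, 0 = inactive."""

    date: dt.date
    flags: np.ndarray

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=np.int8)
        if self.flags.shape != (SLOTS_PER_DAY,):
            raise ValueError(f"usage vector must have {SLOTS_PER_DAY} flags")
        if not np.isin(self.flags, (0, 1)).all():
            raise ValueError("usage flags must be 0 or 1")


@dataclass(frozen=True)
class ActiveScore:
    """Percentage of the day's 96 slots that are active."""

    date: dt.date
    score: float


@dataclass
class NormProfile:
    """Per-slot percentage of active days over a trailing window (default 28 d)."""

    window_end_date: dt.date
    slot_percentages: np.ndarray

    def __post_init__(self) -> None:
        self.slot_percentages = np.asarray(self.slot_percentages, dtype=float)
        if self.slot_percentages.shape != (SLOTS_PER_DAY,):
            raise ValueError(f"profile must have {SLOTS_PER_DAY} values")


@dataclass(frozen=True)
class NormBand:
    """Mean active score over the window, flanked by the sorted-half means."""

    low: float
    norm: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.norm <= self.high):
            raise ValueError(
                f"norm band must satisfy low <= norm <= high, got "
                f"({self.low}, {self.norm}, {self.high})"
            )


@dataclass(frozen=True)
class RegularityResult:
    """Pearson correlation between a day's usage and the usage norm.

    ``defined`` is False when either vector has zero variance; the
    correlation is then reported as not assessable rather than coerced to 0.
    """

    cc: float | None
    defined: bool
    n: int = SLOTS_PER_DAY


@dataclass
class DailyAssessment:
    """The full per-day verdict: scores, regularity, tiers, and status color."""

    date: dt.date
    active_score: float
    norm_band: NormBand
    cc: float | None
    cc_defined: bool
    activity_level: str
    regularity_level: str
    overall_status: str
    status_color: str

    def to_dict(self) -> dict:
        return {
            "date": self.date.isoformat(),
            "active_score": self.active_score,
            "norm_low": self.norm_band.low,
            "norm": self.norm_band.norm,
            "norm_high": self.norm_band.high,
            "cc": self.cc,
            "cc_defined": self.cc_defined,
            "activity_level": self.activity_level,
            "regularity_level": self.regularity_level,
            "overall_status": self.overall_status,
            "status_color": self.status_color,
        }


@dataclass
class AccuracyRecord:
    """Per-day binarization accuracy against ground truth."""

    household_id: str
    date: dt.date
    n_slots: int
    n_correct: int

    @property
    def accuracy(self) -> float:
        return 100.0 * self.n_correct / self.n_slots


@dataclass
class TruthSeries:
    """Ground-truth per-slot activity labels aligned with a simulated trace."""

    dates: list[dt.date]
    labels: np.ndarray = field(repr=False)  # (n_days, 96) in {0, 1}

    def day(self, i: int) -> UsageVector:
        return UsageVector(self.dates[i], self.labels[i])
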