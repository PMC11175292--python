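"""Synthetic household load simulator with ground-truth activity labels.

A household is a continuous background load — a refrigerator compressor duty
cycle plus constant standby — with user-operated appliances from a standard
power-rating catalog fired at daily schedule anchors (meals, chores, evening
leisure) with jitter.  Traces render at 10-s or 15-min resolution from the
same event schedule, so downsampling the fine trace reproduces the coarse
one exactly.  Each 15-min slot carries a ground-truth label: 1 iff any
non-background appliance ran during the slot.

The compressor square wave (50% duty, 30-min period, 400 W when on, 200 W
mean) is phase-offset by half a slot so that every 15-min slot contains
exactly 7.5 min of compressor time.  The metered background is therefore
flat at slot resolution — the "low valley" structure the thresholding
method assumes — while the 10-s rendering still shows the cycling.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import SLOTS_PER_DAY, DayTrace, MeterSeries, TruthSeries

TICK_SECONDS = 10
TICKS_PER_SLOT = 90
MINUTES_PER_DAY = 1440

SCENARIOS = ("regular", "weekend_shift", "irregular", "inactivity")


@dataclass(frozen=True)
class Appliance:
    """One catalog entry: rated power, typical daily use, event structure."""

    name: str
    rated_power_w: float
    typical_daily_hours: float
    is_background: bool = False
    event_minutes: float = 0.0  # duration of one usage event
    events_per_day: int = 0

    def __post_init__(self) -> None:
        if self.rated_power_w <= 0:
            raise ValueError("rated power must be positive")
        if not 0 <= self.typical_daily_hours <= 24:
            raise ValueError("daily hours must be within [0, 24]")


def default_catalog() -> list[Appliance]:
    """The 11-appliance power-rating catalog (power W, hours/day).

    The refrigerator is the only background appliance (24 h/day); the rest
    are user-operated and carry an event structure splitting their daily
    hours across one or two scheduled events.
    """
    rows = [
        # name, W, h/day, background, minutes/event, events/day
        ("air_conditioner", 2200, 8, False, 480, 1),
        ("hair_dryer", 800, 0.25, False, 15, 1),
        ("rice_cooker", 1250, 0.4, False, 24, 1),
        ("dehumidifier", 630, 4, False, 240, 1),
        ("electric_fan", 70, 8, False, 480, 1),
        ("microwave_oven", 1700, 0.17, False, 5.1, 2),
        ("hot_water_kettle", 700, 0.5, False, 15, 2),
        ("refrigerator", 200, 24, True, 0, 0),
        ("electric_pot", 600, 0.67, False, 40.2, 1),
        ("washing_machine", 500, 0.67, False, 40.2, 1),
        ("television", 300, 8, False, 240, 2),
    ]
    return [
        Appliance(name, p, h, bg, minutes, n) for name, p, h, bg, minutes, n in rows
    ]


def appliance_daily_energy(a: Appliance) -> float:
    """Typical daily energy in kWh/day: rated power x daily hours / 1000."""
    return a.rated_power_w * a.typical_daily_hours / 1000.0


# appliances a default (non-seasonal) household operates every day
DEFAULT_ACTIVE = (
    "hair_dryer",
    "rice_cooker",
    "microwave_oven",
    "hot_water_kettle",
    "electric_pot",
    "washing_machine",
    "television",
)


@dataclass
class HouseholdModel:
    """Schedule and noise parameters of one simulated household."""

    seed: int
    household_id: str = "sim"
    catalog: list[Appliance] = field(default_factory=default_catalog)
    active_appliances: tuple[str, ...] = DEFAULT_ACTIVE
    wake_slot: int = 28  # 07:00
    sleep_slot: int = 92  # 23:00
    jitter_minutes: float = 15.0
    irregular: bool = False
    weekend_wake_shift_minutes: float = 0.0
    weekend_extra_events: bool = False
    inactivity_onset_day: int | None = None  # 1-based day number
    standby_w: float = 30.0
    noise_sigma: float = 0.05
    seasonal_amplitude: float = 0.0  # optional sinusoidal background modulation
    start_date: dt.date = dt.date(2024, 1, 1)

    def __post_init__(self) -> None:
        if not self.wake_slot < self.sleep_slot:
            raise ValueError(
                f"wake slot ({self.wake_slot}) must precede sleep slot ({self.sleep_slot})"
            )
        if self.jitter_minutes < 0:
            raise ValueError("jitter must be non-negative")

    def appliance(self, name: str) -> Appliance:
        for a in self.catalog:
            if a.name == name:
                return a
        raise KeyError(name)


@dataclass(frozen=True)
class ScheduledEvent:
    """One appliance run: [start, start+duration) minutes from local midnight."""

    appliance: str
    power_w: float
    start_minute: float
    duration_minutes: float

    @property
    def end_minute(self) -> float:
        return self.start_minute + self.duration_minutes


def _snap(minutes: float) -> float:
    """Snap a time in minutes to the 10-s grid."""
    return round(minutes * 6) / 6


def _anchor_plan(model: HouseholdModel) -> list[tuple[str, float]]:
    """(appliance name, anchor minute) for each daily event of the household."""
    wake = model.wake_slot * 15
    anchors = {
        "hair_dryer": [wake + 15],
        "rice_cooker": [17 * 60 + 30],
        "microwave_oven": [wake + 5, 12 * 60 + 10],
        "hot_water_kettle": [wake, 20 * 60],
        "electric_pot": [12 * 60],
        "washing_machine": [wake + 90],
        "television": [14 * 60, 19 * 60],
        "air_conditioner": [13 * 60],
        "dehumidifier": [9 * 60],
        "electric_fan": [13 * 60],
    }
    plan: list[tuple[str, float]] = []
    for a in model.catalog:
        if a.is_background or a.name not in model.active_appliances:
            continue
        for anchor in anchors.get(a.name, [12 * 60])[: max(a.events_per_day, 1)]:
            plan.append((a.name, float(anchor)))
    return plan


def build_schedule(
    model: HouseholdModel, n_days: int
) -> tuple[list[list[ScheduledEvent]], np.ndarray, np.ndarray]:
    """Draw the full stochastic schedule for ``n_days``.

    Returns ``(events_by_day, noise_factors (n_days, 96), season_factors
    (n_days,))``.  All randomness flows from ``model.seed`` in a fixed
    stream order (per day: event jitter in catalog order, then the day's 96
    background noise factors), so traces are bit-reproducible and identical
    across rendering resolutions.
    """
    rng = np.random.default_rng(model.seed)
    plan = _anchor_plan(model)
    wake_min = model.wake_slot * 15.0
    sleep_min = model.sleep_slot * 15.0
    j = model.jitter_minutes
    events_by_day: list[list[ScheduledEvent]] = []
    noise = np.empty((n_days, SLOTS_PER_DAY))
    season = np.empty(n_days)
    for d in range(n_days):
        date = model.start_date + dt.timedelta(days=d)
        weekend = date.weekday() >= 5
        inactive = (
            model.inactivity_onset_day is not None
            and d + 1 >= model.inactivity_onset_day
        )
        shift = model.weekend_wake_shift_minutes if weekend else 0.0
        todays_plan = list(plan)
        if weekend and model.weekend_extra_events and not inactive:
            todays_plan += [("television", 10 * 60.0), ("microwave_oven", 15 * 60.0)]
        day_events: list[ScheduledEvent] = []
        for name, anchor in todays_plan:
            a = model.appliance(name)
            dur = _snap(max(a.event_minutes, TICK_SECONDS / 60))
            if model.irregular:
                start = rng.uniform(wake_min, sleep_min - dur)
            else:
                start = anchor + shift + rng.uniform(-j, j)
            start = _snap(min(max(start, 0.0), MINUTES_PER_DAY - dur))
            if not inactive:
                day_events.append(ScheduledEvent(name, a.rated_power_w, start, dur))
        events_by_day.append(day_events)
        noise[d] = np.clip(rng.normal(1.0, model.noise_sigma, SLOTS_PER_DAY), 0.0, None)
        season[d] = 1.0 + model.seasonal_amplitude * np.sin(2 * np.pi * d / 365.0)
    if model.noise_sigma == 0:
        noise[:] = 1.0
    return events_by_day, noise, season


def _overlap_minutes(start: float, end: float, lo: float, hi: float) -> float:
    return max(0.0, min(end, hi) - max(start, lo))


def _fridge_slot_wh(model: HouseholdModel) -> float:
    # compressor: 2x rated power at 50% duty; phase-offset by half a slot
    # => exactly half of every slot is compressor-on time
    fridge = model.appliance("refrigerator")
    return 2 * fridge.rated_power_w * 7.5 / 60.0


def render_slot_matrix(
    model: HouseholdModel, n_days: int
) -> tuple[np.ndarray, np.ndarray]:
    """Render (energy (n_days, 96) in Wh, truth labels (n_days, 96) in {0,1})."""
    events_by_day, noise, season = build_schedule(model, n_days)
    background = _fridge_slot_wh(model) + model.standby_w * 0.25
    energy = noise * season[:, None] * background
    truth = np.zeros((n_days, SLOTS_PER_DAY), dtype=np.int8)
    for d, day_events in enumerate(events_by_day):
        for ev in day_events:
            lo_slot = int(ev.start_minute // 15)
            hi_slot = min(int(np.ceil(ev.end_minute / 15)), SLOTS_PER_DAY)
            for s in range(lo_slot, hi_slot):
                ov = _overlap_minutes(ev.start_minute, ev.end_minute, 15 * s, 15 * (s + 1))
                if ov > 1e-9:
                    energy[d, s] += ev.power_w * ov / 60.0
                    truth[d, s] = 1
    return energy, truth


def _render_ticks(model: HouseholdModel, n_days: int) -> tuple[np.ndarray, np.ndarray]:
    """10-s rendering; returns (energy per tick in Wh, truth (n_days, 96))."""
    events_by_day, noise, season = build_schedule(model, n_days)
    fridge = model.appliance("refrigerator")
    on_power = 2 * fridge.rated_power_w
    ticks_per_day = MINUTES_PER_DAY * 60 // TICK_SECONDS
    t0 = np.arange(ticks_per_day) * TICK_SECONDS  # tick start, seconds
    # compressor on during [450, 1350) of each 1800-s period (half-slot phase)
    fridge_w = np.where((t0 % 1800 >= 450) & (t0 % 1800 < 1350), on_power, 0.0)
    slot_of_tick = t0 // (15 * 60)
    truth = np.zeros((n_days, SLOTS_PER_DAY), dtype=np.int8)
    out = np.empty((n_days, ticks_per_day))
    for d, day_events in enumerate(events_by_day):
        background_w = fridge_w + model.standby_w
        e = noise[d][slot_of_tick] * season[d] * background_w * TICK_SECONDS / 3600.0
        for ev in day_events:
            s0, s1 = ev.start_minute * 60, ev.end_minute * 60
            lo, hi = int(s0 // TICK_SECONDS), int(np.ceil(s1 / TICK_SECONDS))
            for t in range(lo, min(hi, ticks_per_day)):
                ov = _overlap_minutes(s0, s1, t0[t], t0[t] + TICK_SECONDS)
                if ov > 0:
                    e[t] += ev.power_w * ov / 3600.0
                    truth[d, slot_of_tick[t]] = 1
        out[d] = e
    return out, truth


def simulate_household(
    model: HouseholdModel, n_days: int, resolution: str = "15min"
) -> tuple[MeterSeries, TruthSeries]:
    """Simulate a household trace with ground-truth per-slot activity labels.

    ``resolution`` is ``'15min'`` (the meter's native interval, 96 readings a
    day) or ``'10s'`` (a fine-grained validation meter).  The same seed gives
    the same schedule at both resolutions; summing the 10-s trace into slots
    reproduces the 15-min trace.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    dates = [model.start_date + dt.timedelta(days=d) for d in range(n_days)]
    if resolution == "15min":
        energy, truth = render_slot_matrix(model, n_days)
        stamps = pd.date_range(
            start=pd.Timestamp(model.start_date),
            periods=n_days * SLOTS_PER_DAY,
            freq="15min",
        )
        frame = pd.DataFrame({"timestamp": stamps, "energy_wh": energy.ravel()})
        series = MeterSeries(model.household_id, frame, 900)
    elif resolution == "10s":
        energy, truth = _render_ticks(model, n_days)
        stamps = pd.date_range(
            start=pd.Timestamp(model.start_date),
            periods=energy.size,
            freq=f"{TICK_SECONDS}s",
        )
        frame = pd.DataFrame({"timestamp": stamps, "energy_wh": energy.ravel()})
        series = MeterSeries(model.household_id, frame, TICK_SECONDS)
    else:
        raise ValueError(f"unknown resolution {resolution!r} (use '15min' or '10s')")
    return series, TruthSeries(dates, truth)


def simulate_day_traces(
    model: HouseholdModel, n_days: int
) -> tuple[list[DayTrace], TruthSeries]:
    """Convenience: simulate directly into per-day 96-slot traces."""
    energy, truth = render_slot_matrix(model, n_days)
    dates = [model.start_date + dt.timedelta(days=d) for d in range(n_days)]
    return (
        [DayTrace(date, row) for date, row in zip(dates, energy)],
        TruthSeries(dates, truth),
    )


def make_scenario(kind: str, seed: int, **overrides) -> HouseholdModel:
    """Build a household model for one of the study scenarios.

    regular
        Tight schedule jitter (15 min) around fixed daily anchors.
    weekend_shift
        Two-hour later anchors plus extra leisure events on Sat/Sun.
    irregular
        Event start times drawn uniformly over the waking day, every day.
    inactivity
        Regular until an onset day (default 43), after which all
        user-operated events are suppressed.
    """
    base = dict(seed=seed, household_id=f"{kind}-{seed}")
    if kind == "regular":
        pass
    elif kind == "weekend_shift":
        base.update(weekend_wake_shift_minutes=120.0, weekend_extra_events=True)
    elif kind == "irregular":
        base.update(irregular=True)
    elif kind == "inactivity":
        base.update(inactivity_onset_day=43)
    else:
        raise ValueError(f"unknown scenario kind {kind!r} (choose from {SCENARIOS})")
    base.update(overrides)
    return HouseholdModel(**base)
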