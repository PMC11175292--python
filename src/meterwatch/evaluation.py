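"""Binarization-accuracy evaluation against ground truth.

Replicates the rolling-threshold validation protocol: collect a fixed number
of days per household, generate a fresh 14-day rolling threshold every day,
binarize the evaluation days, and score per-slot agreement with the
ground-truth activity labels.  The default protocol (10 households, 24 days,
14-day window, 10 evaluation days) yields exactly 100 accuracy records.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .estimators import ValleyThresholdBinarizer
from .simulator import HouseholdModel, simulate_day_traces
from .types import AccuracyRecord, UsageVector


def binarization_accuracy(
    predicted: UsageVector,
    truth: UsageVector,
    household_id: str = "",
) -> AccuracyRecord:
    """Per-slot percent agreement between predicted and true activity flags."""
    if predicted.flags.shape != truth.flags.shape:
        raise ValueError(
            f"length mismatch: {predicted.flags.size} vs {truth.flags.size}"
        )
    n_correct = int((predicted.flags == truth.flags).sum())
    return AccuracyRecord(
        household_id=household_id,
        date=predicted.date,
        n_slots=predicted.flags.size,
        n_correct=n_correct,
    )


def display_accuracy(accuracy: float, decimals: int = 1) -> float:
    """Truncate (not round) an accuracy percentage for display: 95/96 -> 98.9."""
    scale = 10**decimals
    return math.floor(accuracy * scale) / scale


def validation_protocol(
    cohort: list[HouseholdModel],
    days_per_household: int = 24,
    threshold_window: int = 14,
    eval_days: int = 10,
    endpoint_policy: str = "exclude",
    fallback: str = "min",
) -> tuple[list[AccuracyRecord], float]:
    """Run the rolling-threshold accuracy protocol on a simulated cohort.

    For each household, ``days_per_household`` days are simulated; each of
    the last ``eval_days`` days is binarized with a threshold refreshed daily
    from the preceding ``threshold_window`` days and compared against the
    simulator's ground truth.  Returns the per-household-day records and the
    cohort mean accuracy (percent, full precision).
    """
    if not cohort:
        raise ValueError("cohort must not be empty")
    if days_per_household < threshold_window + eval_days:
        raise ValueError(
            f"need at least {threshold_window + eval_days} days per household "
            f"({threshold_window} threshold + {eval_days} evaluation), "
            f"got {days_per_household}"
        )
    records: list[AccuracyRecord] = []
    for model in cohort:
        traces, truth = simulate_day_traces(model, days_per_household)
        energy = np.stack([t.slots for t in traces])
        for k in range(eval_days):
            i = threshold_window + k
            binarizer = ValleyThresholdBinarizer(
                endpoint_policy=endpoint_policy,
                fallback=fallback,
                window=threshold_window,
            ).fit(energy[i - threshold_window : i])
            flags = binarizer.transform(energy[i])[0]
            predicted = UsageVector(traces[i].date, flags)
            records.append(
                binarization_accuracy(predicted, truth.day(i), model.household_id)
            )
    mean_accuracy = float(np.mean([r.accuracy for r in records]))
    return records, mean_accuracy


def records_to_frame(records: list[AccuracyRecord]) -> pd.DataFrame:
    """Tabulate accuracy records (household_id, date, n_correct, accuracy)."""
    return pd.DataFrame(
        {
            "household_id": [r.household_id for r in records],
            "date": [r.date.isoformat() for r in records],
            "n_correct": [r.n_correct for r in records],
            "accuracy": [r.accuracy for r in records],
        }
    )
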