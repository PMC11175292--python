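"""Background-power threshold estimation from daily low valleys.

The threshold separates user-driven appliance usage from the always-on base
load (refrigerator, standby devices).  A day's threshold is the mean slot
energy over its "low valleys" — slots that do not exceed either neighbour —
and a deployment-grade threshold averages the per-day estimates over a
rolling window (default 14 days), refreshed daily.
"""

from __future__ import annotations

import datetime as dt

import numpy as np

from .estimators import ValleyThresholdBinarizer, day_threshold_kernel, prominence_kernel
from .types import DayTrace, ThresholdEstimate


def prominence(day: DayTrace, endpoint_policy: str = "exclude") -> np.ndarray:
    """Valley-prominence vector of a day: zero exactly at non-strict local minima.

    Interior slots use the two-sided difference
    ``max(A[i]-A[i-1], 0) + max(A[i]-A[i+1], 0)``; endpoints use the
    one-sided difference under ``'include'`` and an ``inf`` sentinel under
    ``'exclude'`` (the default, which restricts valleys to interior slots).
    """
    return prominence_kernel(day.slots, endpoint_policy)


def background_threshold(
    day: DayTrace,
    endpoint_policy: str = "exclude",
    fallback: str = "min",
) -> ThresholdEstimate:
    """Single-day background-power threshold: mean energy of the valley slots.

    If the day has no valleys (e.g. strictly monotone energies), the fallback
    supplies the day's minimum slot energy and ``fallback_used`` is set.
    """
    value, valleys, used = day_threshold_kernel(day.slots, endpoint_policy, fallback)
    return ThresholdEstimate(
        value=value,
        valley_indices=tuple(int(i) for i in valleys),
        fallback_used=used,
        source=day.date.isoformat(),
    )


def rolling_threshold(
    history: list[DayTrace],
    window: int = 14,
    target_date: dt.date | None = None,
    endpoint_policy: str = "exclude",
    fallback: str = "min",
) -> ThresholdEstimate:
    """Rolling threshold for ``target_date``: the mean of the per-day valley
    thresholds over the ``window`` most recent complete days strictly before it.

    When ``target_date`` is None the window is taken from the end of the
    history.  Raises if fewer than ``window`` qualifying days exist.
    """
    days = sorted(history, key=lambda d: d.date)
    if target_date is not None:
        days = [d for d in days if d.date < target_date]
    if len(days) < window:
        raise ValueError(
            f"insufficient history for rolling threshold: {len(days)} day(s) "
            f"available, {window} required"
        )
    days = days[-window:]
    est = ValleyThresholdBinarizer(
        endpoint_policy=endpoint_policy, fallback=fallback, window=window
    ).fit(np.stack([d.slots for d in days]))
    return ThresholdEstimate(
        value=est.threshold_,
        valley_indices=(),
        fallback_used=bool(est.fallback_used_.any()),
        source=f"{days[0].date.isoformat()}..{days[-1].date.isoformat()}",
    )
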