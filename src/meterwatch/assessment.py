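"""Tier classification and the end-to-end daily assessment.

Activity levels compare the day's active score with the 28-day norm band;
regularity levels tier the Pearson correlation at 0.7 / 0.5 / 0.3.  The
overall household status is the worst severity among the available indices,
colored green / blue / yellow / red (gray when nothing is assessable).
"""

from __future__ import annotations

import datetime as dt

import numpy as np

from .config import PipelineConfig
from .estimators import (
    LEVEL_COLORS,
    LifestyleMonitor,
    aggregate_status,
    regularity_level_from_cc,
)
from .types import ActiveScore, DailyAssessment, DayTrace, NormBand, RegularityResult

ACTIVITY_LEVELS = ("high", "normal", "low", "abnormally_low")
# §-style regularity labels; "poor" is an accepted alias of "irregular"
REGULARITY_LEVELS = ("high", "normal", "low", "irregular", "not_assessable")


class InsufficientHistoryError(ValueError):
    """Raised when fewer complete days are available than the windows require."""


def activity_level(score: ActiveScore | float, band: NormBand) -> str:
    """Tier a day's active score against the norm band.

    above high -> high; within [norm, high] -> normal; within [low, norm) ->
    low; below low -> abnormally low.
    """
    s = score.score if isinstance(score, ActiveScore) else float(score)
    if s > band.high:
        return "high"
    if s >= band.norm:
        return "normal"
    if s >= band.low:
        return "low"
    return "abnormally_low"


def regularity_level(result: RegularityResult) -> str:
    """Tier a regularity correlation (CC >= 0.7 high, >= 0.5 normal,
    >= 0.3 low, else irregular; undefined -> not assessable)."""
    return regularity_level_from_cc(result.cc, result.defined)


def overall_status(
    activity: str | None,
    regularity: str | None,
    other_indices: list[str] | None = None,
) -> tuple[str, str]:
    """Aggregate available index levels into (overall status, color).

    The overall verdict is the most severe available level; unavailable or
    not-assessable indices are ignored (gray).  With no available index at
    all the status is unknown/gray.
    """
    levels = [activity, regularity, *(other_indices or [])]
    return aggregate_status(*levels)


def assess_day(
    target_date: dt.date,
    history: list[DayTrace],
    config: PipelineConfig | None = None,
) -> DailyAssessment:
    """Run the full pipeline for one day against its own history.

    ``history`` must contain the target day's trace and at least
    ``norm_window + threshold_window`` complete days strictly before it:
    each norm-window day is binarized with its own rolling threshold, so the
    earliest norm day needs a full threshold window behind it.
    """
    cfg = config or PipelineConfig()
    by_date = {d.date: d for d in history}
    if target_date not in by_date:
        raise ValueError(f"no trace for target date {target_date} in history")
    prior = sorted((d for d in history if d.date < target_date), key=lambda d: d.date)
    need = cfg.norm_window_days + cfg.threshold_window_days
    if len(prior) < need:
        raise InsufficientHistoryError(
            f"insufficient history before {target_date}: have {len(prior)} day(s), "
            f"need {need} ({cfg.norm_window_days}-day norm window plus "
            f"{cfg.threshold_window_days}-day threshold window)"
        )
    monitor = LifestyleMonitor(
        threshold_window=cfg.threshold_window_days,
        norm_window=cfg.norm_window_days,
        endpoint_policy=cfg.endpoint_policy,
        fallback=cfg.fallback,
    ).fit(np.stack([d.slots for d in prior]))
    out = monitor.assess(by_date[target_date].slots)
    low, norm, high = out["norm_band"]
    return DailyAssessment(
        date=target_date,
        active_score=out["active_score"],
        norm_band=NormBand(low=low, norm=norm, high=high),
        cc=out["cc"],
        cc_defined=out["cc_defined"],
        activity_level=out["activity_level"],
        regularity_level=out["regularity_level"],
        overall_status=out["overall_status"],
        status_color=out["status_color"],
    )


def level_color(level: str) -> str:
    """Dashboard color for a tier label (green/blue/yellow/red; gray = n/a)."""
    return LEVEL_COLORS[level]
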