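"""Activity scoring and routine-regularity measures.

A day's 96 slot energies are binarized against the background threshold
(strictly greater -> active).  The active score is the percentage of active
slots; the 28-day norm band and per-slot usage profile summarize the recent
routine; the Pearson correlation of a day's usage against the profile
quantifies regularity.
"""

from __future__ import annotations

import numpy as np

from .estimators import RoutineNormScorer, half_mean_band, pearson_kernel
from .types import (
    ActiveScore,
    DayTrace,
    NormBand,
    NormProfile,
    RegularityResult,
    ThresholdEstimate,
    UsageVector,
)


def binarize(day: DayTrace, threshold: ThresholdEstimate | float) -> UsageVector:
    """Flag each slot active (1) iff its energy strictly exceeds the threshold.

    Equality is inactive: "higher than the threshold" is read strictly.
    """
    value = threshold.value if isinstance(threshold, ThresholdEstimate) else float(threshold)
    return UsageVector(day.date, (day.slots > value).astype(np.int8))


def active_score(usage: UsageVector) -> ActiveScore:
    """Percentage of active slots: ``100 * (number of 1s) / 96``."""
    return ActiveScore(usage.date, RoutineNormScorer.active_score(usage.flags))


def usage_norm(history: list[UsageVector], window: int = 28) -> NormProfile:
    """Per-slot percentage of active days over the trailing window."""
    if len(history) != window:
        raise ValueError(f"usage norm needs exactly {window} days, got {len(history)}")
    flags = np.stack([u.flags for u in history])
    return NormProfile(history[-1].date, 100.0 * flags.mean(axis=0))


def norm_band(scores: list[ActiveScore], window: int = 28) -> NormBand:
    """Norm band over the trailing window of daily active scores.

    ``norm`` is the mean of all scores; ``low``/``high`` are the means of the
    lower and upper sorted halves (14 days each at the default window).
    """
    if len(scores) != window:
        raise ValueError(f"norm band needs exactly {window} scores, got {len(scores)}")
    low, norm, high = half_mean_band(np.asarray([s.score for s in scores]))
    return NormBand(low=low, norm=norm, high=high)


def pearson_cc(usage: UsageVector, profile: NormProfile) -> RegularityResult:
    """Pearson correlation of a day's binary usage with the usage norm.

    Undefined (zero variance in either vector) is reported as a state, not an
    exception, so that downstream tiers can mark the day not assessable.
    """
    cc, defined = pearson_kernel(usage.flags.astype(float), profile.slot_percentages)
    return RegularityResult(cc=cc, defined=defined, n=usage.flags.size)
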