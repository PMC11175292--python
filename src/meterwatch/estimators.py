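"""Scikit-learn style estimators for the valley-threshold monitoring pipeline.

Three estimators cover the method end to end:

``ValleyThresholdBinarizer``
    Learns a household's background-power threshold from a history of daily
    96-slot energy vectors (mean of each day's "low valley" slots, averaged
    over a rolling window) and binarizes days into active/inactive slots.

``RoutineNormScorer``
    Learns the 28-day norm — the per-slot usage percentages and the
    low/norm/high active-score band — from binary usage history, and scores
    new days (active score, Pearson regularity, tier levels).

``LifestyleMonitor``
    The composed daily assessment: raw energy history in, per-day status out.

All estimators follow the sklearn contract: parameters set in ``__init__``,
state learned in ``fit`` stored in trailing-underscore attributes,
``get_params``/``set_params`` inherited from ``BaseEstimator``.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .types import SLOTS_PER_DAY

# --------------------------------------------------------------------------
# numeric kernels
# --------------------------------------------------------------------------


def prominence_kernel(a: np.ndarray, endpoint_policy: str = "exclude") -> np.ndarray:
    """Per-slot valley prominence of a daily energy vector.

    Interior slots get ``max(a[i]-a[i-1], 0) + max(a[i]-a[i+1], 0)``, which is
    zero exactly when the slot is a non-strict local minimum.  Endpoints use
    the one-sided difference when ``endpoint_policy='include'``; with
    ``'exclude'`` they are assigned ``inf`` so they can never be valleys.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 1 or a.size < 3:
        raise ValueError("need a 1-D vector of at least 3 slots")
    dif = np.empty_like(a)
    dif[1:-1] = np.maximum(a[1:-1] - a[:-2], 0) + np.maximum(a[1:-1] - a[2:], 0)
    if endpoint_policy == "include":
        dif[0] = max(a[0] - a[1], 0.0)
        dif[-1] = max(a[-1] - a[-2], 0.0)
    elif endpoint_policy == "exclude":
        dif[0] = dif[-1] = np.inf
    else:
        raise ValueError(f"unknown endpoint_policy {endpoint_policy!r}")
    return dif


def day_threshold_kernel(
    a: np.ndarray, endpoint_policy: str = "exclude", fallback: str = "min"
) -> tuple[float, np.ndarray, bool]:
    """Single-day background threshold: mean energy over valley slots.

    Returns ``(value, valley_indices, fallback_used)``.  When no slot is a
    valley the configured fallback supplies the estimate (``'min'`` -> the
    day's minimum slot energy, the most conservative background value).
    """
    a = np.asarray(a, dtype=float)
    dif = prominence_kernel(a, endpoint_policy)
    valleys = np.flatnonzero(dif == 0)
    if valleys.size:
        return float(a[valleys].mean()), valleys, False
    if fallback != "min":
        raise ValueError(f"unknown fallback {fallback!r}")
    return float(a.min()), valleys, True


def pearson_kernel(x: np.ndarray, y: np.ndarray) -> tuple[float | None, bool]:
    """Single-pass Pearson correlation.

    Computed as ``(n*Sxy - Sx*Sy) / sqrt((n*Sxx - Sx^2)(n*Syy - Sy^2))``.
    Returns ``(cc, defined)``; ``defined`` is False when either vector has
    zero variance (the denominator vanishes), in which case ``cc`` is None.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    vx = n * sxx - sx * sx
    vy = n * syy - sy * sy
    # guard tiny negative round-off on genuinely constant vectors
    tol = 1e-12 * max(1.0, sxx, syy) * n
    if vx <= tol or vy <= tol:
        return None, False
    cc = (n * sxy - sx * sy) / math.sqrt(vx * vy)
    return float(np.clip(cc, -1.0, 1.0)), True


def half_mean_band(scores: np.ndarray) -> tuple[float, float, float]:
    """(low, norm, high): mean of all scores and of each sorted half."""
    scores = np.sort(np.asarray(scores, dtype=float))
    if scores.size % 2:
        raise ValueError("norm band needs an even number of scores")
    half = scores.size // 2
    return float(scores[:half].mean()), float(scores.mean()), float(scores[half:].mean())


# --------------------------------------------------------------------------
# estimators
# --------------------------------------------------------------------------


def _check_days(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2 or X.shape[1] != SLOTS_PER_DAY:
        raise ValueError(f"expected (n_days, {SLOTS_PER_DAY}) slot energies, got {X.shape}")
    if not np.all(np.isfinite(X)) or (X < 0).any():
        raise ValueError("slot energies must be finite and non-negative")
    return X


class ValleyThresholdBinarizer(TransformerMixin, BaseEstimator):
    """Binarize daily energy vectors against a learned background threshold.

    Parameters
    ----------
    endpoint_policy : {'exclude', 'include'}
        Whether the first/last slot of a day may count as a valley.
    fallback : {'min'}
        Threshold for a day with no valley slots.
    window : int or None
        Number of most recent history days averaged into the rolling
        threshold; ``None`` uses all fitted days.

    Attributes
    ----------
    threshold_ : float
        Rolling background threshold (Wh per slot).
    day_thresholds_ : ndarray of shape (n_days,)
        Per-day valley-mean thresholds of the fitted history.
    valley_indices_ : list of ndarray
        Valley slot indices per fitted day.
    fallback_used_ : ndarray of bool
        Whether the no-valley fallback was needed per fitted day.
    """

    def __init__(
        self,
        endpoint_policy: str = "exclude",
        fallback: str = "min",
        window: int | None = 14,
    ):
        self.endpoint_policy = endpoint_policy
        self.fallback = fallback
        self.window = window

    def fit(self, X, y=None):
        X = _check_days(X)
        if self.window is not None and X.shape[0] < self.window:
            raise ValueError(
                f"insufficient history: {X.shape[0]} day(s) available, "
                f"{self.window} required for the rolling threshold"
            )
        thresholds, valleys, fb = [], [], []
        for row in X:
            t, v, used = day_threshold_kernel(row, self.endpoint_policy, self.fallback)
            thresholds.append(t)
            valleys.append(v)
            fb.append(used)
        self.day_thresholds_ = np.asarray(thresholds)
        self.valley_indices_ = valleys
        self.fallback_used_ = np.asarray(fb)
        used = self.day_thresholds_ if self.window is None else self.day_thresholds_[-self.window:]
        self.threshold_ = float(used.mean())
        return self

    def transform(self, X) -> np.ndarray:
        """Binary usage matrix: 1 where slot energy strictly exceeds the threshold."""
        check_is_fitted(self, "threshold_")
        X = _check_days(X)
        return (X > self.threshold_).astype(np.int8)


class RoutineNormScorer(BaseEstimator):
    """Score daily binary usage against a learned multi-week norm.

    ``fit`` takes a ``(window, 96)`` binary usage history (default 28 days)
    and learns the per-slot usage-percentage profile and the low/norm/high
    active-score band.  ``predict`` maps days to activity-level labels;
    ``correlate`` returns the Pearson regularity of a day against the profile.
    """

    def __init__(self, window: int = 28):
        self.window = window

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2 or X.shape != (self.window, SLOTS_PER_DAY):
            raise ValueError(
                f"expected usage history of shape ({self.window}, {SLOTS_PER_DAY}), "
                f"got {X.shape}"
            )
        if not np.isin(X, (0, 1)).all():
            raise ValueError("usage history must be binary")
        self.daily_scores_ = 100.0 * X.mean(axis=1)
        self.profile_ = 100.0 * X.mean(axis=0)
        self.band_ = half_mean_band(self.daily_scores_)
        return self

    @staticmethod
    def active_score(flags: np.ndarray) -> float:
        """Percentage of active slots in a day (Eq-1-style 100 * mean)."""
        flags = np.asarray(flags)
        return 100.0 * float(flags.mean())

    def correlate(self, flags: np.ndarray) -> tuple[float | None, bool]:
        check_is_fitted(self, "profile_")
        return pearson_kernel(np.asarray(flags, dtype=float), self.profile_)

    def activity_level(self, score: float) -> str:
        check_is_fitted(self, "band_")
        low, norm, high = self.band_
        if score > high:
            return "high"
        if score >= norm:
            return "normal"
        if score >= low:
            return "low"
        return "abnormally_low"

    def predict(self, X) -> np.ndarray:
        """Activity-level label per day of a binary usage matrix."""
        X = np.asarray(X)
        if X.ndim == 1:
            X = X[None, :]
        return np.asarray([self.activity_level(self.active_score(row)) for row in X])


_REGULARITY_CUTS = ((0.7, "high"), (0.5, "normal"), (0.3, "low"))


def regularity_level_from_cc(cc: float | None, defined: bool = True) -> str:
    """Tier a regularity correlation: >=0.7 high, >=0.5 normal, >=0.3 low,
    else irregular; undefined correlations are not assessable."""
    if not defined or cc is None:
        return "not_assessable"
    for cut, label in _REGULARITY_CUTS:
        if cc >= cut:
            return label
    return "irregular"


class LifestyleMonitor(BaseEstimator):
    """End-to-end daily assessment from raw slot-energy history.

    ``fit`` consumes a ``(n_days, 96)`` energy history (most recent day
    last).  It needs at least ``norm_window + threshold_window`` days: every
    day of the norm window is binarized with its *own* rolling threshold,
    i.e. the mean of the valley thresholds of the ``threshold_window`` days
    preceding it, mirroring a deployment where a new threshold is generated
    every day.  ``assess`` (or ``predict``) then evaluates the next day.
    """

    def __init__(
        self,
        threshold_window: int = 14,
        norm_window: int = 28,
        endpoint_policy: str = "exclude",
        fallback: str = "min",
    ):
        self.threshold_window = threshold_window
        self.norm_window = norm_window
        self.endpoint_policy = endpoint_policy
        self.fallback = fallback

    def _required_history(self) -> int:
        return self.threshold_window + self.norm_window

    def fit(self, X, y=None):
        X = _check_days(X)
        need = self._required_history()
        if X.shape[0] < need:
            raise ValueError(
                f"insufficient history: have {X.shape[0]} day(s), need {need} "
                f"({self.norm_window} norm days, each preceded by "
                f"{self.threshold_window} threshold days)"
            )
        X = X[-need:]
        day_thr = np.asarray(
            [day_threshold_kernel(r, self.endpoint_policy, self.fallback)[0] for r in X]
        )
        w = self.threshold_window
        usage = np.empty((self.norm_window, SLOTS_PER_DAY), dtype=np.int8)
        for j in range(self.norm_window):
            i = w + j  # row index of this norm day in X
            rolling = day_thr[i - w : i].mean()
            usage[j] = X[i] > rolling
        self.usage_history_ = usage
        self.scorer_ = RoutineNormScorer(window=self.norm_window).fit(usage)
        self.band_ = self.scorer_.band_
        self.profile_ = self.scorer_.profile_
        self.threshold_ = float(day_thr[-w:].mean())
        return self

    def assess(self, x: np.ndarray) -> dict:
        """Assess one day of 96 slot energies against the fitted norms."""
        check_is_fitted(self, "threshold_")
        x = _check_days(x)[0]
        flags = (x > self.threshold_).astype(np.int8)
        score = self.scorer_.active_score(flags)
        cc, defined = self.scorer_.correlate(flags)
        act = self.scorer_.activity_level(score)
        reg = regularity_level_from_cc(cc, defined)
        overall, color = aggregate_status(act, reg)
        low, norm, high = self.band_
        return {
            "usage": flags,
            "active_score": score,
            "norm_band": (low, norm, high),
            "cc": cc,
            "cc_defined": defined,
            "activity_level": act,
            "regularity_level": reg,
            "overall_status": overall,
            "status_color": color,
            "threshold": self.threshold_,
        }

    def predict(self, X) -> np.ndarray:
        """Overall status label per day."""
        X = _check_days(X)
        return np.asarray([self.assess(row)["overall_status"] for row in X])


# severity ordering used for the overall verdict: best (0) .. worst (3)
_SEVERITY = {
    "high": 0,
    "normal": 1,
    "low": 2,
    "abnormally_low": 3,
    "irregular": 3,
    "poor": 3,
}
_OVERALL = {0: "high", 1: "normal", 2: "low", 3: "abnormal"}
LEVEL_COLORS = {
    "high": "green",
    "normal": "blue",
    "low": "yellow",
    "abnormal": "red",
    "abnormally_low": "red",
    "irregular": "red",
    "poor": "red",
    "not_assessable": "gray",
    "unknown": "gray",
}


def aggregate_status(*levels: str | None) -> tuple[str, str]:
    """Worst-severity aggregation over the available index levels.

    Indices that are missing or not assessable are ignored (shown gray on a
    dashboard); if none remain the overall status is unknown/gray.
    """
    sev = [
        _SEVERITY[lv]
        for lv in levels
        if lv is not None and lv != "not_assessable"
    ]
    if not sev:
        return "unknown", "gray"
    overall = _OVERALL[max(sev)]
    return overall, LEVEL_COLORS[overall]
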