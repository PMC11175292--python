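"""Binarization, active score, norm band/profile, and Pearson regularity."""

import datetime as dt

import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from meterwatch.estimators import half_mean_band, pearson_kernel
from meterwatch.scoring import (
    active_score,
    binarize,
    norm_band,
    pearson_cc,
    usage_norm,
)
from meterwatch.types import (
    SLOTS_PER_DAY,
    ActiveScore,
    NormProfile,
    ThresholdEstimate,
    UsageVector,
)

from conftest import D0, make_day


class TestBinarize:
    def test_strictly_greater_rule(self):
        day = make_day([2.0, 1.0, 1.5])
        flags = binarize(day, ThresholdEstimate(value=1.5)).flags
        assert flags[:3].tolist() == [1, 0, 0]  # equality -> inactive

    def test_all_below_and_all_equal_threshold(self):
        assert binarize(make_day([], pad=1.0), 2.0).flags.sum() == 0
        assert binarize(make_day([], pad=2.0), 2.0).flags.sum() == 0

    def test_accepts_plain_float_threshold(self):
        day = make_day([], pad=5.0)
        assert binarize(day, 4.9).flags.sum() == SLOTS_PER_DAY


class TestActiveScore:
    @pytest.mark.parametrize(
        "ones, expected, display",
        [
            (0, 0.0, "0.0"),
            (46, 100 * 46 / 96, "47.92"),  # dashboard-style 2-dp display
            (27, 28.125, "28.1"),  # 1-dp display
            (96, 100.0, "100.0"),
        ],
    )
    def test_exact_fraction_and_display_rounding(self, ones, expected, display):
        flags = np.zeros(SLOTS_PER_DAY, dtype=int)
        flags[:ones] = 1
        score = active_score(UsageVector(D0, flags)).score
        assert score == pytest.approx(expected, abs=1e-12)
        dp = len(display.split(".")[1])
        assert f"{round(score, dp):.{dp}f}" == display


class TestUsageNorm:
    def _history(self, flag_matrix):
        return [
            UsageVector(D0 + dt.timedelta(days=i), row)
            for i, row in enumerate(flag_matrix)
        ]

    def test_identical_vectors_scale_to_percent(self, rng):
        v = rng.integers(0, 2, SLOTS_PER_DAY)
        profile = usage_norm(self._history(np.tile(v, (28, 1))))
        assert np.array_equal(profile.slot_percentages, 100.0 * v)

    def test_partial_activity_counting(self):
        flags = np.zeros((28, SLOTS_PER_DAY), dtype=int)
        flags[:7, 10] = 1  # slot 10 active on 7 of 28 days
        profile = usage_norm(self._history(flags))
        assert profile.slot_percentages[10] == 25.0
        assert profile.slot_percentages[11] == 0.0

    def test_wrong_history_length_rejected(self):
        with pytest.raises(ValueError, match="27"):
            usage_norm(self._history(np.zeros((27, SLOTS_PER_DAY), dtype=int)))


class TestNormBand:
    def _scores(self, values):
        return [ActiveScore(D0 + dt.timedelta(days=i), v) for i, v in enumerate(values)]

    @pytest.mark.parametrize(
        "values, expected",
        [
            ([50.0] * 28, (50.0, 50.0, 50.0)),
            (list(range(1, 29)), (7.5, 14.5, 21.5)),
            ([0.0] * 14 + [100.0] * 14, (0.0, 50.0, 100.0)),
        ],
    )
    def test_half_mean_construction(self, values, expected):
        band = norm_band(self._scores(values))
        assert (band.low, band.norm, band.high) == pytest.approx(expected)

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError):
            norm_band(self._scores([1.0] * 27))

    @given(hnp.arrays(float, 28, elements=st.floats(0, 100)))
    def test_ordering_low_norm_high(self, values):
        low, norm, high = half_mean_band(values)
        assert low <= norm + 1e-12 and norm <= high + 1e-12


class TestPearson:
    def test_perfect_positive_and_negative(self):
        flags = np.zeros(SLOTS_PER_DAY, dtype=int)
        flags[10:40] = 1
        usage = UsageVector(D0, flags)
        same = NormProfile(D0, 100.0 * flags)
        opposite = NormProfile(D0, 100.0 * (1 - flags))
        assert pearson_cc(usage, same).cc == pytest.approx(1.0)
        assert pearson_cc(usage, opposite).cc == pytest.approx(-1.0)

    def test_hand_worked_four_slot_example(self):
        # n*Sxy - Sx*Sy = 100; denominator sqrt(20000)
        cc, defined = pearson_kernel([1, 0, 1, 0], [75, 25, 50, 50])
        assert defined
        assert cc == pytest.approx(100 / np.sqrt(20000), abs=1e-12)

    @pytest.mark.parametrize("fill", [0, 1])
    def test_constant_usage_is_undefined(self, fill):
        usage = UsageVector(D0, np.full(SLOTS_PER_DAY, fill))
        profile = NormProfile(D0, np.linspace(0, 100, SLOTS_PER_DAY))
        result = pearson_cc(usage, profile)
        assert not result.defined and result.cc is None

    @given(
        hnp.arrays(np.int8, SLOTS_PER_DAY, elements=st.integers(0, 1)),
        hnp.arrays(
            float,
            SLOTS_PER_DAY,
            # profiles are day-counts over a 28-day window, scaled to percent
            elements=st.integers(0, 28).map(lambda k: 100.0 * k / 28),
        ),
    )
    def test_matches_two_pass_oracle(self, flags, profile):
        cc, defined = pearson_kernel(flags.astype(float), profile)
        x, y = flags.astype(float), profile
        sx, sy = x.std(), y.std()
        if sx < 1e-9 or sy < 1e-9:
            assert not defined
        else:
            oracle = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
            assert defined
            assert cc == pytest.approx(np.clip(oracle, -1, 1), abs=1e-9)
            assert -1.0 <= cc <= 1.0

    @given(
        hnp.arrays(
            float,
            SLOTS_PER_DAY,
            elements=st.integers(0, 28).map(lambda k: 100.0 * k / 28),
        ),
        st.floats(0.1, 50),
        st.floats(-100, 100),
    )
    def test_invariant_under_positive_affine_profile_transform(self, y, a, b):
        x = np.zeros(SLOTS_PER_DAY)
        x[::3] = 1.0
        cc0, d0 = pearson_kernel(x, y)
        cc1, d1 = pearson_kernel(x, a * y + b)
        assert d0 == d1
        if d0:
            assert cc1 == pytest.approx(cc0, abs=1e-7)

    def test_agrees_with_scipy_reference(self, rng):
        for _ in range(20):
            x = rng.integers(0, 2, SLOTS_PER_DAY).astype(float)
            y = rng.uniform(0, 100, SLOTS_PER_DAY)
            if x.std() == 0:
                continue
            cc, _ = pearson_kernel(x, y)
            assert cc == pytest.approx(scipy.stats.pearsonr(x, y).statistic, abs=1e-12)
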