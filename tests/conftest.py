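import datetime as dt

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from meterwatch.types import SLOTS_PER_DAY, DayTrace

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

D0 = dt.date(2024, 1, 1)


def make_day(values, date=D0, pad=0.0):
    """Build a DayTrace from a short vector, padding the tail with ``pad``."""
    slots = np.full(SLOTS_PER_DAY, float(pad))
    values = np.asarray(values, dtype=float)
    slots[: values.size] = values
    return DayTrace(date, slots)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
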