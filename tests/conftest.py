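import datetime as dt

import numpy as np
import pandas as pd
import pytest

from hrsleep.ts_core import HRSeries, LabelSeries

T0 = pd.Timestamp("2024-01-01 15:00:00")


def make_hr(hr, epoch_length=60, t0=T0, subject="test"):
    """HRSeries from an array of bpm values (NaN = missing)."""
    hr = np.asarray(hr, dtype=float)
    times = pd.date_range(t0, periods=len(hr), freq=pd.Timedelta(seconds=epoch_length))
    return HRSeries(subject, epoch_length, times, hr)


def make_labels(labels, epoch_length=60, t0=T0):
    labels = np.asarray(labels, dtype=float)
    times = pd.date_range(t0, periods=len(labels), freq=pd.Timedelta(seconds=epoch_length))
    return LabelSeries(epoch_length, times, labels)


def two_level_day(sleep_start_min, sleep_end_min, wake=75.0, sleep=55.0,
                  epoch_length=60, n_min=1440):
    """One noise-free day: wake bpm everywhere except [start, end) minutes."""
    hr = np.full(n_min, wake)
    hr[sleep_start_min:sleep_end_min] = sleep
    return make_hr(hr, epoch_length=epoch_length)


@pytest.fixture
def day_2300_0700():
    """Noise-free day starting 15:00 with sleep 23:00-07:00 (epochs 480-960)."""
    return two_level_day(480, 960)
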