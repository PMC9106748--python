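"""Epoch-grid time series, ECDF quantiles, rolling statistics and day segmentation.

Heart-rate traces from wearables arrive as (timestamp, bpm) samples at a
device-specific rate.  Everything downstream operates on a uniform epoch
grid: this module defines the gridded containers (:class:`HRSeries`,
:class:`LabelSeries`), the resampling step that puts raw samples onto the
grid (:func:`regularize`), the sample-valued ECDF quantile used for
thresholding (:func:`ecdf_quantile`), centred rolling statistics
(:func:`rolling_median`, :func:`rolling_std`) and the segmentation of a
recording into 24-hour analysis days anchored at an arbitrary clock time
(:func:`segment_days`).

Timestamps are timezone-naive local clock time throughout; missing heart
rate is represented as NaN and is excluded from ECDFs and rolling windows
rather than imputed.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HRSeries",
    "LabelSeries",
    "DayWindow",
    "InsufficientDataError",
    "InputFormatError",
    "regularize",
    "ecdf_quantile",
    "rolling_median",
    "rolling_std",
    "segment_days",
    "window_to_epochs",
    "DAY_COVERAGE_FLOOR",
]

#: Days with a smaller fraction of non-missing epochs are flagged unusable:
#: an ECDF estimated over a sparse day is unstable.
DAY_COVERAGE_FLOOR = 0.5

WAKE = 0
SLEEP = 1


class InsufficientDataError(ValueError):
    """Raised when an operation has no (or too few) non-missing values."""


class InputFormatError(ValueError):
    """Raised when an input file or sample sequence cannot be parsed."""


def _check_grid(times: pd.DatetimeIndex, epoch_length: int) -> None:
    if len(times) > 1:
        deltas = np.diff(times.asi8)
        expected = int(epoch_length) * 1_000_000_000
        if not np.all(deltas == expected):
            raise ValueError(
                f"epoch grid is not uniform with spacing {epoch_length} s"
            )


@dataclass(frozen=True)
class HRSeries:
    """Uniformly gridded heart-rate trace for one subject.

    Parameters
    ----------
    subject_id : str
        Opaque identifier carried through to outputs.
    epoch_length : int
        Grid spacing in seconds (positive).
    times : pandas.DatetimeIndex
        Epoch start times; each epoch covers ``[t, t + epoch_length)``.
    hr : numpy.ndarray
        Beats per minute per epoch, NaN where missing.  Non-missing values
        must lie strictly inside (0, 300) bpm.
    """

    subject_id: str
    epoch_length: int
    times: pd.DatetimeIndex
    hr: np.ndarray

    def __post_init__(self) -> None:
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be a positive number of seconds")
        times = pd.DatetimeIndex(self.times)
        hr = np.asarray(self.hr, dtype=float)
        if len(times) != len(hr):
            raise ValueError("times and hr must have equal length")
        if len(times) == 0:
            raise InsufficientDataError("empty heart-rate series")
        _check_grid(times, self.epoch_length)
        finite = hr[np.isfinite(hr)]
        if finite.size and (np.any(finite <= 0) or np.any(finite >= 300)):
            raise ValueError("heart rate values must satisfy 0 < hr < 300 bpm")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "hr", hr)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.hr).sum())

    def slice(self, start: int, stop: int) -> "HRSeries":
        """Sub-series over epoch indices ``[start, stop)``."""
        return HRSeries(
            self.subject_id, self.epoch_length, self.times[start:stop], self.hr[start:stop]
        )

    def shift(self, delta: pd.Timedelta) -> "HRSeries":
        """Same trace with every timestamp translated by ``delta``."""
        return HRSeries(self.subject_id, self.epoch_length, self.times + delta, self.hr)


@dataclass(frozen=True)
class LabelSeries:
    """Binary sleep/wake labels on an epoch grid (0 wake, 1 sleep, NaN missing)."""

    epoch_length: int
    times: pd.DatetimeIndex
    labels: np.ndarray

    def __post_init__(self) -> None:
        times = pd.DatetimeIndex(self.times)
        labels = np.asarray(self.labels, dtype=float)
        if len(times) != len(labels):
            raise ValueError("times and labels must have equal length")
        _check_grid(times, self.epoch_length)
        finite = labels[np.isfinite(labels)]
        if not np.all(np.isin(finite, (0.0, 1.0))):
            raise ValueError("labels must be 0 (wake), 1 (sleep) or NaN (missing)")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.times)

    def slice(self, start: int, stop: int) -> "LabelSeries":
        return LabelSeries(self.epoch_length, self.times[start:stop], self.labels[start:stop])


@dataclass(frozen=True)
class DayWindow:
    """One 24-hour analysis window ``[anchor, anchor + 24 h)``.

    ``start_idx``/``end_idx`` index the parent series' epochs that fall in
    the span.  ``coverage`` is the fraction of the span's epoch slots that
    hold a non-missing heart rate; days under :data:`DAY_COVERAGE_FLOOR`
    are flagged unusable but still returned.
    """

    day_index: int
    anchor: pd.Timestamp
    start_idx: int
    end_idx: int
    coverage: float
    usable: bool

    @property
    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return self.anchor, self.anchor + pd.Timedelta(hours=24)


def regularize(
    raw_samples, epoch_length: int, max_gap: float = 5.0, subject_id: str = ""
) -> HRSeries:
    """Grid-align raw (timestamp, bpm) samples to a uniform epoch series.

    Samples falling inside one epoch are averaged.  Epochs containing no
    sample borrow the nearest sample's value if that sample lies within
    ``max_gap`` minutes of the epoch start, and are marked missing
    otherwise — nothing is interpolated across genuine gaps.

    Parameters
    ----------
    raw_samples : sequence of (timestamp, bpm) pairs or DataFrame
        ``bpm`` may be NaN/None for missing readings.
    epoch_length : int
        Target grid spacing in seconds.
    max_gap : float
        Largest tolerated distance, in minutes, between an empty epoch and
        the nearest raw sample before the epoch is declared missing.
    """
    if epoch_length <= 0:
        raise ValueError("epoch_length must be positive")
    if isinstance(raw_samples, pd.DataFrame):
        pairs = list(raw_samples.itertuples(index=False, name=None))
    else:
        pairs = list(raw_samples)
    if not pairs:
        raise InsufficientDataError("no raw samples to regularize")
    try:
        ts = pd.DatetimeIndex([pd.Timestamp(t) for t, _ in pairs])
    except (ValueError, TypeError) as exc:
        raise InputFormatError(f"unparseable timestamp in raw samples: {exc}") from exc
    vals = np.array([np.nan if v is None else float(v) for _, v in pairs])
    order = np.argsort(ts.asi8, kind="stable")
    ts, vals = ts[order], vals[order]

    span_s = (ts[-1] - ts[0]).total_seconds()
    if len(ts) > 1 and span_s < epoch_length and ts.nunique() == 1:
        raise InsufficientDataError("all samples share one timestamp within a single epoch")

    step = pd.Timedelta(seconds=epoch_length)
    t0 = ts[0].floor(step)
    grid = pd.date_range(t0, ts[-1].floor(step), freq=step)
    bins = (ts - t0) // step
    binned = pd.Series(vals, index=ts).groupby(bins).mean()
    hr = np.full(len(grid), np.nan)
    idx = binned.index.to_numpy()
    hr[idx] = binned.to_numpy()

    # fill epochs with no sample at all from the nearest observed sample;
    # epochs that held only NA readings stay missing
    empty = np.ones(len(grid), dtype=bool)
    empty[np.unique(np.asarray(bins))] = False
    if empty.any():
        obs = pd.Series(vals, index=ts).dropna()
        if len(obs):
            nearest = obs.reindex(
                grid[empty], method="nearest", tolerance=pd.Timedelta(minutes=max_gap)
            )
            hr[np.flatnonzero(empty)] = nearest.to_numpy()
    return HRSeries(subject_id, int(epoch_length), grid, hr)


def ecdf_quantile(values, q: float) -> float:
    """Sample-valued quantile from the empirical CDF.

    Returns the smallest sample value ``x`` such that the fraction of
    observations ``<= x`` reaches ``q`` — the left-continuous generalized
    inverse of the ECDF.  The result is always one of the observed values.

    Parameters
    ----------
    values : array-like
        Observations; NaNs are dropped.
    q : float
        Probability in (0, 1].
    """
    if not 0.0 < q <= 1.0:
        raise ValueError("q must lie in (0, 1]")
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise InsufficientDataError("cannot take a quantile of an empty sample")
    srt = np.sort(arr)
    n = srt.size
    # smallest k with k/n >= q; plain ceil(q*n) can land one off when q*n
    # is representable only approximately, so settle it by direct comparison
    k = min(max(int(np.ceil(q * n)), 1), n)
    while k > 1 and (k - 1) / n >= q:
        k -= 1
    while k < n and k / n < q:
        k += 1
    return float(srt[k - 1])


def window_to_epochs(window_minutes: float, epoch_length: int) -> int:
    """Convert a window stated in minutes to an odd, centred epoch count.

    The nearest epoch count is taken and bumped up to the next odd number
    so a centred window has a well-defined middle epoch regardless of the
    cohort's epoch length.
    """
    if window_minutes * 60 < epoch_length:
        raise ValueError("window shorter than one epoch")
    n = int(round(window_minutes * 60.0 / epoch_length))
    n = max(n, 1)
    if n % 2 == 0:
        n += 1
    return n


def rolling_median(values, window_minutes: float, epoch_length: int) -> np.ndarray:
    """Centred rolling median over a time window; NaNs excluded per window.

    Edges use shrunken windows (``min_periods=1``) so the output has the
    same length as the input.
    """
    n = window_to_epochs(window_minutes, epoch_length)
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(n, center=True, min_periods=1).median().to_numpy()


def rolling_std(values, window_minutes: float, epoch_length: int) -> np.ndarray:
    """Centred rolling standard deviation (sample, n-1 convention).

    Windows holding fewer than two non-missing values yield NaN.
    """
    n = window_to_epochs(window_minutes, epoch_length)
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(n, center=True, min_periods=2).std(ddof=1).to_numpy()


def segment_days(
    series: HRSeries,
    day_start: _dt.time = _dt.time(15, 0),
    coverage_floor: float = DAY_COVERAGE_FLOOR,
) -> list[DayWindow]:
    """Tile a recording into 24-hour windows anchored at ``day_start``.

    The first window is anchored at the last ``day_start`` clock time at or
    before the first epoch, so windows tile the whole recording and every
    epoch belongs to exactly one window.  Partial leading/trailing windows
    are returned with proportionally low coverage.
    """
    first = series.times[0]
    anchor0 = first.normalize() + pd.Timedelta(
        hours=day_start.hour, minutes=day_start.minute, seconds=day_start.second
    )
    if anchor0 > first:
        anchor0 -= pd.Timedelta(days=1)
    day = pd.Timedelta(hours=24)
    epochs_per_day = int(round(day.total_seconds() / series.epoch_length))

    windows: list[DayWindow] = []
    k = 0
    last = series.times[-1]
    while anchor0 + k * day <= last:
        lo, hi = anchor0 + k * day, anchor0 + (k + 1) * day
        start_idx = int(series.times.searchsorted(lo, side="left"))
        end_idx = int(series.times.searchsorted(hi, side="left"))
        if end_idx > start_idx:
            n_ok = int(np.isfinite(series.hr[start_idx:end_idx]).sum())
            cov = n_ok / epochs_per_day
            windows.append(
                DayWindow(
                    day_index=len(windows),
                    anchor=lo,
                    start_idx=start_idx,
                    end_idx=end_idx,
                    coverage=cov,
                    usable=cov >= coverage_floor,
                )
            )
        k += 1
    return windows
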