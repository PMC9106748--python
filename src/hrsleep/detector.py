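"""Heart-rate sleep-window detection.

The algorithm infers the main sleep window of each 24-hour day from heart
rate alone, exploiting the drop in resting heart rate when a person falls
asleep.  Per day it:

1. labels each epoch *sleep* when its heart rate is at or below the
   day-level ECDF quantile ``Q`` (:func:`label_by_quantile`);
2. smooths the binary labels with a short rolling median
   (:func:`smooth_labels`);
3. extracts sleep runs longer than ``L`` minutes and merges runs whose
   gaps are shorter than ``G`` minutes (:func:`extract_merge_blocks`);
4. drops candidate blocks preceded by too much wake in the recent past
   (:func:`eligible_blocks`), keeps the longest survivor as the main
   sleep window, and refines its onset/offset by searching for nearby
   high heart-rate-volatility epochs (:func:`refine_limits`);
5. labels naps (secondary blocks far from the main window) and brief
   awakenings (heart-rate excursions above a daytime quantile inside the
   window).

Because the threshold is a within-day quantile, nothing in the method
assumes an absolute clock time for sleep: the same trace shifted by eight
hours yields the same window shifted by eight hours, which is what makes
the approach applicable to shift workers and non-monophasic sleepers.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ts_core import (
    DAY_COVERAGE_FLOOR,
    DayWindow,
    HRSeries,
    LabelSeries,
    ecdf_quantile,
    rolling_median,
    rolling_std,
    segment_days,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AlgorithmParams",
    "Block",
    "SleepAnnotation",
    "FULL_DAY",
    "NIGHT_ONLY",
    "PRESETS",
    "label_by_quantile",
    "smooth_labels",
    "extract_merge_blocks",
    "eligible_blocks",
    "select_main_block",
    "refine_limits",
    "main_sleep_window",
    "detect_naps",
    "detect_awakenings",
    "annotate",
]


@dataclass(frozen=True)
class AlgorithmParams:
    """All tunables of the detector.

    Parameters
    ----------
    quantile : float
        Sleep quantile ``Q`` of the day-level heart-rate ECDF; epochs at or
        below the corresponding bpm value become candidate sleep.
    min_length : float
        ``L``, minutes — sleep runs must exceed this length to survive.
    merge_gap : float
        ``G``, minutes — kept runs closer than this are merged.
    awakening_quantile : float
        ``AV`` — daytime ECDF quantile above which an in-window epoch
        counts toward an awakening.
    smooth_window : float
        Rolling-median smoothing window, minutes.
    vol_window : float
        Rolling standard-deviation window for heart-rate volatility, minutes.
    vol_threshold : float
        Volatility at or above this many bpm marks a high-volatility epoch.
    search_before, search_after : float
        Minutes around each candidate limit searched for high-volatility
        epochs during onset/offset refinement.
    elig_lookback, elig_max_wake : float
        A block is ineligible when strictly more than ``elig_max_wake``
        minutes of wake fall in the ``elig_lookback`` minutes before it.
    day_start : datetime.time
        Clock-time anchor of the 24-hour analysis windows.
    nap_buffer : float
        Minutes either side of the main window inside which secondary
        blocks are never naps.
    nap_max_len : float
        Naps must be strictly shorter than this many minutes.
    awk_min_len, awk_merge_gap : float
        Awakenings must exceed ``awk_min_len`` minutes; awakenings split by
        less than ``awk_merge_gap`` minutes of sleep are merged.
    awk_max_len : float
        Merged excursions reaching this length are not awakenings.
    daytime_span : (datetime.time, datetime.time)
        Clock interval whose heart rates form the awakening-threshold ECDF.
    coverage_floor : float
        Minimum fraction of non-missing epochs for a day to be analysed.
    nap_require_short : bool
        Apply the ``nap_max_len`` cap (the buffer rule always applies).
    """

    quantile: float = 0.325
    min_length: float = 20.0
    merge_gap: float = 90.0
    awakening_quantile: float = 0.80
    smooth_window: float = 5.0
    vol_window: float = 10.0
    vol_threshold: float = 6.0
    search_before: float = 240.0
    search_after: float = 60.0
    elig_lookback: float = 240.0
    elig_max_wake: float = 90.0
    day_start: _dt.time = _dt.time(15, 0)
    nap_buffer: float = 180.0
    nap_max_len: float = 60.0
    awk_min_len: float = 5.0
    awk_merge_gap: float = 5.0
    awk_max_len: float = 60.0
    daytime_span: tuple[_dt.time, _dt.time] = (_dt.time(8, 0), _dt.time(22, 0))
    coverage_floor: float = DAY_COVERAGE_FLOOR
    nap_require_short: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.quantile < 1.0:
            raise ValueError("quantile must lie in (0, 1)")
        if not 0.0 < self.awakening_quantile < 1.0:
            raise ValueError("awakening_quantile must lie in (0, 1)")
        for name in (
            "min_length", "merge_gap", "smooth_window", "vol_window",
            "search_before", "search_after", "elig_lookback", "elig_max_wake",
            "nap_buffer", "nap_max_len", "awk_min_len", "awk_merge_gap",
            "awk_max_len",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: Shipped presets: optima of the exhaustive (Q, L, G) grid search for
#: full-day recordings and for night-only recordings.
FULL_DAY = AlgorithmParams(quantile=0.325, min_length=20.0, merge_gap=90.0)
NIGHT_ONLY = AlgorithmParams(quantile=0.80, min_length=20.0, merge_gap=420.0)
PRESETS = {"full_day": FULL_DAY, "night_only": NIGHT_ONLY}


@dataclass(frozen=True)
class Block:
    """Half-open epoch-index interval [start, end) in a given state."""

    start: int
    end: int
    state: str = "sleep"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("block end must exceed start")

    def duration_minutes(self, epoch_length: int) -> float:
        return (self.end - self.start) * epoch_length / 60.0


@dataclass
class SleepAnnotation:
    """Per-day result: main sleep window plus nap and awakening intervals.

    ``labels`` holds the final epoch labels for the day: 1 inside
    [onset, offset) except during awakenings, 0 elsewhere.  ``tst`` is the
    sleep-labelled time inside the window in minutes.  Days where no
    eligible block exists carry ``onset = offset = None`` and all-wake
    labels.
    """

    subject_id: str
    day: DayWindow
    onset: pd.Timestamp | None
    offset: pd.Timestamp | None
    tst: float
    naps: list[Block] = field(default_factory=list)
    awakenings: list[Block] = field(default_factory=list)
    labels: LabelSeries | None = None
    low_confidence: bool = False
    polyphasic: bool = False

    @property
    def detected(self) -> bool:
        return self.onset is not None


# ---------------------------------------------------------------------------
# pipeline stages


def label_by_quantile(day_hr: HRSeries, quantile: float) -> LabelSeries:
    """Label each epoch sleep when hr <= the day-level ECDF quantile.

    The threshold is sample-valued, so ties occur by construction; a tied
    epoch is labelled sleep (the threshold bpm itself counts as a dip).
    Missing heart rate yields a missing label.
    """
    thr = ecdf_quantile(day_hr.hr, quantile)
    labels = np.where(np.isfinite(day_hr.hr), (day_hr.hr <= thr).astype(float), np.nan)
    return LabelSeries(day_hr.epoch_length, day_hr.times, labels)


def smooth_labels(labels: LabelSeries, smooth_window: float = 5.0) -> LabelSeries:
    """Rolling-median smoothing of binary labels; output stays binary.

    An even split inside a window (possible near edges or missing data)
    resolves to sleep, matching the inclusive tie rule of the thresholding
    step.
    """
    med = rolling_median(labels.labels, smooth_window, labels.epoch_length)
    out = np.where(np.isfinite(med), (med >= 0.5).astype(float), np.nan)
    return LabelSeries(labels.epoch_length, labels.times, out)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def extract_merge_blocks(
    labels: LabelSeries, min_length: float, merge_gap: float
) -> list[Block]:
    """Keep sleep runs longer than ``min_length`` min, merge gaps < ``merge_gap`` min.

    Missing labels break runs (they count as neither sleep nor part of a
    gap's sleep).  Both comparisons are strict, matching the run-length
    rules: runs *longer than* L survive; kept runs whose gap is *smaller
    than* G coalesce into one block spanning both.
    """
    el = labels.epoch_length
    sleep_mask = labels.labels == 1.0
    kept = [
        Block(a, b)
        for a, b in _runs(sleep_mask)
        if (b - a) * el / 60.0 > min_length
    ]
    if not kept:
        return []
    merged = [kept[0]]
    for blk in kept[1:]:
        gap_min = (blk.start - merged[-1].end) * el / 60.0
        if gap_min < merge_gap:
            merged[-1] = Block(merged[-1].start, blk.end)
        else:
            merged.append(blk)
    return merged


def eligible_blocks(
    blocks: list[Block],
    labels: LabelSeries,
    elig_lookback: float = 240.0,
    elig_max_wake: float = 90.0,
) -> list[Block]:
    """Drop blocks preceded by too much wake in the recent past.

    A block is ineligible when the cumulative wake-labelled time in the
    ``elig_lookback`` minutes before its start strictly exceeds
    ``elig_max_wake`` minutes (missing epochs count as neither).  Blocks
    near the start of the recording are judged on the available prefix.
    """
    el = labels.epoch_length
    lb_epochs = int(round(elig_lookback * 60.0 / el))
    wake = labels.labels == 0.0
    out = []
    for blk in blocks:
        lo = max(0, blk.start - lb_epochs)
        wake_min = wake[lo: blk.start].sum() * el / 60.0
        if wake_min > elig_max_wake:
            logger.debug("block [%d,%d) dropped: %.0f min wake in lookback", blk.start, blk.end, wake_min)
            continue
        out.append(blk)
    return out


def select_main_block(
    blocks: list[Block], labels: LabelSeries, params: AlgorithmParams
) -> Block | None:
    """Pick the day's main sleep block: longest eligible, ties earliest.

    The eligibility rule (no more than ``elig_max_wake`` minutes of wake in
    the ``elig_lookback`` minutes before the block) discriminates between
    competing candidates: it demotes secondary sequences that sit isolated
    in a long stretch of wake.  Taken as an absolute filter it would also
    reject a perfectly ordinary night — the main sleep onset always follows
    an evening of wake — so when it eliminates every candidate, selection
    falls back to the full merged-block list.  With no blocks at all the
    day carries no sleep window.
    """
    if not blocks:
        return None
    elig = eligible_blocks(blocks, labels, params.elig_lookback, params.elig_max_wake)
    pool = elig if elig else blocks
    return max(pool, key=lambda b: (b.end - b.start, -b.start))


def refine_limits(
    day_hr: HRSeries,
    block: Block,
    params: AlgorithmParams,
    volatility: np.ndarray | None = None,
) -> tuple[int, int]:
    """Refine block limits toward nearby high heart-rate-volatility epochs.

    High volatility (rolling ``vol_window`` standard deviation at or above
    ``vol_threshold`` bpm) marks posture/activity transitions; the true
    fall-asleep and wake-up moments sit at the last such epoch before the
    candidate onset and the first such epoch after the candidate offset.
    Each limit searches ``search_before`` minutes before to
    ``search_after`` minutes after its candidate; if the forward search
    for the offset finds nothing, the last high-volatility epoch before it
    is used.  If no high-volatility epoch exists, or refinement would
    invert the window, the unrefined limits stand.

    Returns epoch indices ``(onset_idx, offset_idx)`` into ``day_hr``
    (half-open: offset is one past the last sleep epoch).
    """
    el = day_hr.epoch_length
    if volatility is None:
        volatility = rolling_std(day_hr.hr, params.vol_window, el)
    with np.errstate(invalid="ignore"):
        high = volatility >= params.vol_threshold
    n = len(day_hr)
    before = int(round(params.search_before * 60.0 / el))
    after = int(round(params.search_after * 60.0 / el))

    onset = block.start
    lo = max(0, block.start - before)
    hi = min(n, block.start + after + 1)
    cand = np.flatnonzero(high[lo:hi])
    if cand.size:
        onset = lo + int(cand[-1])

    offset = block.end
    lo = max(0, block.end - before)
    hi = min(n, block.end + after + 1)
    cand = np.flatnonzero(high[lo:hi]) + lo
    if cand.size:
        fwd = cand[cand >= block.end]
        offset = int(fwd[0]) + 1 if fwd.size else int(cand[-1]) + 1

    if onset >= offset:
        warnings.warn(
            "volatility refinement inverted the sleep window; keeping unrefined limits",
            stacklevel=2,
        )
        return block.start, block.end
    return onset, offset


def _final_labels(
    day_hr: HRSeries, onset_idx: int, offset_idx: int, awakenings: list[Block]
) -> LabelSeries:
    lab = np.zeros(len(day_hr))
    lab[onset_idx:offset_idx] = 1.0
    for awk in awakenings:
        lab[awk.start: awk.end] = 0.0
    return LabelSeries(day_hr.epoch_length, day_hr.times, lab)


def main_sleep_window(
    day_hr: HRSeries,
    params: AlgorithmParams = FULL_DAY,
    _smoothed: LabelSeries | None = None,
    _volatility: np.ndarray | None = None,
) -> tuple[SleepAnnotation, list[Block]]:
    """Run the per-day pipeline and select the main sleep window.

    Returns the annotation (without naps/awakenings, which need the block
    list and the day context) together with the merged candidate blocks.
    Among eligible blocks the longest wins; ties go to the earliest.  A
    day whose candidate block spans (almost) the entire day — as happens
    on a constant trace where every epoch ties with the threshold — is
    flagged low-confidence.
    """
    el = day_hr.epoch_length
    if _smoothed is None:
        raw = label_by_quantile(day_hr, params.quantile)
        _smoothed = smooth_labels(raw, params.smooth_window)
    blocks = extract_merge_blocks(_smoothed, params.min_length, params.merge_gap)
    main = select_main_block(blocks, _smoothed, params)

    day = DayWindow(0, day_hr.times[0], 0, len(day_hr), 1.0, True)
    if main is None:
        ann = SleepAnnotation(
            day_hr.subject_id, day, None, None, 0.0,
            labels=LabelSeries(el, day_hr.times, np.zeros(len(day_hr))),
        )
        return ann, blocks

    onset_idx, offset_idx = refine_limits(day_hr, main, params, volatility=_volatility)

    long_blocks = [b for b in blocks if b.duration_minutes(el) > 90.0]
    ann = SleepAnnotation(
        subject_id=day_hr.subject_id,
        day=day,
        onset=day_hr.times[onset_idx],
        offset=day_hr.times[offset_idx - 1] + pd.Timedelta(seconds=el),
        tst=(offset_idx - onset_idx) * el / 60.0,
        labels=_final_labels(day_hr, onset_idx, offset_idx, []),
        low_confidence=(offset_idx - onset_idx) >= 0.95 * len(day_hr),
        polyphasic=len(long_blocks) > 2,
    )
    ann._onset_idx = onset_idx  # epoch indices kept for nap/awakening stages
    ann._offset_idx = offset_idx
    return ann, blocks


def detect_naps(
    blocks: list[Block], main: SleepAnnotation, params: AlgorithmParams = FULL_DAY
) -> list[Block]:
    """Label secondary sleep blocks far from the main window as naps.

    A candidate block is a nap when it lies entirely outside the main
    window padded by ``nap_buffer`` minutes on both sides and (optionally)
    is strictly shorter than ``nap_max_len`` minutes.
    """
    if not main.detected or main.labels is None:
        return []
    el = main.labels.epoch_length
    buf = int(round(params.nap_buffer * 60.0 / el))
    lo = main._onset_idx - buf
    hi = main._offset_idx + buf
    naps = []
    for blk in blocks:
        if blk.end <= lo or blk.start >= hi:
            if params.nap_require_short and not (
                blk.duration_minutes(el) < params.nap_max_len
            ):
                continue
            naps.append(Block(blk.start, blk.end, state="nap"))
    return naps


def detect_awakenings(
    day_hr: HRSeries, main: SleepAnnotation, params: AlgorithmParams = FULL_DAY
) -> list[Block]:
    """Find brief heart-rate excursions above the daytime level inside the window.

    The threshold is the ``awakening_quantile`` of the ECDF of heart rates
    whose clock time falls in ``daytime_span``.  Inside [onset, offset),
    epochs with hr strictly above the threshold form candidate runs; runs
    longer than ``awk_min_len`` minutes are kept, runs separated by less
    than ``awk_merge_gap`` minutes of sleep are merged, and anything
    reaching ``awk_max_len`` minutes is deemed too long to be an awakening
    and discarded.
    """
    if not main.detected:
        return []
    el = day_hr.epoch_length
    t = day_hr.times
    lo_t, hi_t = params.daytime_span
    clock = t.hour * 3600 + t.minute * 60 + t.second
    lo_s = lo_t.hour * 3600 + lo_t.minute * 60 + lo_t.second
    hi_s = hi_t.hour * 3600 + hi_t.minute * 60 + hi_t.second
    day_mask = (clock >= lo_s) & (clock < hi_s)
    daytime_hr = day_hr.hr[day_mask]
    daytime_hr = daytime_hr[np.isfinite(daytime_hr)]
    if daytime_hr.size == 0:
        warnings.warn("no daytime heart rate available; skipping awakening detection", stacklevel=2)
        return []
    thr = ecdf_quantile(daytime_hr, params.awakening_quantile)

    a, b = main._onset_idx, main._offset_idx
    with np.errstate(invalid="ignore"):
        above = day_hr.hr > thr
    above &= np.isfinite(day_hr.hr)
    window_mask = np.zeros(len(day_hr), dtype=bool)
    window_mask[a:b] = True
    runs = [
        (s, e) for s, e in _runs(above & window_mask)
        if (e - s) * el / 60.0 > params.awk_min_len
    ]
    if not runs:
        return []
    merged = [runs[0]]
    for s, e in runs[1:]:
        if (s - merged[-1][1]) * el / 60.0 < params.awk_merge_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [
        Block(s, e, state="awakening")
        for s, e in merged
        if (e - s) * el / 60.0 < params.awk_max_len
    ]


def annotate(
    series: HRSeries, params: AlgorithmParams = FULL_DAY
) -> list[SleepAnnotation]:
    """Annotate every usable 24-hour day of a recording.

    Days are segmented at ``params.day_start``; days under the coverage
    floor are skipped (reported as undetected, low-confidence).  The
    result is a pure function of the inputs: identical series and
    parameters give identical annotations.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    out: list[SleepAnnotation] = []
    for day in segment_days(series, params.day_start, params.coverage_floor):
        sub = series.slice(day.start_idx, day.end_idx)
        if not day.usable:
            logger.info("day %d skipped: coverage %.2f below floor", day.day_index, day.coverage)
            ann = SleepAnnotation(series.subject_id, day, None, None, 0.0, low_confidence=True)
            out.append(ann)
            continue
        ann, blocks = main_sleep_window(sub, params)
        ann.day = day
        if ann.detected:
            ann.naps = detect_naps(blocks, ann, params)
            ann.awakenings = detect_awakenings(sub, ann, params)
            ann.labels = _final_labels(sub, ann._onset_idx, ann._offset_idx, ann.awakenings)
            awk_min = sum(b.duration_minutes(sub.epoch_length) for b in ann.awakenings)
            ann.tst -= awk_min
        out.append(ann)
    return out
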