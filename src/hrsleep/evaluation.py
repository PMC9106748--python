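"""Epoch-level agreement metrics, summary statistics and hyperparameter search.

The epoch-wise error measure is the misclassified fraction

    MSE = (1/n) * sum_i (pred_i - truth_i)^2

which for binary labels equals the Hamming distance divided by n: 0 for a
perfect reconstruction; the truth's sleep proportion when everything is
labelled wake; the sum of both sleep proportions when the two label sets
are disjoint.  Chance-corrected agreement is Cohen's kappa,
``(p_o - p_e) / (1 - p_e)`` on the 2x2 contingency table.  Window-level
agreement is reported as signed onset/offset/total-sleep-time differences
in minutes, summarised as mean +/- 95% CI, and compared between methods
with Bland-Altman limits of agreement and paired t-tests.

:func:`grid_search` tunes the detector's (Q, L, G) triple by exhaustive
evaluation of mean epoch MSE over a labelled dataset; the default lattice
is Q in [0.10, 0.95] step 0.025, L in [10, 120] step 5 minutes, G in
[30, 420] step 30 minutes.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import detector as _det
from .detector import AlgorithmParams, annotate, eligible_blocks, extract_merge_blocks, refine_limits
from .ts_core import HRSeries, InsufficientDataError, LabelSeries, rolling_std, segment_days

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationResult",
    "GridSearchResult",
    "epoch_mse",
    "cohens_kappa",
    "window_deltas",
    "summarize",
    "bland_altman",
    "paired_ttest",
    "align_grids",
    "evaluate_subject",
    "grid_search",
    "default_lattice",
]


@dataclass(frozen=True)
class EvaluationResult:
    """Agreement between one predicted and one ground-truth labelling."""

    mse: float
    kappa: float
    tst_diff: float | None
    onset_diff: float | None
    offset_diff: float | None
    n_epochs: int


@dataclass(frozen=True)
class GridSearchResult:
    """Exhaustive lattice evaluation: full table plus the argmin."""

    table: pd.DataFrame  # columns Q, L, G, mean_mse
    best: AlgorithmParams
    best_mse: float
    tie: bool


def _comparable(pred: LabelSeries, truth: LabelSeries) -> tuple[np.ndarray, np.ndarray]:
    if len(pred) != len(truth) or not pred.times.equals(truth.times):
        pred, truth = align_grids(pred, truth)
    ok = np.isfinite(pred.labels) & np.isfinite(truth.labels)
    if not ok.any():
        raise InsufficientDataError("no epochs where both labellings are defined")
    return pred.labels[ok], truth.labels[ok]


def epoch_mse(pred: LabelSeries, truth: LabelSeries) -> float:
    """Misclassified fraction over epochs where both labels are defined."""
    p, t = _comparable(pred, truth)
    return float(np.mean((p - t) ** 2))


def cohens_kappa(pred: LabelSeries, truth: LabelSeries) -> float:
    """Chance-corrected epoch agreement from the 2x2 contingency table.

    Degenerate tables: if both labellings are the same constant, agreement
    is perfect and kappa is 1; if both are constant but different, kappa
    is 0 (with a warning), since no chance correction is estimable.
    """
    p, t = _comparable(pred, truth)
    n = p.size
    po = float(np.mean(p == t))
    marg_p = np.array([np.mean(p == 0), np.mean(p == 1)])
    marg_t = np.array([np.mean(t == 0), np.mean(t == 1)])
    pe = float(marg_p @ marg_t)
    if np.unique(p).size == 1 and np.unique(t).size == 1:
        if po == 1.0:
            return 1.0
        warnings.warn("both labellings constant but different; kappa undefined, returning 0", stacklevel=2)
        return 0.0
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def window_deltas(
    pred_onset: pd.Timestamp,
    pred_offset: pd.Timestamp,
    truth_onset: pd.Timestamp,
    truth_offset: pd.Timestamp,
) -> tuple[float, float, float]:
    """Signed (tst_diff, onset_diff, offset_diff), predicted minus truth, minutes."""
    onset_diff = (pred_onset - truth_onset).total_seconds() / 60.0
    offset_diff = (pred_offset - truth_offset).total_seconds() / 60.0
    pred_tst = (pred_offset - pred_onset).total_seconds() / 60.0
    truth_tst = (truth_offset - truth_onset).total_seconds() / 60.0
    return pred_tst - truth_tst, onset_diff, offset_diff


def summarize(values, use_t: bool = False) -> tuple[float, float]:
    """Mean and 95% CI half-width (1.96 * sd / sqrt(n), or t quantile if use_t)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise InsufficientDataError("need at least two values to summarise")
    mult = stats.t.ppf(0.975, arr.size - 1) if use_t else 1.96
    return float(arr.mean()), float(mult * arr.std(ddof=1) / np.sqrt(arr.size))


def bland_altman(a, b) -> tuple[float, float, float, pd.DataFrame]:
    """Bland-Altman agreement between paired measurements.

    Returns (mean_diff, loa_low, loa_high, points) where points is a
    DataFrame with per-pair ``mean`` and ``diff`` (a - b) columns and the
    limits of agreement are mean_diff +/- 1.96 * sd(diff).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise InsufficientDataError("need >= 2 paired values of equal length")
    diff = a - b
    md = float(diff.mean())
    sd = float(diff.std(ddof=1))
    points = pd.DataFrame({"mean": (a + b) / 2.0, "diff": diff})
    return md, md - 1.96 * sd, md + 1.96 * sd, points


def paired_ttest(a, b) -> float:
    """Two-sided paired t-test p-value for mean(a - b) = 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise InsufficientDataError("need >= 2 paired values of equal length")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return 1.0
        warnings.warn("zero-variance differences with nonzero mean; p -> 0 limit", stacklevel=2)
        return 0.0
    return float(stats.ttest_rel(a, b).pvalue)


def align_grids(pred: LabelSeries, truth: LabelSeries) -> tuple[LabelSeries, LabelSeries]:
    """Put two labellings on a common grid: the coarser epoch, the overlap span.

    The finer series is down-sampled by majority label inside each coarse
    epoch, ties resolving to sleep; missing epochs are ignored in the vote
    and a coarse epoch with no finite votes stays missing.
    """
    coarse = max(pred.epoch_length, truth.epoch_length)

    def to_coarse(s: LabelSeries) -> LabelSeries:
        if s.epoch_length == coarse:
            return s
        step = pd.Timedelta(seconds=coarse)
        t0 = s.times[0].floor(step)
        bins = ((s.times - t0) // step).astype(int)
        df = pd.DataFrame({"bin": bins, "lab": s.labels}).dropna()
        votes = df.groupby("bin")["lab"].mean()
        n_bins = int(bins.max()) + 1
        lab = np.full(n_bins, np.nan)
        lab[votes.index.to_numpy()] = (votes.to_numpy() >= 0.5).astype(float)
        times = pd.date_range(t0, periods=n_bins, freq=step)
        return LabelSeries(coarse, times, lab)

    p, t = to_coarse(pred), to_coarse(truth)
    lo = max(p.times[0], t.times[0])
    hi = min(p.times[-1], t.times[-1])
    if lo > hi:
        raise ValueError("label series do not overlap in time")

    def clip(s: LabelSeries) -> LabelSeries:
        i = int(s.times.searchsorted(lo, side="left"))
        j = int(s.times.searchsorted(hi, side="right"))
        return s.slice(i, j)

    return clip(p), clip(t)


def evaluate_subject(
    pred_labels: LabelSeries,
    truth_labels: LabelSeries,
    pred_window: tuple[pd.Timestamp, pd.Timestamp] | None = None,
    truth_window: tuple[pd.Timestamp, pd.Timestamp] | None = None,
) -> EvaluationResult:
    """Epoch metrics for one prediction/truth pair, window deltas if given."""
    p, t = _comparable(pred_labels, truth_labels)
    mse = float(np.mean((p - t) ** 2))
    kappa = cohens_kappa(pred_labels, truth_labels)
    tst = onset = offset = None
    if pred_window is not None and truth_window is not None:
        tst, onset, offset = window_deltas(pred_window[0], pred_window[1],
                                           truth_window[0], truth_window[1])
    return EvaluationResult(mse, kappa, tst, onset, offset, int(p.size))


# ---------------------------------------------------------------------------
# grid search


def default_lattice() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The standard (Q, L, G) search lattice."""
    q = np.round(np.arange(0.10, 0.95 + 1e-9, 0.025), 3)
    l = np.arange(10, 120 + 1, 5, dtype=float)
    g = np.arange(30, 420 + 1, 30, dtype=float)
    return q, l, g


def _day_mse_for_params(day_hr, smoothed, vol, truth_day, params):
    """Detector tail (blocks -> window -> labels) for one day, one (L, G)."""
    blocks = extract_merge_blocks(smoothed, params.min_length, params.merge_gap)
    main = _det.select_main_block(blocks, smoothed, params)
    lab = np.zeros(len(day_hr))
    if main is not None:
        with warnings.catch_warnings():
            # extreme lattice corners routinely trip the inversion guard
            warnings.simplefilter("ignore", UserWarning)
            a, b = refine_limits(day_hr, main, params, volatility=vol)
        lab[a:b] = 1.0
    pred = LabelSeries(day_hr.epoch_length, day_hr.times, lab)
    return epoch_mse(pred, truth_day)


def grid_search(
    dataset,
    q_grid=None,
    l_grid=None,
    g_grid=None,
    base_params: AlgorithmParams = _det.FULL_DAY,
) -> GridSearchResult:
    """Exhaustive (Q, L, G) search minimising mean epoch MSE over a dataset.

    Parameters
    ----------
    dataset : list of (HRSeries, LabelSeries)
        Subjects with ground-truth labels on the same epoch grid.
    q_grid, l_grid, g_grid : array-like, optional
        Lattice axes; defaults to :func:`default_lattice`.
    base_params : AlgorithmParams
        Non-searched parameters (smoothing, volatility, eligibility ...).

    Mean MSE is computed per subject-day and averaged across all usable
    subject-days.  Ties on the minimum resolve to the smallest Q, then L,
    then G (the iteration order), and set the ``tie`` flag.

    Notes
    -----
    Per-day quantile labelling and smoothing depend only on Q and the
    volatility trace not at all, so both are computed once per (day, Q)
    and reused across the (L, G) sub-lattice; the search cost is dominated
    by cheap run-length operations.
    """
    if not dataset:
        raise ValueError("empty dataset")
    dq, dl, dg = default_lattice()
    q_grid = dq if q_grid is None else np.asarray(q_grid, dtype=float)
    l_grid = dl if l_grid is None else np.asarray(l_grid, dtype=float)
    g_grid = dg if g_grid is None else np.asarray(g_grid, dtype=float)

    # pre-slice days and precompute volatility (Q-independent)
    days = []
    for series, truth in dataset:
        for day in segment_days(series, base_params.day_start, base_params.coverage_floor):
            if not day.usable:
                continue
            sub = series.slice(day.start_idx, day.end_idx)
            tsub = truth.slice(day.start_idx, day.end_idx)
            vol = rolling_std(sub.hr, base_params.vol_window, sub.epoch_length)
            days.append((sub, tsub, vol))
    if not days:
        raise ValueError("dataset contains no usable days")

    rows = []
    for q in q_grid:
        pq = replace(base_params, quantile=float(q))
        smoothed = [
            _det.smooth_labels(_det.label_by_quantile(sub, pq.quantile), pq.smooth_window)
            for sub, _, _ in days
        ]
        for l in l_grid:
            for g in g_grid:
                p = replace(pq, min_length=float(l), merge_gap=float(g))
                mses = [
                    _day_mse_for_params(sub, sm, vol, tsub, p)
                    for (sub, tsub, vol), sm in zip(days, smoothed)
                ]
                rows.append((float(q), float(l), float(g), float(np.mean(mses))))

    table = pd.DataFrame(rows, columns=["Q", "L", "G", "mean_mse"])
    best_mse = table["mean_mse"].min()
    winners = table[table["mean_mse"] == best_mse]
    first = winners.iloc[0]
    best = replace(
        base_params, quantile=first["Q"], min_length=first["L"], merge_gap=first["G"]
    )
    return GridSearchResult(table, best, float(best_mse), tie=len(winners) > 1)
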