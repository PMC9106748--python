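"""Synthetic circadian heart-rate traces with known sleep structure.

The generator emulates the signal features the detector relies on: a
resting heart rate during sleep that sits below the waking level, a
24-hour sinusoidal modulation of waking heart rate, smooth ramps at
state transitions, excess heart-rate volatility around those transitions
(posture changes, settling into bed), additive noise (i.i.d. Gaussian or
AR(1)), optional naps, brief awakenings and missing epochs.  Ground-truth
labels and windows follow the configured schedule exactly, so detector
output can be scored without any real dataset.

All randomness flows from one integer seed: subject ``k`` of a cohort
draws from ``SeedSequence((seed, k))``, so any subject is reproducible in
isolation.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ts_core import HRSeries, LabelSeries

__all__ = ["SyntheticConfig", "simulate_subject", "scenario", "make_cohort", "SCENARIOS"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of one simulated subject.

    Times of day are ``datetime.time``; durations are minutes.  The
    recording starts at 15:00 on ``start_date`` and runs ``n_days`` * 24 h.

    Parameters
    ----------
    n_days : int
        Number of simulated 24-hour days.
    epoch_length : int
        Grid spacing, seconds.
    sleep_onset, sleep_offset : datetime.time
        Daily main sleep window (offset earlier than onset means the
        window wraps past midnight — the monophasic default 23:00-07:00).
    wake_hr_mean, sleep_hr_mean : float
        Mean waking / sleeping heart rate, bpm; sleep must be lower.
    circadian_amplitude : float
        Amplitude of a 24 h sinusoid added to waking heart rate, bpm.
    transition_width : float
        Minutes over which heart rate ramps smoothly at state changes.
    transition_volatility : float
        Extra noise s.d. (bpm) injected within +/- ``transition_width`` of
        each state change, giving the volatility-refinement stage signal.
    noise_sd : float
        Additive noise s.d., bpm.
    ar1 : float
        AR(1) coefficient of the noise; 0 gives i.i.d. Gaussian noise.
    naps : tuple of (datetime.time, float)
        Daily naps as (start clock time, duration minutes).
    awakenings : tuple of (float, float)
        Brief awakenings as (minutes after sleep onset, duration minutes).
    missing_rate : float
        Fraction of epochs whose heart rate is dropped.
    seed : int
        Seed for all randomness.
    """

    n_days: int = 7
    epoch_length: int = 60
    sleep_onset: _dt.time = _dt.time(23, 0)
    sleep_offset: _dt.time = _dt.time(7, 0)
    wake_hr_mean: float = 75.0
    sleep_hr_mean: float = 55.0
    circadian_amplitude: float = 5.0
    transition_width: float = 10.0
    transition_volatility: float = 8.0
    noise_sd: float = 3.0
    ar1: float = 0.0
    naps: tuple = ()
    awakenings: tuple = ()
    missing_rate: float = 0.0
    seed: int = 0
    start_date: _dt.date = _dt.date(2024, 1, 1)
    subject_id: str = "sim"

    def __post_init__(self) -> None:
        if self.sleep_hr_mean >= self.wake_hr_mean:
            raise ValueError("sleep_hr_mean must be below wake_hr_mean")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.ar1 < 1.0:
            raise ValueError("ar1 must lie in [0, 1)")


def _clock_to_offset_min(t: _dt.time, day_anchor_min: float = 15 * 60) -> float:
    """Minutes from the 15:00 day anchor to clock time ``t`` (within 24 h)."""
    m = t.hour * 60 + t.minute + t.second / 60.0
    return (m - day_anchor_min) % (24 * 60)


def _schedule_intervals(cfg: SyntheticConfig, n_epochs: int):
    """Ground-truth sleep intervals as half-open epoch-index pairs.

    Returns (main_windows, nap_intervals, awakening_intervals); awakenings
    are wake-within-sleep and are carved out of the labels.
    """
    epm = 60.0 / cfg.epoch_length  # epochs per minute
    per_day = int(round(24 * 60 * epm))
    mains, naps, awks = [], [], []
    on = _clock_to_offset_min(cfg.sleep_onset)
    off = _clock_to_offset_min(cfg.sleep_offset)
    if off <= on:
        off += 24 * 60
    for d in range(cfg.n_days):
        base = d * per_day
        a = base + int(round(on * epm))
        b = base + int(round(off * epm))
        mains.append((a, min(b, n_epochs)))
        for nap_t, dur in cfg.naps:
            s = base + int(round(_clock_to_offset_min(nap_t) * epm))
            e = s + int(round(dur * epm))
            if s < n_epochs:
                naps.append((s, min(e, n_epochs)))
        for after_min, dur in cfg.awakenings:
            s = a + int(round(after_min * epm))
            e = s + int(round(dur * epm))
            if s < min(b, n_epochs):
                awks.append((s, min(e, b, n_epochs)))
    return mains, naps, awks


def simulate_subject(
    cfg: SyntheticConfig,
) -> tuple[HRSeries, LabelSeries, list[tuple[pd.Timestamp, pd.Timestamp]]]:
    """Simulate one subject: heart rate, truth labels, truth main windows.

    Heart rate is the state mean (waking mean plus the circadian sinusoid
    when awake), passed through a moving-average ramp of width
    ``transition_width`` so transitions are smooth, plus noise; extra
    variance is injected around each state change.  Truth labels mark
    scheduled sleep (naps included, awakenings carved out) before any
    missingness is applied.  Deterministic given the config (which embeds
    the seed).
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n = cfg.n_days * int(round(24 * 3600 / cfg.epoch_length))
    t0 = pd.Timestamp(cfg.start_date) + pd.Timedelta(hours=15)
    times = pd.date_range(t0, periods=n, freq=pd.Timedelta(seconds=cfg.epoch_length))

    mains, naps, awks = _schedule_intervals(cfg, n)
    intervals = sorted(mains + naps)
    for (a1, b1), (a2, b2) in zip(intervals, intervals[1:]):
        if a2 < b1:
            raise ValueError("overlapping schedule entries")

    asleep = np.zeros(n, dtype=bool)
    for a, b in mains + naps:
        asleep[a:b] = True
    labels = asleep.astype(float)
    for a, b in awks:
        labels[a:b] = 0.0
    # during a brief awakening the person is awake: heart rate rises too
    state_wake = ~asleep.copy()
    for a, b in awks:
        state_wake[a:b] = True

    hours = (times - times[0]).total_seconds() / 3600.0
    # circadian trough in the early night hours; phase fixed, amplitude on wake
    circ = cfg.circadian_amplitude * np.sin(2 * np.pi * (hours + 15 - 9) / 24.0)
    level = np.where(state_wake, cfg.wake_hr_mean + circ, cfg.sleep_hr_mean)

    # smooth ramp at transitions: moving average of the level trace
    w = max(1, int(round(cfg.transition_width * 60 / cfg.epoch_length)))
    if w > 1:
        level = pd.Series(level).rolling(w, center=True, min_periods=1).mean().to_numpy()

    noise = rng.normal(0.0, 1.0, n)
    if cfg.ar1 > 0:
        ar = np.empty(n)
        ar[0] = noise[0]
        c = np.sqrt(1 - cfg.ar1**2)
        for i in range(1, n):
            ar[i] = cfg.ar1 * ar[i - 1] + c * noise[i]
        noise = ar
    hr = level + cfg.noise_sd * noise

    if cfg.transition_volatility > 0:
        half = max(1, int(round(cfg.transition_width * 60 / cfg.epoch_length)))
        edges = np.flatnonzero(np.diff(state_wake.astype(np.int8)) != 0) + 1
        burst = np.zeros(n, dtype=bool)
        for e in edges:
            burst[max(0, e - half): min(n, e + half)] = True
        hr[burst] += rng.normal(0.0, cfg.transition_volatility, int(burst.sum()))

    hr = np.clip(hr, 30.0, 220.0)
    if cfg.missing_rate > 0:
        drop = rng.random(n) < cfg.missing_rate
        hr[drop] = np.nan

    series = HRSeries(cfg.subject_id, cfg.epoch_length, times, hr)
    truth = LabelSeries(cfg.epoch_length, times, labels)
    windows = [
        (times[a], times[min(b, n) - 1] + pd.Timedelta(seconds=cfg.epoch_length))
        for a, b in mains
    ]
    return series, truth, windows


SCENARIOS = ("monophasic", "shift_worker", "biphasic_nap", "fragmented")


def scenario(name: str, seed: int = 0, n_days: int = 7) -> SyntheticConfig:
    """Documented presets covering the use cases the detector must handle.

    - ``monophasic``: one nightly window, 23:00-07:00.
    - ``shift_worker``: daytime sleep 09:00-17:00 (night-shift pattern).
    - ``biphasic_nap``: nightly window plus a 40 min mid-afternoon nap
      more than 4 h from the main window.
    - ``fragmented``: nightly window with three brief awakenings
      (6-15 min) spread through the night.
    """
    base = SyntheticConfig(n_days=n_days, seed=seed, subject_id=name)
    if name == "monophasic":
        return base
    if name == "shift_worker":
        return replace(base, sleep_onset=_dt.time(9, 0), sleep_offset=_dt.time(17, 0))
    if name == "biphasic_nap":
        return replace(base, naps=((_dt.time(15, 30), 40.0),))
    if name == "fragmented":
        return replace(base, awakenings=((90.0, 8.0), (210.0, 15.0), (330.0, 6.0)))
    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")


def make_cohort(
    n_subjects: int,
    base_config: SyntheticConfig,
    inter_subject_sd: float = 5.0,
    seed: int = 0,
) -> list[tuple[HRSeries, LabelSeries, list]]:
    """Simulate a cohort with between-subject resting-heart-rate variation.

    Each subject's wake and sleep means are drawn Normal(base, sd) around
    the base configuration — fitter individuals have lower resting heart
    rates and cohorts spread accordingly.  Subject ``k`` uses
    ``SeedSequence((seed, k))`` so results are reproducible per subject.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    out = []
    for k in range(n_subjects):
        ss = np.random.SeedSequence(entropy=(int(seed), k))
        rng = np.random.default_rng(ss)
        d_wake, d_sleep = rng.normal(0.0, inter_subject_sd, 2)
        sub_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        cfg = replace(
            base_config,
            wake_hr_mean=base_config.wake_hr_mean + d_wake,
            sleep_hr_mean=min(
                base_config.sleep_hr_mean + d_sleep,
                base_config.wake_hr_mean + d_wake - 5.0,
            ),
            seed=sub_seed,
            subject_id=f"{base_config.subject_id}-{k:03d}",
        )
        out.append(simulate_subject(cfg))
    return out
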