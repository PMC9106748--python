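import datetime as dt

import numpy as np
import pandas as pd
import pytest

import hrsleep.detector as det
from hrsleep.detector import (
    FULL_DAY,
    NIGHT_ONLY,
    AlgorithmParams,
    Block,
    annotate,
    detect_awakenings,
    detect_naps,
    eligible_blocks,
    extract_merge_blocks,
    label_by_quantile,
    main_sleep_window,
    refine_limits,
    select_main_block,
    smooth_labels,
)
from hrsleep.ts_core import ecdf_quantile

from conftest import make_hr, make_labels, two_level_day


def labels_from_runs(runs, n):
    """Build a 0/1 label array from sleep runs given as (start, end) minutes."""
    lab = np.zeros(n)
    for a, b in runs:
        lab[a:b] = 1.0
    return make_labels(lab)


class TestPresets:
    def test_shipped_optima(self):
        assert (FULL_DAY.quantile, FULL_DAY.min_length, FULL_DAY.merge_gap) == (0.325, 20.0, 90.0)
        assert (NIGHT_ONLY.quantile, NIGHT_ONLY.min_length, NIGHT_ONLY.merge_gap) == (0.80, 20.0, 420.0)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            AlgorithmParams(quantile=1.2)
        with pytest.raises(ValueError):
            AlgorithmParams(min_length=-3)


class TestLabelByQuantile:
    def test_constant_day_all_sleep(self):
        s = make_hr(np.full(1440, 70.0))
        lab = label_by_quantile(s, 0.325)
        assert (lab.labels == 1.0).all()  # tie rule: hr <= threshold -> sleep

    def test_two_level_trace_selects_low_level(self):
        # 8 h at 55, 16 h at 75; ECDF(55) = 1/3 >= 0.325
        s = two_level_day(480, 960)
        lab = label_by_quantile(s, 0.325)
        assert (lab.labels[480:960] == 1.0).all()
        assert (lab.labels[:480] == 0.0).all() and (lab.labels[960:] == 0.0).all()

    def test_high_quantile_sweeps_everything(self):
        s = two_level_day(480, 960)
        lab = label_by_quantile(s, 0.95)
        assert (lab.labels == 1.0).all()

    def test_missing_hr_gives_missing_label(self):
        hr = np.full(100, 70.0)
        hr[10] = np.nan
        lab = label_by_quantile(make_hr(hr), 0.5)
        assert np.isnan(lab.labels[10])

    def test_sleep_count_monotone_in_quantile(self):
        rng = np.random.default_rng(5)
        s = make_hr(rng.normal(70, 10, 1440).clip(40, 120))
        counts = [
            (label_by_quantile(s, q).labels == 1.0).sum()
            for q in np.arange(0.1, 0.96, 0.05)
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))


class TestSmoothLabels:
    def test_all_sleep_fixed_point(self):
        lab = make_labels(np.ones(100))
        assert (smooth_labels(lab, 5).labels == 1.0).all()

    def test_isolated_wake_epoch_removed(self):
        arr = np.ones(60)
        arr[30] = 0.0
        out = smooth_labels(make_labels(arr), 5)
        assert (out.labels == 1.0).all()

    def test_alternation_resolves_by_majority(self):
        arr = np.tile([0.0, 1.0], 30)
        out = smooth_labels(make_labels(arr), 5)
        assert set(np.unique(out.labels)) <= {0.0, 1.0}


class TestExtractMergeBlocks:
    def test_merge_when_gap_below_threshold(self):
        lab = labels_from_runs([(0, 50), (80, 125)], 200)
        blocks = extract_merge_blocks(lab, min_length=40, merge_gap=60)
        assert [(b.start, b.end) for b in blocks] == [(0, 125)]

    def test_no_merge_when_gap_too_wide(self):
        lab = labels_from_runs([(0, 50), (80, 125)], 200)
        blocks = extract_merge_blocks(lab, min_length=40, merge_gap=20)
        assert [(b.start, b.end) for b in blocks] == [(0, 50), (80, 125)]

    def test_short_runs_dropped(self):
        lab = labels_from_runs([(10, 20)], 100)
        assert extract_merge_blocks(lab, min_length=20, merge_gap=60) == []

    def test_length_rule_is_strict(self):
        # exactly L minutes does not survive; L+1 does
        lab = labels_from_runs([(10, 30)], 100)
        assert extract_merge_blocks(lab, 20, 60) == []
        lab = labels_from_runs([(10, 31)], 100)
        assert len(extract_merge_blocks(lab, 20, 60)) == 1

    def test_chain_merging(self):
        lab = labels_from_runs([(0, 30), (40, 70), (80, 110)], 200)
        blocks = extract_merge_blocks(lab, min_length=20, merge_gap=15)
        assert [(b.start, b.end) for b in blocks] == [(0, 110)]


class TestEligibility:
    def test_preceded_by_sleep_kept(self):
        # 4 h of sleep labels, then the block itself
        lab = labels_from_runs([(0, 240), (250, 500)], 600)
        blocks = [Block(250, 500)]
        assert eligible_blocks(blocks, lab) == blocks

    def test_cumulative_wake_over_limit_dropped(self):
        # 100 min wake scattered in the prior 240 min
        arr = np.ones(600)
        arr[150:250] = 0.0  # 100 min wake
        arr[250:500] = 1.0
        lab = make_labels(arr)
        assert eligible_blocks([Block(250, 500)], lab) == []

    def test_exactly_90_min_wake_is_kept(self):
        arr = np.ones(600)
        arr[160:250] = 0.0  # exactly 90 min
        lab = make_labels(arr)
        assert eligible_blocks([Block(250, 500)], lab) == [Block(250, 500)]
        arr[159] = 0.0  # 91 min
        assert eligible_blocks([Block(250, 500)], make_labels(arr)) == []

    def test_recording_prefix_shorter_than_lookback(self):
        lab = labels_from_runs([(30, 300)], 400)  # 30 min wake prefix only
        assert eligible_blocks([Block(30, 300)], lab) == [Block(30, 300)]

    def test_fallback_keeps_longest_when_all_ineligible(self):
        # an ordinary night: block preceded by a whole evening of wake
        lab = labels_from_runs([(480, 960)], 1440)
        assert eligible_blocks([Block(480, 960)], lab) == []
        chosen = select_main_block([Block(480, 960)], lab, FULL_DAY)
        assert chosen == Block(480, 960)

    def test_eligibility_discriminates_between_candidates(self):
        # continuation fragment (little prior wake) beats a longer isolated one
        arr = np.zeros(1440)
        arr[480:960] = 1.0    # main sleep (preceded by evening wake)
        arr[1100:1200] = 1.0  # isolated later block, preceded by 140 min wake
        lab = make_labels(arr)
        blocks = [Block(480, 960), Block(1100, 1200)]
        assert eligible_blocks(blocks, lab) == []
        assert select_main_block(blocks, lab, FULL_DAY) == Block(480, 960)


class TestSelection:
    def test_longest_wins_ties_earliest(self):
        lab = labels_from_runs([(0, 100), (200, 300), (400, 450)], 600)
        blocks = [Block(0, 100), Block(200, 300), Block(400, 450)]
        assert select_main_block(blocks, lab, FULL_DAY) == Block(0, 100)

    def test_empty_gives_none(self):
        lab = make_labels(np.zeros(100))
        assert select_main_block([], lab, FULL_DAY) is None


class TestRefineLimits:
    def test_constant_volatility_leaves_limits(self):
        s = two_level_day(480, 960)
        # two-level but flat within each state; transitions create volatility
        # at the state edges only -> supply an explicitly zero volatility
        a, b = refine_limits(s, Block(480, 960), FULL_DAY,
                             volatility=np.zeros(1440))
        assert (a, b) == (480, 960)

    def test_onset_moves_to_last_high_volatility_epoch(self):
        s = two_level_day(480, 960)
        vol = np.zeros(1440)
        vol[450] = 10.0  # spike 30 min before block start
        a, b = refine_limits(s, Block(480, 960), FULL_DAY, volatility=vol)
        assert a == 450 and b == 960

    def test_offset_prefers_first_spike_after_candidate(self):
        s = two_level_day(480, 960)
        vol = np.zeros(1440)
        vol[940] = 10.0  # before candidate offset
        vol[975] = 10.0  # after candidate offset -> preferred
        vol[1000] = 10.0
        a, b = refine_limits(s, Block(480, 960), FULL_DAY, volatility=vol)
        assert b == 976  # half-open: one past the spike epoch

    def test_offset_falls_back_to_last_before(self):
        s = two_level_day(480, 960)
        vol = np.zeros(1440)
        vol[940] = 10.0
        a, b = refine_limits(s, Block(480, 960), FULL_DAY, volatility=vol)
        assert b == 941

    def test_inversion_guard(self):
        s = two_level_day(480, 520)
        vol = np.full(1440, 10.0)  # high volatility everywhere
        with pytest.warns(UserWarning):
            a, b = refine_limits(s, Block(480, 520), FULL_DAY, volatility=vol)
        assert (a, b) == (480, 520)
        assert a < b


class TestMainWindow:
    def test_noise_free_day_recovers_schedule(self, day_2300_0700):
        ann, blocks = main_sleep_window(day_2300_0700, FULL_DAY)
        assert ann.detected
        onset_err = abs((ann.onset - pd.Timestamp("2024-01-01 23:00")).total_seconds()) / 60
        offset_err = abs((ann.offset - pd.Timestamp("2024-01-02 07:00")).total_seconds()) / 60
        assert onset_err <= FULL_DAY.smooth_window
        assert offset_err <= FULL_DAY.smooth_window

    def test_constant_day_flagged_low_confidence(self):
        s = make_hr(np.full(1440, 70.0))
        ann, _ = main_sleep_window(s, FULL_DAY)
        assert ann.detected and ann.low_confidence

    def test_no_block_reports_no_sleep(self):
        # dips alternate every 5 min: every sleep run dies under L = 20 min
        hr = np.where(np.arange(1440) // 5 % 2 == 0, 55.0, 75.0)
        ann, blocks = main_sleep_window(make_hr(hr), FULL_DAY)
        assert not ann.detected
        assert ann.onset is None and ann.tst == 0.0
        assert (ann.labels.labels == 0.0).all()


class TestNaps:
    def _main_ann(self, day):
        ann, blocks = main_sleep_window(day, FULL_DAY)
        return ann, blocks

    def test_far_short_block_is_nap(self, day_2300_0700):
        ann, _ = self._main_ann(day_2300_0700)
        # candidate 40 min block 5 h after offset (07:00 + 5 h = epoch 1260)
        cand = [Block(480, 960), Block(1260, 1300)]
        naps = detect_naps(cand, ann, FULL_DAY)
        assert [(b.start, b.end) for b in naps] == [(1260, 1300)]

    def test_block_inside_buffer_not_nap(self, day_2300_0700):
        ann, _ = self._main_ann(day_2300_0700)
        cand = [Block(480, 960), Block(1010, 1050)]  # ~1 h after offset
        assert detect_naps(cand, ann, FULL_DAY) == []

    def test_long_block_outside_buffer_not_nap(self, day_2300_0700):
        ann, _ = self._main_ann(day_2300_0700)
        cand = [Block(480, 960), Block(1260, 1330)]  # 70 min > nap_max_len
        assert detect_naps(cand, ann, FULL_DAY) == []
        loose = det.AlgorithmParams(nap_require_short=False)
        assert len(detect_naps(cand, ann, loose)) == 1

    def test_no_secondary_blocks(self, day_2300_0700):
        ann, blocks = self._main_ann(day_2300_0700)
        assert detect_naps(blocks, ann, FULL_DAY) == []


class TestAwakenings:
    def test_quiet_sleep_no_awakenings(self, day_2300_0700):
        ann, _ = main_sleep_window(day_2300_0700, FULL_DAY)
        assert detect_awakenings(day_2300_0700, ann, FULL_DAY) == []

    def test_excursion_detected_and_nested(self):
        hr = np.full(1440, 75.0)
        hr[480:960] = 55.0
        hr[700:710] = 90.0  # 10 min above the daytime threshold
        s = make_hr(hr)
        ann, _ = main_sleep_window(s, FULL_DAY)
        awks = detect_awakenings(s, ann, FULL_DAY)
        assert len(awks) == 1
        a = awks[0]
        assert 695 <= a.start <= 700 and 710 <= a.end <= 715
        assert ann._onset_idx <= a.start and a.end <= ann._offset_idx

    def test_nearby_excursions_merged(self):
        hr = np.full(1440, 75.0)
        hr[480:960] = 55.0
        hr[700:707] = 90.0
        hr[710:717] = 90.0  # 3 min gap < awk_merge_gap
        s = make_hr(hr)
        ann, _ = main_sleep_window(s, FULL_DAY)
        awks = detect_awakenings(s, ann, FULL_DAY)
        assert len(awks) == 1
        assert awks[0].start <= 700 and awks[0].end >= 717

    def test_five_minute_rule_is_strict(self):
        hr = np.full(1440, 75.0)
        hr[480:960] = 55.0
        hr[700:705] = 90.0  # exactly 5 min: not kept
        s = make_hr(hr)
        ann, _ = main_sleep_window(s, FULL_DAY)
        assert detect_awakenings(s, ann, FULL_DAY) == []

    def test_hour_long_excursion_not_an_awakening(self):
        hr = np.full(1440, 75.0)
        hr[480:960] = 55.0
        hr[700:760] = 90.0  # 60 min: too long
        s = make_hr(hr)
        ann, _ = main_sleep_window(s, FULL_DAY)
        assert detect_awakenings(s, ann, FULL_DAY) == []


class TestAnnotate:
    def test_multiday_trace_one_annotation_per_day(self):
        hr = np.tile(np.r_[np.full(480, 75.0), np.full(480, 55.0), np.full(480, 75.0)], 3)
        s = make_hr(hr)
        anns = annotate(s, FULL_DAY)
        assert len(anns) == 3
        assert all(a.detected for a in anns)

    def test_unusable_day_skipped(self):
        hr = np.tile(np.r_[np.full(480, 75.0), np.full(480, 55.0), np.full(480, 75.0)], 2)
        hr[:1100] = np.nan  # first day ~76% missing
        s = make_hr(hr)
        anns = annotate(s, FULL_DAY)
        assert not anns[0].detected and anns[1].detected

    def test_determinism(self):
        rng = np.random.default_rng(9)
        hr = np.tile(np.r_[np.full(480, 75.0), np.full(480, 55.0), np.full(480, 75.0)], 2)
        hr = hr + rng.normal(0, 3, hr.size)
        s = make_hr(hr.clip(35, 200))
        a1 = annotate(s, FULL_DAY)
        a2 = annotate(s, FULL_DAY)
        assert [(x.onset, x.offset, x.tst) for x in a1] == [(x.onset, x.offset, x.tst) for x in a2]

    def test_translation_equivariance(self):
        # shifting every timestamp (and the arbitrary day anchor with it)
        # shifts every detected limit exactly: no stage after segmentation
        # consults absolute clock time
        rng = np.random.default_rng(13)
        hr = np.tile(np.r_[np.full(480, 75.0), np.full(480, 55.0), np.full(480, 75.0)], 2)
        hr = (hr + rng.normal(0, 3, hr.size)).clip(35, 200)
        s = make_hr(hr)
        delta = pd.Timedelta(hours=8)
        shifted = s.shift(delta)
        p_shifted = dt.time(23, 0)  # 15:00 + 8 h
        a1 = annotate(s, FULL_DAY)
        a2 = annotate(shifted, det.AlgorithmParams(day_start=p_shifted))
        got = [(x.onset, x.offset) for x in a1 if x.detected]
        want = [(x.onset - delta, x.offset - delta) for x in a2 if x.detected]
        assert got == want

    def test_window_at_least_min_length(self):
        rng = np.random.default_rng(21)
        hr = np.tile(np.r_[np.full(480, 75.0), np.full(480, 55.0), np.full(480, 75.0)], 2)
        hr = (hr + rng.normal(0, 3, hr.size)).clip(35, 200)
        anns = annotate(make_hr(hr), FULL_DAY)
        for a in anns:
            if a.detected:
                assert (a.offset - a.onset).total_seconds() / 60 >= FULL_DAY.min_length
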