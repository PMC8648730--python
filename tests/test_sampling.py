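"""Sampling rules: leading seizures, preictal/interictal intervals, tiling.

The heavy artillery is the oracle-equivalence check: interval-algebra
labeling must agree with a per-second brute-force state machine on
randomized gappy timelines.
"""

import numpy as np
import pytest

from szbench import intervals as iv
from szbench.annotations_io import SeizureEvent
from szbench.sampling import (
    EmptyPreictalWarning,
    SamplingParams,
    build_sample_set,
    find_leading_seizures,
    interictal_intervals,
    preictal_intervals,
    segment_timeline,
    tile_windows,
)

from conftest import brute_force_leading, per_second_state, random_toy_layout, toy_timeline


def ev(pairs):
    return [SeizureEvent(i, a, b) for i, (a, b) in enumerate(pairs)]


class TestLeadingSeizures:
    def test_single_seizure_is_leading(self):
        (s,) = find_leading_seizures(ev([(100, 160)]), t_free=14400)
        assert s.seizure_id == 0

    def test_three_hour_gap_under_four_hour_t_is_not_leading(self):
        events = ev([(10000, 10060), (10060 + 3 * 3600, 10060 + 3 * 3600 + 60)])
        leading = find_leading_seizures(events, t_free=4 * 3600)
        assert [s.seizure_id for s in leading] == [0]

    def test_gap_measured_offset_to_onset(self):
        # onset gap is 4 h but offset-to-onset gap is only 3 h 59 min
        events = ev([(0, 60), (14400, 14460)])
        assert len(find_leading_seizures(events, t_free=14400)) == 1
        events = ev([(0, 60), (14460, 14520)])
        assert len(find_leading_seizures(events, t_free=14400)) == 2

    def test_unsorted_input_rejected(self):
        events = [SeizureEvent(0, 500, 560), SeizureEvent(1, 100, 160)]
        with pytest.raises(ValueError, match="sorted"):
            find_leading_seizures(events, t_free=1000)

    def test_matches_brute_force_on_random_event_lists(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            onsets = np.sort(rng.integers(0, 5000, size=20))
            events, t = [], 0
            for on in onsets:
                on = max(on, t + 1)
                off = on + int(rng.integers(5, 60))
                events.append((float(on), float(off)))
                t = off
            t_free = float(rng.integers(50, 2000))
            got = [s.seizure_id for s in find_leading_seizures(ev(events), t_free)]
            assert got == brute_force_leading(events, t_free)

    def test_monotone_in_t_free(self):
        rng = np.random.default_rng(3)
        events, t = [], 0
        for _ in range(15):
            on = t + int(rng.integers(10, 600))
            off = on + 20
            events.append((float(on), float(off)))
            t = off
        counts = [
            len(find_leading_seizures(ev(events), tf))
            for tf in [0, 100, 300, 600, 1200, 1e9]
        ]
        assert counts == sorted(counts, reverse=True)


class TestPreictalIntervals:
    params = SamplingParams()

    def test_nominal_interval_under_default_geometry(self):
        tl = toy_timeline([(0, 20000)], [(10000, 10060)])
        got = preictal_intervals(tl.seizures[0], self.params, tl)
        assert got == ((7900.0, 9700.0),)

    def test_coverage_gap_splits_interval(self):
        tl = toy_timeline([(0, 8000), (8500, 20000)], [(10000, 10060)])
        got = preictal_intervals(tl.seizures[0], self.params, tl)
        assert got == ((7900.0, 8000.0), (8500.0, 9700.0))

    def test_clipped_at_recording_start(self):
        tl = toy_timeline([(0, 5000)], [(1000, 1040)])
        got = preictal_intervals(tl.seizures[0], self.params, tl)
        assert got == ((0.0, 700.0),)

    def test_earlier_ictal_span_subtracted(self):
        params = SamplingParams(sph=10, sop=100)
        tl = toy_timeline([(0, 2000)], [(920, 940), (1000, 1040)])
        got = preictal_intervals(tl.seizures[1], params, tl)
        assert got == ((890.0, 920.0), (940.0, 990.0))

    def test_empty_result_is_valid_not_an_error(self):
        tl = toy_timeline([(9800, 20000)], [(10000, 10060)])
        assert preictal_intervals(tl.seizures[0], self.params, tl) == ()


class TestInterictalIntervals:
    def test_guard_carved_out_of_coverage(self):
        tl = toy_timeline([(0, 20000)], [(10000, 10060)])
        got = interictal_intervals(tl, SamplingParams())
        assert got == ((0.0, 2800.0), (17260.0, 20000.0))

    def test_no_seizures_gives_full_coverage(self):
        tl = toy_timeline([(0, 500), (700, 900)], [])
        assert interictal_intervals(tl, SamplingParams()) == ((0.0, 500.0), (700.0, 900.0))

    def test_guard_applies_to_follow_up_seizures_too(self):
        params = SamplingParams(t_free=10000, interictal_guard=100)
        tl = toy_timeline([(0, 5000)], [(1000, 1020), (1500, 1520)])
        got = interictal_intervals(tl, params)
        assert got == ((0.0, 900.0), (1120.0, 1400.0), (1620.0, 5000.0))

    def test_matches_per_second_scan_on_random_seizures(self):
        rng = np.random.default_rng(7)
        cov = [(0.0, 3000.0)]
        t, seizures = 0, []
        for _ in range(10):
            on = t + int(rng.integers(50, 250))
            off = on + int(rng.integers(5, 30))
            if off >= 3000:
                break
            seizures.append((float(on), float(off)))
            t = off
        params = SamplingParams(interictal_guard=60)
        tl = toy_timeline(cov, seizures)
        got = interictal_intervals(tl, params)
        for sec in range(3000):
            inside = iv.contains_point(got, sec)
            want = per_second_state(sec, cov, seizures, params) == "interictal"
            assert inside == want, sec

    def test_guard_monotonicity(self):
        tl = toy_timeline([(0, 50000)], [(10000, 10060), (30000, 30100)])
        lengths = [
            iv.total_length(interictal_intervals(tl, SamplingParams(interictal_guard=g)))
            for g in [0, 600, 3600, 7200, 20000]
        ]
        assert lengths == sorted(lengths, reverse=True)


class TestTileWindows:
    params = SamplingParams()  # 5 s windows, no overlap

    def test_thirty_minute_interval_yields_360(self):
        assert len(tile_windows([(0, 1800)], self.params)) == 360

    def test_interval_shorter_than_window_yields_none(self):
        assert tile_windows([(0, 4.5)], self.params) == []

    def test_partial_window_dropped(self):
        got = tile_windows([(100, 112)], self.params)
        assert got == [(100.0, 105.0), (105.0, 110.0)]

    def test_overlapping_windows_advance_by_step(self):
        p = SamplingParams(window_len=8, window_overlap=2)
        got = tile_windows([(0, 20)], p)
        assert got == [(0.0, 8.0), (6.0, 14.0), (12.0, 20.0)]

    def test_conservation(self):
        rng = np.random.default_rng(2)
        spans = []
        t = 0.0
        for _ in range(6):
            t += rng.uniform(0, 10)
            d = rng.uniform(0, 40)
            spans.append((t, t + d))
            t += d
        wins = tile_windows(spans, self.params)
        tiled = len(wins) * self.params.window_len
        assert tiled <= iv.total_length(spans)
        assert iv.total_length(spans) - tiled < len(spans) * self.params.window_len


class TestBuildSampleSet:
    def test_eligible_fixture_yields_three_full_preictal_segments(self, fixture_suite):
        timeline, _ = fixture_suite["eligible"]
        ss = build_sample_set(timeline, SamplingParams(), load_signal=False)
        assert ss.n_preictal == 3 * 360
        per_seizure = {}
        for w in ss.windows:
            if w.label == 1:
                per_seizure[w.source_seizure] = per_seizure.get(w.source_seizure, 0) + 1
        assert set(per_seizure.values()) == {360}

    def test_gap_inside_preictal_reduces_yield(self, fixture_suite):
        timeline, _ = fixture_suite["gapped"]
        ss = build_sample_set(timeline, SamplingParams(), load_signal=False)
        counts = {}
        for w in ss.windows:
            if w.label == 1:
                counts[w.source_seizure] = counts.get(w.source_seizure, 0) + 1
        assert sorted(counts.values()) == [240, 360, 360]

    def test_clustered_followup_contributes_no_positives(self, fixture_suite):
        timeline, _ = fixture_suite["clustered"]
        ss = build_sample_set(timeline, SamplingParams(), load_signal=False)
        leading_ids = {s.seizure_id for s in ss.leading_seizures}
        assert leading_ids == {0, 2, 3}  # seizure 1 is a follow-up
        assert {w.source_seizure for w in ss.windows if w.label == 1} <= leading_ids

    def test_missing_preictal_data_warns_not_raises(self):
        tl = toy_timeline([(9800, 30000)], [(10000, 10060)])
        with pytest.warns(EmptyPreictalWarning):
            ss = build_sample_set(tl, SamplingParams(), load_signal=False)
        assert ss.n_preictal == 0

    def test_wall_to_wall_seizures_leave_no_interictal(self):
        tl = toy_timeline([(0, 2000)], [(500, 600), (1500, 1600)])
        with pytest.warns(UserWarning, match="no interictal"):
            ss = build_sample_set(tl, SamplingParams(t_free=100), load_signal=False)
        assert ss.n_interictal == 0

    def test_window_labels_match_per_second_oracle_on_random_timelines(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(120):
            cov, seizures, params = random_toy_layout(rng)
            tl = toy_timeline(cov, seizures)
            import warnings as w

            with w.catch_warnings():
                w.simplefilter("ignore")
                ss = build_sample_set(tl, params, load_signal=False)
            state_of = {1: "preictal", 0: "interictal"}
            for win in ss.windows:
                want = state_of[win.label]
                # every covered integer second of the window must agree
                for sec in range(int(np.ceil(win.t_start)), int(win.t_end)):
                    got = per_second_state(sec, cov, seizures, params)
                    assert got == want, (win, sec, got, want)
                checked += 1
        assert checked > 100

    def test_preictal_interictal_and_ictal_windows_disjoint(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            cov, seizures, params = random_toy_layout(rng)
            tl = toy_timeline(cov, seizures)
            import warnings as w

            with w.catch_warnings():
                w.simplefilter("ignore")
                ss = build_sample_set(tl, params, load_signal=False)
            pre = iv.normalize((x.t_start, x.t_end) for x in ss.windows if x.label == 1)
            inter = iv.normalize((x.t_start, x.t_end) for x in ss.windows if x.label == 0)
            assert iv.intersect(pre, inter) == ()
            assert iv.intersect(pre, seizures) == ()
            assert iv.intersect(inter, seizures) == ()

    def test_manifest_and_bed_outputs(self, fixture_suite):
        timeline, _ = fixture_suite["eligible"]
        ss = build_sample_set(timeline, SamplingParams(), load_signal=False)
        lines = ss.manifest().splitlines()
        assert lines[0].split("\t") == [
            "window_id", "segment_id", "label", "t_start", "t_end", "source_seizure"
        ]
        assert len(lines) == len(ss.windows) + 1
        assert all(len(l.split("\t")) == 4 for l in ss.segments_bed().splitlines())
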