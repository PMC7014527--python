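from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chewevents import synthetic
from chewevents.bottom_up import (
    BottomUpParams,
    SegmentParams,
    detect_eating_bottom_up,
    detect_segments,
    eliminate_gaps,
    fuse_sources,
    onset_frequency,
)
from chewevents.cycles import CycleDetectParams, OnsetList
from chewevents.signal_io import Interval, SegmentList, ValidationError

import oracles

FS = 256.0


def onset_list(times_s):
    return OnsetList(np.round(np.asarray(times_s) * FS).astype(np.int64))


class TestOnsetFrequency:
    def test_single_onset_counts_itself(self):
        assert onset_frequency(onset_list([12.0]), 0, 5.0, FS) == 1

    def test_closed_window_edge(self):
        # onsets every 0.5 s; closed window [t, t+5] includes both edges
        C = onset_list(np.arange(40) * 0.5)
        assert onset_frequency(C, 10, 5.0, FS) == 11

    def test_out_of_range_rejected(self):
        with pytest.raises(IndexError):
            onset_frequency(onset_list([1.0]), 1, 5.0, FS)

    def test_matches_bruteforce(self, rng):
        for _ in range(30):
            onsets = oracles.random_onset_list(rng)
            if onsets.size == 0:
                continue
            C = OnsetList(onsets)
            w0s = int(rng.integers(50, 2000))
            j = int(rng.integers(0, onsets.size))
            assert onset_frequency(C, j, w0s / FS, FS) == oracles.count_in_window(
                onsets, j, int(round(w0s / FS * FS))
            )


class TestDetectSegments:
    def test_empty_in_empty_out(self):
        got = detect_segments(OnsetList(np.empty(0)), SegmentParams(5.0, 2), FS)
        assert len(got) == 0

    def test_isolated_onset_makes_no_segment(self):
        got = detect_segments(onset_list([10.0]), SegmentParams(5.0, 2), FS)
        assert len(got) == 0

    def test_dense_run_matches_declarative_oracle(self):
        """60 onsets at 0.5 s spacing from t=10 s: one segment starting at
        10 s, ending where the brute-force predicate scan says."""
        C = onset_list(10.0 + np.arange(60) * 0.5)
        p = SegmentParams(w0=5.0, theta_0=4)
        got = detect_segments(C, p, FS)
        expect = oracles.segments_bruteforce(C.onsets, int(5.0 * FS), 4)
        assert len(got) == len(expect) == 1
        s, e = expect[0]
        assert got.segments[0].start == pytest.approx(10.0, abs=1 / FS)
        assert got.segments[0].start == C.onsets[s] / FS
        assert got.segments[0].end == C.onsets[e] / FS

    def test_boundaries_are_onsets_and_contain_theta0(self, rng):
        for _ in range(50):
            onsets = oracles.random_onset_list(rng)
            if onsets.size == 0:
                continue
            C = OnsetList(onsets)
            p = SegmentParams(
                w0=float(rng.integers(1, 8)), theta_0=int(rng.integers(2, 6))
            )
            got = detect_segments(C, p, FS)
            times = set(np.round(onsets / FS, 9))
            for seg in got:
                assert round(seg.start, 9) in times
                assert round(seg.end, 9) in times
                inside = np.sum(
                    (onsets / FS >= seg.start) & (onsets / FS <= seg.end)
                )
                assert inside >= p.theta_0

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10**6),
        w0s=st.sampled_from([100, 400, 1300]),
        theta_0=st.integers(2, 6),
    )
    def test_bruteforce_equivalence_property(self, seed, w0s, theta_0):
        onsets = oracles.random_onset_list(np.random.default_rng(seed))
        if onsets.size == 0:
            return
        got = detect_segments(OnsetList(onsets), SegmentParams(w0s / FS, theta_0), FS)
        expect = oracles.segments_bruteforce(onsets, w0s, theta_0)
        assert [(s.start, s.end) for s in got] == [
            (onsets[a] / FS, onsets[b] / FS) for a, b in expect
        ]

    def test_trailing_open_segment_closes_at_last_onset(self):
        # dense run right up to the end of the list
        C = onset_list(np.arange(20) * 0.5)
        got = detect_segments(C, SegmentParams(w0=5.0, theta_0=4), FS)
        assert len(got) == 1
        assert got.segments[0].end == C.onsets[-1] / FS

    def test_raising_theta0_never_adds_covered_time_on_chewing_like_input(
        self, rng
    ):
        """On quasi-periodic onset runs separated by silence, a stricter
        onset-count threshold can only shrink the covered time."""
        for _ in range(15):
            onsets = oracles.bursty_onset_list(rng)
            C = OnsetList(onsets)
            covered = [
                detect_segments(C, SegmentParams(5.0, th), FS).total_duration
                for th in (2, 3, 4, 5, 6)
            ]
            assert all(a >= b - 1e-9 for a, b in zip(covered, covered[1:]))


class TestFusion:
    def test_union_of_identical_lists_is_identity(self):
        sl = SegmentList((Interval(0, 10), Interval(20, 30)), "a")
        fused = fuse_sources([sl, SegmentList(sl.segments, "b")])
        assert tuple(fused) == sl.segments

    def test_disjoint_preserved(self):
        got = fuse_sources(
            [
                SegmentList((Interval(0, 10),), "a"),
                SegmentList((Interval(20, 30),), "b"),
            ]
        )
        assert tuple(got) == (Interval(0, 10), Interval(20, 30))

    def test_overlap_coalesced(self):
        got = fuse_sources(
            [
                SegmentList((Interval(0, 10),), "a"),
                SegmentList((Interval(5, 15),), "b"),
            ]
        )
        assert tuple(got) == (Interval(0, 15),)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_union_laws(self, seed):
        rng = np.random.default_rng(seed)
        a = SegmentList(oracles.random_interval_list(rng), "a")
        b = SegmentList(oracles.random_interval_list(rng), "b")
        c = SegmentList(oracles.random_interval_list(rng), "c")
        ab = fuse_sources([a, b])
        ba = fuse_sources([b, a])
        assert tuple(ab) == tuple(ba)  # commutative
        assert tuple(fuse_sources([a, a])) == tuple(fuse_sources([a]))  # idempotent
        left = fuse_sources([fuse_sources([a, b]), c])
        right = fuse_sources([a, fuse_sources([b, c])])
        assert tuple(left) == tuple(right)  # associative


class TestGapElimination:
    def test_short_gap_merged(self):
        got = eliminate_gaps(
            SegmentList((Interval(0, 60), Interval(120, 180)), "x"), 300.0
        )
        assert tuple(got) == (Interval(0, 180),)

    def test_long_gap_kept(self):
        segs = (Interval(0, 60), Interval(500, 560))
        got = eliminate_gaps(SegmentList(segs, "x"), 300.0)
        assert tuple(got) == segs

    def test_single_segment_unchanged(self):
        segs = (Interval(5, 25),)
        assert tuple(eliminate_gaps(SegmentList(segs, "x"), 300.0)) == segs

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), t_gap=st.sampled_from([30.0, 300.0]))
    def test_idempotent_and_coverage_preserving(self, seed, t_gap):
        rng = np.random.default_rng(seed)
        sl = SegmentList(oracles.random_interval_list(rng), "x")
        once = eliminate_gaps(sl, t_gap)
        twice = eliminate_gaps(once, t_gap)
        assert tuple(once) == tuple(twice)
        assert once.total_duration >= sl.total_duration - 1e-9
        gaps = [
            b.start - a.end for a, b in zip(once.segments, once.segments[1:])
        ]
        assert all(g >= t_gap for g in gaps)


class TestEndToEnd:
    def _params(self, theta_c):
        return BottomUpParams(
            segment=SegmentParams(w0=7.0, theta_0=6),
            cycle=CycleDetectParams(theta_c=theta_c),
        )

    def test_pure_noise_yields_no_events(self):
        cfg = replace(
            synthetic.SynthConfig(),
            duration=900.0,
            n_events=0,
            grind_rate_per_hour=0.0,
            seed=4,
        )
        rec, _ = synthetic.generate_recording(cfg)
        # baseline threshold from the whole (non-eating) recording
        from chewevents.preprocessing import preprocess
        from chewevents.cycles import estimate_burst_threshold

        xp = preprocess(rec)
        theta_c = estimate_burst_threshold(xp.values.ravel())
        got = detect_eating_bottom_up(rec, self._params(theta_c))
        assert len(got) == 0

    def test_single_event_recovered(self, short_recording, short_preprocessed):
        _, rec, gt = short_recording
        _, theta_c, _ = short_preprocessed
        got = detect_eating_bottom_up(rec, self._params(theta_c))
        assert len(got) == 1
        ev = gt.reference.events[0]
        assert got.segments[0].overlap(ev) > 0.9 * ev.duration

    def test_conversation_pause_bridged(self):
        """A 2-minute chew-free pause inside a meal (shorter than t_gap)
        yields one merged eating event."""
        cfg = replace(
            synthetic.SynthConfig(),
            duration=1500.0,
            n_events=1,
            event_duration_range=(600.0, 600.0),
            min_event_gap=120.0,
            pause_prob=1.0,
            pause_duration_range=(120.0, 120.0),
            seed=9,
        )
        rec, gt = synthetic.generate_recording(cfg)
        assert gt.pauses and gt.pauses[0].duration == pytest.approx(120.0)
        from chewevents.preprocessing import preprocess
        from chewevents.cycles import baseline_samples, estimate_burst_threshold

        xp = preprocess(rec)
        theta_c = estimate_burst_threshold(baseline_samples(xp, gt.reference))
        got = detect_eating_bottom_up(rec, self._params(theta_c))
        assert len(got) == 1
        ev = gt.reference.events[0]
        assert got.segments[0].start < gt.pauses[0].start
        assert got.segments[0].end > gt.pauses[0].end
        assert got.segments[0].overlap(ev) > 0.9 * (
            ev.duration - gt.pauses[0].duration
        )


def test_segment_params_validation():
    with pytest.raises(ValidationError):
        SegmentParams(w0=-1.0, theta_0=2)
    with pytest.raises(ValidationError):
        SegmentParams(w0=5.0, theta_0=1)
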