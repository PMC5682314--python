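"""Tapping-event detection: envelopes, template response, segmentation, FDER."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmgtap import (
    DetectorSpec,
    Event,
    EventTable,
    Recording,
    binarize_and_segment,
    compute_fder,
    detect_events,
    dtf_response,
    dtf_threshold,
    extract_segments,
    rms_envelope,
    rms_threshold,
)
from mmgtap.detect import DIFFERENCE_TEMPLATE


def naive_rms(x, w):
    windows = np.lib.stride_tricks.sliding_window_view(x, w)[: len(x) - w]
    return np.sqrt((windows**2).sum(axis=1) / w)


def naive_dtf(x):
    """Direct convolution sum over all lags, 'same' alignment at the zero tap."""
    n = len(x)
    out = np.zeros(n)
    for t in range(n):
        acc = 0.0
        for j, d in enumerate(DIFFERENCE_TEMPLATE):
            k = t + 8 - j
            if 0 <= k < n:
                acc += d * x[k]
        out[t] = acc
    return out


class TestRmsEnvelope:
    def test_constant_signal_gives_exact_rms(self):
        g = rms_envelope(np.full(1000, 3.0), 400)
        assert g.shape == (600,)
        np.testing.assert_allclose(g, 3.0, rtol=1e-12)

    def test_alternating_unit_signal(self):
        x = np.tile([1.0, -1.0], 500)
        np.testing.assert_allclose(rms_envelope(x, 64), 1.0, rtol=1e-12)

    def test_matches_naive_window_evaluation(self, rng):
        x = rng.standard_normal(1000)
        np.testing.assert_allclose(
            rms_envelope(x, 400), naive_rms(x, 400), rtol=1e-9
        )

    def test_window_too_long(self):
        with pytest.raises(ValueError):
            rms_envelope(np.zeros(100), 100)


class TestThresholds:
    def test_constant_envelope(self):
        assert rms_threshold(np.full(100, 2.0), (0, 100), 2.15) == pytest.approx(4.3)

    def test_small_arithmetic(self):
        assert rms_threshold(np.array([1.0, 2.0, 3.0]), (0, 3), 2.0) == pytest.approx(
            4.0
        )

    def test_random_envelope_matches_naive_mean(self, rng):
        g = rng.uniform(0, 5, 500)
        th = rms_threshold(g, (50, 300), 2.15)
        assert th == pytest.approx(2.15 * g[50:300].mean(), rel=1e-12)

    def test_zero_baseline_warns(self, caplog):
        with caplog.at_level("WARNING"):
            th = dtf_threshold(np.zeros(100), (0, 100), 2.0)
        assert th == 0.0
        assert any("degenerate" in r.message for r in caplog.records)

    def test_baseline_outside_range(self):
        with pytest.raises(ValueError):
            rms_threshold(np.zeros(10), (5, 20), 2.0)


class TestDtfResponse:
    def test_constant_signal_cancels(self):
        g = dtf_response(np.full(200, 7.0), rectify=False)
        np.testing.assert_allclose(g[8:-8], 0.0, atol=1e-12)

    def test_unit_step_extreme_is_eight(self):
        x = np.zeros(200)
        x[100:] = 1.0
        g = dtf_response(x)
        oracle = np.abs(naive_dtf(x))
        np.testing.assert_allclose(g, oracle, atol=1e-12)
        assert g.max() == 8.0

    def test_linear_ramp_interior_magnitude(self):
        x = np.arange(300, dtype=float)
        g = dtf_response(x)
        oracle = np.abs(naive_dtf(x))
        np.testing.assert_allclose(g, oracle, atol=1e-9)
        # signed half-sums give sum(2k, k=1..8) = 72 on a unit-slope ramp
        np.testing.assert_allclose(g[20:280], 72.0, atol=1e-9)

    def test_random_signal_matches_direct_convolution(self, rng):
        x = rng.standard_normal(400)
        np.testing.assert_allclose(
            dtf_response(x, rectify=False), naive_dtf(x), rtol=1e-9, atol=1e-12
        )

    def test_too_short_signal(self):
        with pytest.raises(ValueError):
            dtf_response(np.zeros(16))

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(shift=st.integers(1, 40), seed=st.integers(0, 50))
    def test_shift_equivariance(self, shift, seed):
        g = np.random.default_rng(seed)
        x = g.standard_normal(300)
        shifted = np.roll(x, shift)
        a = dtf_response(x, rectify=False)
        b = dtf_response(shifted, rectify=False)
        # compare away from edges and the roll seam
        np.testing.assert_allclose(
            np.roll(a, shift)[shift + 20 : -20], b[shift + 20 : -20], rtol=1e-9
        )


def brute_force_segments(z, min_dur, gap):
    """Independent run scan: merge gaps < gap, then drop runs < min_dur."""
    runs = []
    start = None
    for i, v in enumerate(list(z) + [0]):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged if e - s >= min_dur]


class TestBinarizeAndSegment:
    SPEC = DetectorSpec(min_event_duration=100, merge_gap=50)

    def test_all_below_threshold(self):
        res = binarize_and_segment(np.zeros(1000), 1.0, self.SPEC)
        assert len(res.events) == 0

    def test_single_pulse_boundaries(self):
        g = np.zeros(2000)
        g[700:1300] = 5.0
        res = binarize_and_segment(g, 1.0, self.SPEC)
        assert [(e.start, e.end) for e in res.events] == [(700, 1300)]

    @pytest.mark.parametrize("gap,expected", [(50, 1), (10, 2)])
    def test_merge_gap_controls_fusion(self, gap, expected):
        g = np.zeros(3000)
        g[500:1100] = 5.0
        g[1120:1720] = 5.0  # 20-sample gap
        spec = DetectorSpec(min_event_duration=100, merge_gap=gap)
        res = binarize_and_segment(g, 1.0, spec)
        assert len(res.events) == expected

    def test_matches_brute_force_run_enumeration(self, rng):
        for _ in range(20):
            z = (rng.uniform(size=500) < 0.4).astype(float)
            spec = DetectorSpec(min_event_duration=5, merge_gap=8)
            res = binarize_and_segment(z, 0.5, spec)
            expected = brute_force_segments(z > 0.5, 5, 8)
            assert [(e.start, e.end) for e in res.events] == expected

    def test_idempotent_on_own_events(self, rng):
        g = rng.uniform(size=2000)
        spec = DetectorSpec(min_event_duration=20, merge_gap=30)
        first = binarize_and_segment(g, 0.8, spec)
        indicator = np.zeros_like(g)
        for ev in first.events:
            indicator[ev.start : ev.end] = 1.0
        second = binarize_and_segment(indicator, 0.5, spec)
        assert [(e.start, e.end) for e in second.events] == [
            (e.start, e.end) for e in first.events
        ]

    def test_infinite_threshold_rejected(self):
        with pytest.raises(ValueError):
            binarize_and_segment(np.zeros(10), np.inf, self.SPEC)

    def test_event_count_monotone_in_alpha(self):
        # unimodal bumps: raising the threshold can only shrink or drop runs
        t = np.arange(5000, dtype=float)
        g = sum(
            np.exp(-0.5 * ((t - c) / 120.0) ** 2) for c in (800, 2000, 3100, 4200)
        )
        baseline_mean = g[:400].mean() + 1e-3
        spec = DetectorSpec(min_event_duration=50, merge_gap=100)
        counts = [
            len(binarize_and_segment(g, a * baseline_mean, spec).events)
            for a in (0.5, 1.0, 2.0, 5.0, 20.0, 2000.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestExtractSegments:
    def test_centering_arithmetic(self):
        rec = Recording(np.arange(4000, dtype=float)[None, :], 1000.0)
        (seg,) = extract_segments(rec, EventTable([Event(1000, 1400)]), 1024)
        np.testing.assert_array_equal(seg[0], np.arange(688, 1712, dtype=float))

    def test_left_edge_zero_padded(self, rng):
        rec = Recording(rng.standard_normal((2, 3000)), 1000.0)
        (seg,) = extract_segments(rec, EventTable([Event(10, 200)]), 1024)
        assert seg.shape == (2, 1024)
        lo = (10 + 200) // 2 - 512  # negative: padded amount
        np.testing.assert_array_equal(seg[:, : -lo], 0.0)
        np.testing.assert_array_equal(seg[:, -lo:], rec.samples[:, : 1024 + lo])

    def test_interior_energy_preserved(self, rng):
        rec = Recording(rng.standard_normal((2, 5000)), 1000.0)
        (seg,) = extract_segments(rec, EventTable([Event(2000, 2400)]), 1024)
        lo = 2200 - 512
        assert np.sum(seg**2) == pytest.approx(
            np.sum(rec.samples[:, lo : lo + 1024] ** 2)
        )

    def test_event_outside_recording(self):
        rec = Recording(np.zeros((1, 1000)), 1000.0)
        with pytest.raises(ValueError, match="outside"):
            extract_segments(rec, EventTable([Event(2000, 2400)]), 1024)

    def test_length_must_be_multiple_of_32(self):
        rec = Recording(np.zeros((1, 1000)), 1000.0)
        with pytest.raises(ValueError):
            extract_segments(rec, EventTable([Event(0, 100)]), 1000)


def optimal_match_count(det_mids, tru_mids, tol):
    """Exhaustive maximum one-to-one matching on tiny tables."""
    best = 0
    k = min(len(det_mids), len(tru_mids))
    for det_sub in itertools.permutations(range(len(det_mids)), k):
        for tru_sub in itertools.combinations(range(len(tru_mids)), k):
            n = sum(
                abs(det_mids[i] - tru_mids[j]) <= tol
                for i, j in zip(det_sub, tru_sub)
            )
            best = max(best, n)
    return best


class TestFder:
    def test_perfect_detection(self, sim_default):
        _, truth, _ = sim_default
        res = compute_fder(truth, truth, tol=100)
        assert (res.fder, res.n_fp, res.n_fn, res.n_all) == (0.0, 0, 0, 125)

    def test_ratio_arithmetic(self):
        truth = EventTable([Event(i * 1000, i * 1000 + 400) for i in range(100)])
        # 99 aligned detections + 1 spurious -> 1 FP and 1 FN over 100 detected
        detected = EventTable(
            [Event(i * 1000 + 10, i * 1000 + 410) for i in range(99)]
            + [Event(990_000, 990_400)]
        )
        res = compute_fder(detected, truth, tol=50)
        assert res.n_fp == 1 and res.n_fn == 1 and res.n_all == 100
        assert res.fder == pytest.approx(0.02)

    def test_jittered_truth_matches_exhaustive_matching(self, rng):
        for _ in range(10):
            starts = np.sort(rng.choice(np.arange(20) * 500, size=6, replace=False))
            truth = EventTable([Event(int(s), int(s) + 300) for s in starts])
            jitter = rng.integers(-40, 41, size=6)
            detected = EventTable(
                [
                    Event(int(s + d), int(s + d) + 300)
                    for s, d in zip(starts, jitter)
                ]
            )
            res = compute_fder(detected, truth, tol=60)
            opt = optimal_match_count(
                detected.midpoints(), truth.midpoints(), tol=60
            )
            assert len(res.matches) == opt == 6
            assert res.fder == 0.0

    def test_no_detections_with_truth_is_undefined(self):
        truth = EventTable([Event(0, 100)])
        res = compute_fder(EventTable([]), truth, tol=10)
        assert res.fder is None
        assert res.n_fn == 1 and res.n_all == 0

    def test_negative_tol_rejected(self):
        with pytest.raises(ValueError):
            compute_fder(EventTable([]), EventTable([]), tol=-1)


class TestDetectEvents:
    def test_rms_on_default_simulation(self, sim_default):
        _, truth, filtered = sim_default
        res = detect_events(filtered, DetectorSpec(algorithm="rms"))
        assert compute_fder(res.events, truth, tol=500).fder == 0.0

    def test_requires_baseline(self, rng):
        rec = Recording(rng.standard_normal((2, 3000)), 1000.0)
        with pytest.raises(ValueError, match="baseline"):
            detect_events(rec, DetectorSpec())

    def test_baseline_shorter_than_window(self, rng):
        rec = Recording(
            rng.standard_normal((2, 3000)), 1000.0, baseline_interval=(0, 300)
        )
        with pytest.raises(ValueError, match="shorter than"):
            detect_events(rec, DetectorSpec(window=400))
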