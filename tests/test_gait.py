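"""Swing extraction, gait classification, irregularity detection."""

import math

import numpy as np
import pytest

import hexawalk as hw
from hexawalk.gait import (PATTERN_PAIRS, StepIntervals, classify,
                           detect_prolonged_lift, exact_recurrence,
                           extract_swings, mirror_swings, overlap_matrix,
                           synth_traces)

LABELS = sorted(PATTERN_PAIRS)


class TestExtractSwings:
    def test_constant_contact_band_gives_no_swings(self):
        sw = extract_swings(np.full(5000, 31.0))
        assert sw.intervals == []

    def test_square_wave_recovers_plateaus(self):
        t = np.arange(6000)
        beta = np.where((t % 600) < 300, 55.0, 31.0)
        sw = extract_swings(beta)
        closed = sw.closed()
        assert len(closed) >= 9
        for a, b in closed:
            assert b - a == pytest.approx(300, abs=1)

    def test_short_ripple_excursions_are_ignored(self):
        beta = np.full(3000, 31.0)
        beta[1000:1010] = 33.0           # 10 ms blip < min_duration
        assert extract_swings(beta).intervals == []

    def test_open_interval_at_end(self):
        beta = np.full(1000, 31.0)
        beta[800:] = 55.0
        sw = extract_swings(beta)
        assert len(sw.intervals) == 1
        assert math.isinf(sw.intervals[0][1])

    def test_empty_trace_raises(self):
        with pytest.raises(ValueError):
            extract_swings(np.array([]))


class TestClassifier:
    @pytest.mark.parametrize("pattern,duty", [
        ("tripod", 0.33), ("tetrapod_B", 0.25), ("tetrapod_C", 0.25),
        ("bilateral_sync", 0.25), ("new_pattern", 0.2),
    ])
    def test_synthetic_closure(self, pattern, duty):
        t, traces = synth_traces(pattern, period=1800, duty=duty, jitter=0,
                                 seed=0)
        swings = {leg: extract_swings(traces[leg], t, leg=leg)
                  for leg in traces}
        lab = classify(swings, (1800.0, float(t[-1])))
        assert lab.label == pattern

    @pytest.mark.parametrize("pattern", LABELS)
    def test_mirror_symmetry(self, pattern):
        """Left-right mirroring maps B <-> C tetrapod and fixes the
        symmetric patterns."""
        t, traces = synth_traces(pattern, period=1800, duty=0.25, jitter=0)
        swings = {leg: extract_swings(traces[leg], t, leg=leg)
                  for leg in traces}
        lab = classify(mirror_swings(swings), (1800.0, float(t[-1])))
        expected = {"tetrapod_B": "tetrapod_C",
                    "tetrapod_C": "tetrapod_B"}.get(pattern, pattern)
        assert lab.label == expected

    def test_heavy_jitter_defeats_classification(self):
        n_unclassified = 0
        for seed in range(100):
            t, traces = synth_traces("tetrapod_B", period=1800, duty=0.25,
                                     jitter=0.3 * 1800, seed=seed)
            swings = {leg: extract_swings(traces[leg], t, leg=leg)
                      for leg in traces}
            if classify(swings, (1800.0, float(t[-1]))).label \
                    != "tetrapod_B":
                n_unclassified += 1
        assert n_unclassified >= 80

    def test_short_window_unclassified_with_reason(self):
        t, traces = synth_traces("tripod", period=1800, duty=0.33)
        swings = {leg: extract_swings(traces[leg], t, leg=leg)
                  for leg in traces}
        lab = classify(swings, (0.0, 1000.0))
        assert lab.label == "unclassified"
        assert lab.reason

    def test_unknown_pattern_raises(self):
        with pytest.raises(ValueError):
            synth_traces("gallop")

    def test_generated_onsets_recovered_within_one_sample(self):
        period, duty = 1500.0, 0.3
        t, traces = synth_traces("tripod", period=period, duty=duty)
        sw = extract_swings(traces["L2"], t, leg="L2")
        phase = 0.5  # L2 is in the second tripod triple
        for a, b in sw.closed():
            k = round((a - phase * period) / period)
            assert a == pytest.approx((k + phase) * period, abs=1.0)
            assert b == pytest.approx(a + duty * period, abs=1.0)


class TestOverlapMatrix:
    def test_symmetric_unit_diagonal_bounded(self):
        t, traces = synth_traces("tetrapod_B", period=1800, duty=0.25,
                                 jitter=100, seed=3)
        swings = {leg: extract_swings(traces[leg], t, leg=leg)
                  for leg in traces}
        M = overlap_matrix(swings, (1800.0, float(t[-1]))).to_numpy()
        assert np.allclose(M, M.T)
        assert np.allclose(np.diag(M), 1.0)
        assert (M >= 0).all() and (M <= 1).all()


class TestProlongedLift:
    def test_threshold_and_permanence(self):
        swings = {"L1": StepIntervals("L1", [(0.0, 400.0), (1000.0, 2200.0),
                                             (5000.0, math.inf)])}
        ev = detect_prolonged_lift(swings, horizon=8000.0)
        assert len(ev) == 2
        flagged = {(e.liftoff, e.permanent) for e in ev}
        assert flagged == {(1000.0, False), (5000.0, True)}

    def test_swing_in_progress_at_horizon_not_flagged(self):
        swings = {"L1": StepIntervals("L1", [(7800.0, math.inf)])}
        assert detect_prolonged_lift(swings, horizon=8000.0) == []


class TestRecurrence:
    def test_known_period_recovered_exactly(self):
        base = [True, True, True, False, False, True, False]
        flags = base * 5
        assert exact_recurrence(flags, step=50.0) == 7 * 50.0

    def test_constant_sequence_has_no_period(self):
        assert exact_recurrence([True] * 30, step=50.0) is None


def test_scan_is_deterministic():
    """Repeating the transition-start scan gives an identical map."""
    kw = dict(window=(6000.0, 6100.0), step=50.0, post_window=3000.0)
    a = hw.scan_transition_starts(**kw)["map"]
    b = hw.scan_transition_starts(**kw)["map"]
    assert a.equals(b)


def test_scan_without_transition_all_regular():
    res = hw.scan_transition_starts(window=(6000.0, 6100.0), step=50.0,
                                    post_window=3000.0,
                                    enable_transition=False)
    df = res["map"]
    assert df["L1_regular"].all() and df["R1_regular"].all()
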