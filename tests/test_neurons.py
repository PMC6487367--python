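"""Single-unit dynamics: half-center CPGs and motoneurons."""

import numpy as np
import pytest

import hexawalk as hw
from hexawalk.neurons import measure_rhythm, simulate_cpg, mn_activity, \
    inhibition_response

TETRAPOD = (0.20, 0.295)
TRIPOD = (0.26, 0.32)


def test_zero_drive_is_quiescent():
    res = simulate_cpg((0.0, 0.0), duration=8000)
    assert not res.oscillating
    assert res.V[4000:].std() < 1.0


def test_calibrated_drive_oscillates_in_antiphase(cpg_tetrapod):
    res = cpg_tetrapod
    assert res.oscillating
    assert res.period is not None and 1000 < res.period < 2200
    # plateau-midpoint phase difference: antiphase regardless of duty
    assert res.phase_diff == pytest.approx(0.5, abs=0.05)


def test_period_decreases_from_tetrapod_to_tripod_drive():
    periods = []
    for lam in np.linspace(0.0, 1.0, 5):
        drive = (1 - lam) * np.array(TETRAPOD) + lam * np.array(TRIPOD)
        res = simulate_cpg(tuple(drive), duration=14000)
        assert res.oscillating
        periods.append(res.period)
    assert all(a > b for a, b in zip(periods, periods[1:]))


def test_symmetric_drive_sweep_periods_monotone():
    # same property along the symmetric-drive axis used by prototyping
    p1 = simulate_cpg((0.22, 0.30), duration=12000).period
    p2 = simulate_cpg((0.26, 0.34), duration=12000).period
    assert p1 > p2


class TestInhibitionResponse:
    def _plateau(self, res):
        x = res.V[:, 0]
        above = x > -40
        on = next(t for t in range(5000, 9000) if above[t] and not above[t - 1])
        off = next(t for t in range(on, len(x)) if not above[t])
        return on, off

    def test_mid_plateau_pulse_at_interleg_magnitude_persists(self,
                                                              cpg_tetrapod):
        """Depolarization block: a strongly depolarized half-center
        neuron shrugs off inhibition at the interleg conductance."""
        on, off = self._plateau(cpg_tetrapod)
        r = inhibition_response(TETRAPOD, pulse_start=(on + off) // 2,
                                pulse_duration=100, g_pulse=0.12)
        assert r["persists"]
        assert r["shortening_fraction"] < 0.05

    def test_late_plateau_pulse_terminates_early(self, cpg_tetrapod):
        on, off = self._plateau(cpg_tetrapod)
        r = inhibition_response(TETRAPOD, pulse_start=off - 130,
                                pulse_duration=100, g_pulse=0.12)
        assert not r["persists"]
        assert r["shortening_fraction"] > 0.05

    def test_zero_pulse_leaves_trace_unchanged(self, cpg_tetrapod):
        on, off = self._plateau(cpg_tetrapod)
        r = inhibition_response(TETRAPOD, pulse_start=(on + off) // 2,
                                pulse_duration=100, g_pulse=0.0)
        assert r["plateau_off_perturbed"] == r["plateau_off"]

    def test_termination_deepens_with_pulse_strength(self, cpg_tetrapod):
        """Once above the block threshold, stronger pulses cut the
        plateau shorter; below it the plateau is essentially intact."""
        on, off = self._plateau(cpg_tetrapod)
        mid = (on + off) // 2
        short = {g: inhibition_response(TETRAPOD, pulse_start=mid,
                                        pulse_duration=100,
                                        g_pulse=g)["shortening_fraction"]
                 for g in (0.0, 0.12, 0.3)}
        assert short[0.0] == pytest.approx(0.0, abs=1e-9)
        assert short[0.12] < 0.05
        assert short[0.3] > 0.3

    def test_pulse_outside_window_raises(self):
        with pytest.raises(ValueError):
            inhibition_response(TETRAPOD, pulse_start=99999.0,
                                pulse_duration=100, g_pulse=0.1)


class TestMotoneurons:
    def test_saturating_inhibition_silences(self):
        n = 1500
        act = mn_activity("fast", np.full(n, 0.3), np.full(n, 2.0))
        assert act.max() < 0.05

    def test_slow_mn_adapts_more_than_fast(self):
        n = 2500
        drive = np.zeros(n)
        drive[200:] = 0.3
        inh = np.zeros(n)
        fast = mn_activity("fast", drive, inh)
        slow = mn_activity("slow", drive, inh)
        def ratio(a):
            early = a[300:500].mean()
            late = a[-300:].mean()
            return late / early
        assert ratio(slow) < ratio(fast)

    def test_activation_onset_latency_below_50ms(self):
        n = 1000
        drive = np.zeros(n)
        drive[200:] = 0.3
        act = mn_activity("fast", drive, np.zeros(n))
        onset = np.argmax(act > 0.5)
        assert 0 < onset - 200 < 50

    def test_mismatched_signals_raise(self):
        with pytest.raises(ValueError):
            mn_activity("fast", np.zeros(100), np.zeros(50))


def test_integration_is_deterministic():
    a = simulate_cpg(TETRAPOD, duration=5000)
    b = simulate_cpg(TETRAPOD, duration=5000)
    assert np.array_equal(a.V, b.V)


def test_measure_rhythm_on_synthetic_square_waves():
    # independent check of the rhythm oracle itself
    t = np.arange(12000)
    x = np.where((t % 1000) < 400, -20.0, -60.0)
    y = np.where(((t + 500) % 1000) < 400, -20.0, -60.0)
    osc, period, phase = measure_rhythm(np.stack([x, y], axis=1))
    assert osc
    assert period == pytest.approx(1000, abs=2)
    assert phase == pytest.approx(0.5, abs=0.01)
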