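"""Sensory signals, gate automata, and single-leg stepping."""

import numpy as np
import pytest

import hexawalk as hw
from hexawalk.gates import (GateAutomaton, GateState, compute_sensory,
                            update_gates)
from hexawalk.params import GateParams


class TestSensorySignals:
    @pytest.mark.parametrize("beta,contact", [
        (31.0, True),    # inside the 30-32 deg contact band
        (45.0, False),   # mid swing
        (60.0, False),   # maximally lifted
        (30.0, True),
        (32.0, False),   # band is half-open
    ])
    def test_ground_contact_band(self, beta, contact):
        s = compute_sensory(beta=beta, dbeta=0.0, gamma=75.0)
        assert s.ground_contact is contact

    def test_fields_passed_through(self):
        s = compute_sensory(beta=40.0, dbeta=-0.3, gamma=60.0)
        assert (s.beta, s.dbeta, s.gamma) == (40.0, -0.3, 60.0)


class TestGateAutomaton:
    def test_falling_through_crit_switches_high(self):
        a = GateAutomaton(33.0, 2.0, high=False)
        a.prime(34.0)
        assert a.update(32.5) == "low->high"
        assert a.high

    def test_rising_through_crit_leaves_low_gate(self):
        a = GateAutomaton(33.0, 2.0, high=False)
        a.prime(32.0)
        assert a.update(34.0) is None
        assert not a.high

    def test_release_requires_hysteresis_margin(self):
        a = GateAutomaton(33.0, 2.0, high=True)
        a.prime(31.0)
        assert a.update(34.0) is None          # below crit + hysteresis
        assert a.update(35.5) == "high->low"

    def test_triangular_cycle_gives_one_transition_each_way(self):
        a = GateAutomaton(33.0, 2.0, high=False)
        t = np.arange(0, 1001)  # start at the peak, exactly two cycles
        wave = 45.0 - 15.0 * np.abs(((t + 250) % 500) / 250.0 - 1.0)
        a.prime(wave[0])
        flips = [f for f in (a.update(v) for v in wave[1:]) if f]
        assert flips.count("low->high") == 2
        assert flips.count("high->low") == 2

    def test_functional_form_matches(self):
        p = GateParams()
        st = GateState(pr_high=False, ef_high=False, ld_high=False)
        s = compute_sensory(beta=32.9, dbeta=-0.1, gamma=80.0)
        new = update_gates(s, st, p)
        assert new.pr_high and new.ef_high


class TestSingleLeg:
    def test_periodic_stepping_with_stable_period(self, single_leg_tetrapod):
        sw = hw.extract_swings(single_leg_tetrapod.beta("L2"),
                               single_leg_tetrapod.time)
        onsets = [a for a, _ in sw.intervals]
        assert len(onsets) >= 4
        periods = np.diff(onsets)
        assert periods.std() / periods.mean() < 0.05

    def test_no_central_drive_no_stepping(self):
        """Quiescent preparation: without central drive (CPG drive and
        the tonic MN excitation) the leg produces no swing events."""
        from hexawalk.params import ModelParams, DriveTable
        p = ModelParams()
        p.syn.g_MN = 0.0
        zero = DriveTable(pr=(0.0, 0.0), ld=(0.0, 0.0), ef=(0.0, 0.0))
        rec = hw.simulate_single_leg(duration=5000, gait="tetrapod",
                                     drives=zero, params=p)
        sw = hw.extract_swings(rec.beta("L2"), rec.time)
        assert sw.intervals == []

    def test_tripod_period_smaller_than_tetrapod(self, single_leg_tetrapod,
                                                 single_leg_tripod):
        def period(rec):
            ons = [a for a, _ in hw.extract_swings(rec.beta("L2"),
                                                   rec.time).intervals]
            return np.diff(ons).mean()
        assert period(single_leg_tripod) < period(single_leg_tetrapod)

    def test_gate_dwell_times_exceed_10ms(self, single_leg_tetrapod):
        """No chatter: gates hold each state for well over 10 ms."""
        times = {}
        for e in single_leg_tetrapod.events:
            if e["kind"] != "gate":
                continue
            key = (e["leg"], e["gate"])
            if key in times:
                assert e["t"] - times[key] > 10.0
            times[key] = e["t"]

    def test_stance_retraction_swing_protraction(self, single_leg_tetrapod):
        """Intraleg phase order: the leg retracts while grounded and
        protracts during swing (forward walking)."""
        rec = single_leg_tetrapod
        beta = rec.beta("L2")
        alpha = rec.leg_angle("L2", "alpha")
        dalpha = np.gradient(alpha, rec.time)
        stance = (beta < 32.0) & (np.abs(dalpha) > 0.005)
        swing = (beta > 34.0) & (np.abs(dalpha) > 0.005)
        late = rec.time > 3000
        # retraction = alpha increasing; protraction = decreasing
        assert np.mean(dalpha[stance & late] > 0) > 0.9
        assert np.mean(dalpha[swing & late] < 0) > 0.9


class TestSlowMuscleRipple:
    def test_ripple_present_but_confined_to_contact_band(self,
                                                         single_leg_tetrapod):
        """The slow muscles put a small-amplitude oscillation on the
        stance baseline without ever lifting beta above the contact
        band."""
        rec = single_leg_tetrapod
        beta = rec.beta("L2")
        sw = hw.extract_swings(beta, rec.time)
        closed = sw.closed()
        # stance = between a touchdown and the next liftoff
        for (_, td), (lo, _) in zip(closed[1:-1], closed[2:]):
            seg = beta[int(td) + 80:int(lo) - 80]
            assert seg.max() < 32.0
            assert seg.max() - seg.min() > 0.01   # ripple is visible

    def test_swing_count_unchanged_without_slow_muscles(self,
                                                        single_leg_tetrapod):
        rec_fast = hw.simulate_single_leg(duration=10000, gait="tetrapod",
                                          enable_slow=False)
        def count(rec):
            return len(hw.extract_swings(rec.beta("L2"), rec.time).intervals)
        assert count(rec_fast) == count(single_leg_tetrapod)
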