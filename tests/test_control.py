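"""Behavioral-mode controller rules and schedule validation."""

import pytest

import hexawalk as hw
from hexawalk.control import (BehaviorController, ModeCommand, Schedule,
                              validate_schedule)
from hexawalk.gates import compute_sensory


def make_controller(**kwargs):
    asm = hw.assemble()
    ctrl = BehaviorController(asm, Schedule(**kwargs))
    return ctrl


def sensors(**beta_dbeta):
    """Fake sensory dict; legs default to grounded and stationary."""
    out = {}
    for leg in hw.LEGS:
        beta, dbeta = beta_dbeta.get(leg, (31.0, 0.0))
        out[leg] = compute_sensory(beta, dbeta, 75.0)
    return out


class TestScheduleValidation:
    def test_empty_schedule_valid(self):
        assert validate_schedule([]) == []

    def test_stop_then_search_overlap_is_valid(self):
        cmds = [ModeCommand("stop", 1000.0),
                ModeCommand("search", 2000.0, leg="L1", on=True),
                ModeCommand("search", 3000.0, leg="L1", on=False),
                ModeCommand("restart", 3000.0)]
        assert validate_schedule(cmds) == []

    def test_backward_during_still_stand_conflicts(self):
        cmds = [ModeCommand("stop", 1000.0),
                ModeCommand("direction", 2000.0, target="backward")]
        conflicts = validate_schedule(cmds)
        assert len(conflicts) == 1
        assert conflicts[0]["index"] == 1 and conflicts[0]["other"] == 0

    def test_backward_after_restart_is_valid(self):
        cmds = [ModeCommand("stop", 1000.0),
                ModeCommand("restart", 2000.0),
                ModeCommand("direction", 3000.0, target="backward")]
        assert validate_schedule(cmds) == []

    def test_unsorted_commands_flagged(self):
        cmds = [ModeCommand("stop", 2000.0), ModeCommand("restart", 1000.0)]
        assert any("not time-sorted" in c["conflict"]
                   for c in validate_schedule(cmds))

    def test_bad_search_leg_flagged(self):
        cmds = [ModeCommand("search", 1000.0, leg="L2", on=True)]
        assert validate_schedule(cmds)

    def test_schedule_json_round_trip(self):
        sched = Schedule([ModeCommand("set_gait", 500.0, gait="tripod"),
                          ModeCommand("search", 900.0, leg="R1", on=True,
                                      tibia_drive=(0.4, 0.4))],
                         initial_gait="tetrapod")
        again = Schedule.from_json(sched.to_json())
        assert again.initial_gait == "tetrapod"
        assert vars(again.commands[1]) == vars(sched.commands[1])


class TestTripodInitiation:
    def test_front_or_hind_leg_lifted_rising_initiates(self):
        ctrl = make_controller()
        hit = ctrl.try_start_tripod_transition(
            sensors(L3=(45.0, 0.3)), "L")
        assert hit == ("L3", 3)

    def test_middle_leg_excluded(self):
        ctrl = make_controller()
        assert ctrl.try_start_tripod_transition(
            sensors(L2=(45.0, 0.3)), "L") is None

    def test_all_grounded_no_candidate(self):
        ctrl = make_controller()
        assert ctrl.try_start_tripod_transition(sensors(), "L") is None

    def test_pair_arbiter_restricts_other_side_to_same_segment(self):
        ctrl = make_controller()
        ctrl._pair_segment = 1   # left side already initiated at the front
        assert ctrl.try_start_tripod_transition(
            sensors(R3=(45.0, 0.3)), "R") is None
        assert ctrl.try_start_tripod_transition(
            sensors(R1=(45.0, 0.3)), "R") == ("R1", 1)


class TestTetrapodInitiation:
    def test_descending_legs_initiate(self):
        ctrl = make_controller()
        assert ctrl.try_start_tetrapod_transition(
            sensors(L2=(40.0, -0.2), L3=(35.0, -0.1)), "L")

    def test_rapidly_rising_hind_leg_defers(self):
        ctrl = make_controller()
        assert not ctrl.try_start_tetrapod_transition(
            sensors(L2=(40.0, -0.2), L3=(40.0, 0.4)), "L")


class TestStopRestart:
    def test_descending_right_leg_defers_stop(self):
        ctrl = make_controller()
        assert not ctrl.request_stop(sensors(R2=(45.0, -0.2)))

    def test_all_grounded_accepts_stop(self):
        ctrl = make_controller()
        assert ctrl.request_stop(sensors())

    def test_rising_right_legs_accept_stop(self):
        ctrl = make_controller()
        assert ctrl.request_stop(sensors(R1=(40.0, 0.2), R2=(50.0, 0.1)))

    def test_restart_while_walking_is_noop_with_warning(self):
        ctrl = make_controller()
        ctrl._do_restart(1000.0)
        assert ctrl.events[-1]["kind"] == "restart_ignored"
        assert not ctrl.stopped


class TestSearchAndDirection:
    def test_search_on_middle_leg_rejected(self):
        ctrl = make_controller()
        with pytest.raises(ValueError):
            ctrl.set_search("L2", True, None)

    def test_search_sets_and_clears_tibia_drive(self):
        ctrl = make_controller()
        li = ctrl.asm.legs.index("L1")
        ctrl.set_search("L1", True, (0.4, 0.4))
        assert tuple(ctrl.drives[li, 4:6]) == (0.4, 0.4)
        ctrl.set_search("L1", False, None)
        assert tuple(ctrl.drives[li, 4:6]) != (0.4, 0.4)

    def test_backward_rejected_during_still_stand(self):
        ctrl = make_controller()
        ctrl.stopped = True
        assert ctrl.set_direction("backward", sensors(L2=(59.0, 0.1))) \
            == "rejected"

    def test_backward_accepted_when_middle_leg_near_max(self):
        ctrl = make_controller()
        assert ctrl.set_direction("backward", sensors(L2=(59.0, 0.1))) \
            == "accepted"
        assert ctrl.direction == "backward"

    def test_backward_deferred_when_middle_legs_grounded(self):
        ctrl = make_controller()
        assert ctrl.set_direction("backward", sensors()) == "deferred"

    def test_forward_always_accepted(self):
        ctrl = make_controller()
        ctrl.direction = "backward"
        assert ctrl.set_direction("forward", sensors()) == "accepted"
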