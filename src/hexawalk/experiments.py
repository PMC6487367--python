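"""Canned behavioral experiments on the six-leg model.

Each function builds a schedule, runs the model and measures the result:
stop-pose acquisition time, restart behavior, search-movement isolation,
and the start-time scans that estimate how often transitions to and from
backward walking fail.  These are the protocols behind the quantitative
claims of the model; the functions return plain dicts so they can be
reused from tests, scripts and the command line.
"""

from __future__ import annotations

import math
from typing import Dict, Optional, Sequence

import numpy as np

from . import engine, gait
from .control import ModeCommand, Schedule
from .params import ModelParams, SimulationConfig
from .wiring import assemble, leg_role, LEGS

#: canonical preparation: bilateral-sync start -> tripod -> B-type
#: tetrapod established from about t = 9500 ms on
PIPELINE = [("set_gait", 3000.0, "tripod"), ("set_gait", 7600.0, "tetrapod")]
TETRAPOD_PERIOD = 1740.0


def _pipeline_cmds():
    return [ModeCommand(kind, t, gait=g) for kind, t, g in PIPELINE]


def _run(cmds, t_end, params: Optional[ModelParams] = None):
    asm = assemble(params or ModelParams())
    sched = Schedule(commands=sorted(cmds, key=lambda c: c.t),
                     initial_gait="tetrapod")
    return engine.run(asm, sched, SimulationConfig(t_end=float(t_end)))


# --------------------------------------------------------------------------
# still stand
# --------------------------------------------------------------------------

STOP_TARGET_ALPHA = {"front": 28.0, "middle": 128.0, "hind": 128.0}
STOP_TARGET_GAMMA = 45.0


def in_stop_pose(record, t: int, tol: float = 1.0) -> bool:
    """All six legs within tolerance of the still-stand pose at sample t:
    front legs protracted, the others retracted, all grounded, all
    tibiae stretched."""
    for li, leg in enumerate(record.legs):
        alpha, beta, gamma = record.angles[t, 3 * li:3 * li + 3]
        if abs(alpha - STOP_TARGET_ALPHA[leg_role(leg)]) > tol:
            return False
        if not (30.0 <= beta < 32.0):
            return False
        if abs(gamma - STOP_TARGET_GAMMA) > tol:
            return False
    return True


def measure_stop(t_stop: float = 12800.0, hold: float = 2500.0,
                 params: Optional[ModelParams] = None,
                 pose_tol: float = 1.0) -> dict:
    """Stop during steady tetrapod walking; measure the time from the
    accepted stop command until the complete still-stand pose, then
    restart and record the first lifted leg and the emerging pattern."""
    t_restart = t_stop + hold
    cmds = _pipeline_cmds() + [ModeCommand("stop", t_stop),
                               ModeCommand("restart", t_restart)]
    rec = _run(cmds, t_restart + 4.2 * TETRAPOD_PERIOD, params)
    accept = next(e["t"] for e in rec.events if e["kind"] == "stop_accepted")
    pose_t = None
    for t in range(int(accept), len(rec.time)):
        if in_stop_pose(rec, t, pose_tol):
            pose_t = t
            break
    swings = gait.extract_all(rec)
    after = sorted((iv[0], leg) for leg in rec.legs
                   for iv in swings[leg].intervals if iv[0] >= t_restart)
    first_legs = [leg for t, leg in after if t == after[0][0]] if after else []
    w0 = t_restart + 1200.0
    label = gait.classify(swings, (w0, w0 + 3 * TETRAPOD_PERIOD))
    return {
        "accept_time": float(accept),
        "stop_time_ms": None if pose_t is None else float(pose_t - accept),
        "first_lifted": first_legs,
        "restart_label": label.label,
        "record": rec,
    }


# --------------------------------------------------------------------------
# search movements
# --------------------------------------------------------------------------

def measure_search(t_on: float = 11500.0, duration: float = 4000.0,
                   legs: Sequence[str] = ("L1", "R1"),
                   params: Optional[ModelParams] = None) -> dict:
    """Search movements on the front legs during tetrapod walking."""
    t_off = t_on + duration
    cmds = _pipeline_cmds()
    for leg in legs:
        cmds += [ModeCommand("search", t_on, leg=leg, on=True),
                 ModeCommand("search", t_off, leg=leg, on=False)]
    rec = _run(cmds, t_off + 4.2 * TETRAPOD_PERIOD, params)
    swings = gait.extract_all(rec)

    def mean_period(leg, lo, hi):
        ons = [a for a, _ in swings[leg].intervals if lo < a < hi]
        return float(np.mean(np.diff(ons))) if len(ons) >= 2 else math.nan

    out = {"legs": list(legs), "record": rec}
    win = slice(int(t_on + 1200), int(t_off - 100))
    for leg in legs:
        li = rec.legs.index(leg)
        g = rec.angles[win, 3 * li + 2]
        gsw = gait.extract_swings(g, threshold=70.0, min_duration=10.0)
        ons = [a for a, _ in gsw.intervals]
        out[leg] = {
            "alpha_hold": float(rec.angles[win, 3 * li].mean()),
            "beta_hold": float(rec.angles[win, 3 * li + 1].mean()),
            "beta_max": float(rec.angles[win, 3 * li + 1].max()),
            "gamma_period": (float(np.mean(np.diff(ons)))
                             if len(ons) >= 3 else math.nan),
        }
    walking = [leg for leg in LEGS if leg not in legs]
    out["walking_period_ratio"] = {
        leg: mean_period(leg, t_on + 300, t_off) / mean_period(leg, 8450, t_on)
        for leg in walking}
    w0 = t_off + 1200.0
    out["resumed_label"] = gait.classify(
        swings, (w0, w0 + 2.6 * TETRAPOD_PERIOD)).label
    return out


# --------------------------------------------------------------------------
# backward walking
# --------------------------------------------------------------------------

def _stepping_ok(swings, lo: float, hi: float,
                 expected_period: float = TETRAPOD_PERIOD) -> bool:
    """Every leg keeps stepping properly in [lo, hi]: no prolonged or
    permanent lift, no stance gap much longer than a step cycle."""
    for leg, sw in swings.items():
        iv = [x for x in sw.intervals if x[1] > lo and x[0] < hi]
        for a, b in iv:
            if min(b, hi) - max(a, lo) >= 1000.0:
                return False
        ons = [a for a, _ in iv]
        edges = [lo] + ons + [hi]
        if max(np.diff(edges)) > 1.75 * expected_period:
            return False
    return True


def backward_transition_scan(starts: Optional[Sequence[float]] = None,
                             constraint: bool = True,
                             backward_span: float = 4500.0,
                             params: Optional[ModelParams] = None) -> dict:
    """Scan transition-to-backward start times over a step cycle.

    A trial fails if any leg stops proper backward stepping during the
    backward interval.  With ``constraint`` the transition waits for a
    middle leg (L2 or R2) to be lifted near its 60-degree maximum;
    without it the motor-map swap is applied immediately.
    """
    if starts is None:
        starts = np.arange(11300.0, 13500.0 + 1.0, 100.0)
    results = []
    for t0 in starts:
        cmds = _pipeline_cmds() + [
            ModeCommand("direction", float(t0), target="backward",
                        force=not constraint)]
        rec = _run(cmds, t0 + backward_span + 500.0, params)
        acc = [e["t"] for e in rec.events
               if e["kind"] == "direction" and e.get("target") == "backward"]
        if not acc:
            results.append({"start": float(t0), "accepted": None,
                            "failed": True})
            continue
        swings = gait.extract_all(rec)
        ok = _stepping_ok(swings, acc[0] + 500.0, t0 + backward_span)
        results.append({"start": float(t0), "accepted": float(acc[0]),
                        "failed": not ok})
    failed = sum(r["failed"] for r in results)
    return {"trials": results, "n": len(results),
            "failed_fraction": failed / len(results)}


def forward_restore_scan(starts: Optional[Sequence[float]] = None,
                         t_backward: float = 11600.0,
                         post_window: float = 4.2 * TETRAPOD_PERIOD,
                         params: Optional[ModelParams] = None) -> dict:
    """Scan return-to-forward start times from steady backward walking.

    A trial fails if the classifier does not report a tetrapod (B or C
    type) within the post-return window.
    """
    if starts is None:
        starts = np.arange(16000.0, 18200.0 + 1.0, 100.0)
    results = []
    for t0 in starts:
        cmds = _pipeline_cmds() + [
            ModeCommand("direction", t_backward, target="backward"),
            ModeCommand("direction", float(t0), target="forward")]
        rec = _run(cmds, t0 + post_window + 1400.0, params)
        swings = gait.extract_all(rec)
        lab = gait.classify(swings, (t0 + 1200.0, t0 + 1200.0 + post_window))
        results.append({"start": float(t0), "label": lab.label,
                        "failed": lab.label not in ("tetrapod_B",
                                                    "tetrapod_C")})
    failed = sum(r["failed"] for r in results)
    return {"trials": results, "n": len(results),
            "failed_fraction": failed / len(results)}
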