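"""Antagonistic muscle-pair joint dynamics.

Each of the three leg joints (alpha: protractor-retractor, beta:
levator-depressor, gamma: extensor-flexor) is one second-order ODE
driven by up to four muscles (fast and slow on each side):

    J theta'' = sum_i gain_i a_i (lim_i - theta) - c theta'

Each muscle pulls the joint towards its own limit angle with a torque
proportional to activation and to the remaining excursion, so the joint
limits are attracting equilibria and can never be overshot into
forbidden angles — saturation is part of the force law, not a clip.
The static equilibrium under constant activations is the
activation-weighted mean of the muscle target angles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._kernel import joint_trajectory
from .params import MusclePairParams, JOINT_LIMITS

#: target angle each muscle pulls towards, per joint:
#: (agonist fast, agonist slow, antagonist fast, antagonist slow)
JOINT_TARGETS = {
    "alpha": (28.0, 28.0, 128.0, 128.0),
    "beta": (60.0, 60.0, 30.0, 30.0),
    "gamma": (45.0, 45.0, 110.0, 110.0),
}


@dataclass
class JointState:
    joint_id: str                 # alpha | beta | gamma
    angle: float
    velocity: float = 0.0         # deg/ms


def _gains(params: MusclePairParams) -> np.ndarray:
    return np.array([params.gain_fast, params.gain_slow,
                     params.gain_fast, params.gain_slow])


def _check(activities, dt):
    a = np.asarray(activities, float)
    if a.shape[-1] != 4:
        raise ValueError("expected 4 activities "
                         "(fast/slow x agonist/antagonist)")
    if np.any(a < 0):
        raise ValueError("muscle activities must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return a


def joint_step(state: JointState, activities: Sequence[float],
               params: MusclePairParams | None = None,
               dt: float = 0.05) -> JointState:
    """Advance one joint by ``dt`` under fixed muscle activations."""
    params = params or MusclePairParams()
    a = _check(activities, dt)
    lims = np.asarray(JOINT_TARGETS[state.joint_id])
    out = joint_trajectory(state.angle, state.velocity, a[None, :], lims,
                           _gains(params), params.damping, params.inertia, dt)
    return JointState(state.joint_id, float(out[-1, 0]), float(out[-1, 1]))


def simulate_joint(state: JointState, activities: np.ndarray,
                   params: MusclePairParams | None = None,
                   dt: float = 0.05) -> np.ndarray:
    """Integrate a joint under a (n, 4) activation signal; returns the
    (n, 2) angle/velocity trajectory."""
    params = params or MusclePairParams()
    a = _check(activities, dt)
    lims = np.asarray(JOINT_TARGETS[state.joint_id])
    return joint_trajectory(state.angle, state.velocity, a, lims,
                            _gains(params), params.damping, params.inertia,
                            dt)


def pose_equilibrium(activities: Sequence[float], joint_id: str = "alpha",
                     params: MusclePairParams | None = None,
                     angle0: float | None = None) -> float:
    """Static equilibrium angle under constant activations (closed form).

    The joint settles at the activation-weighted mean of the muscle
    target angles; with no active muscle it stays wherever it is
    (``angle0``, defaulting to mid-range).
    """
    params = params or MusclePairParams()
    a = _check(activities, 1.0)
    w = _gains(params) * a
    lims = np.asarray(JOINT_TARGETS[joint_id])
    total = w.sum()
    if total <= 0:
        if angle0 is not None:
            return float(angle0)
        lo, hi = JOINT_LIMITS[joint_id]
        return 0.5 * (lo + hi)
    return float((w * lims).sum() / total)


def activation_lowpass(signal: np.ndarray, tau: float,
                       dt: float = 0.05) -> np.ndarray:
    """First-order muscle-activation filter (excitation -> activation).

    Fast muscles use ``tau_act_fast``, slow ones the much longer
    ``tau_act_slow``; the step-response rise times scale with tau.
    """
    if tau <= 0 or dt <= 0:
        raise ValueError("tau and dt must be positive")
    sig = np.asarray(signal, float)
    out = np.empty_like(sig)
    k = dt / tau
    acc = sig[0] * 0.0
    for i in range(len(sig)):
        acc = acc + k * (sig[i] - acc)
        out[i] = acc
    return out


def rise_time(trace: np.ndarray, dt: float = 0.05) -> float:
    """10-90% rise time of a monotone step response, in ms."""
    x = np.asarray(trace, float)
    lo, hi = x[0], x[-1]
    span = hi - lo
    if abs(span) < 1e-12:
        return 0.0
    t10 = np.argmax(x >= lo + 0.1 * span)
    t90 = np.argmax(x >= lo + 0.9 * span)
    return float((t90 - t10) * dt)
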