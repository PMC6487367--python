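"""Hybrid simulation engine.

Continuous dynamics (648 neuronal ODEs + 18 second-order joint ODEs) are
advanced with a fixed-step kernel; all discrete structure — sensory gate
automata, interleg coordination rules, contralateral pathways and the
behavioral-mode controller — is evaluated on a 1-ms supervision grid, two
orders of magnitude below every behavioral time scale of the model.  The
integration is fully deterministic: two runs with the same configuration
produce bit-identical trajectories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from . import wiring
from ._kernel import step_network
from .params import ModelParams, SimulationConfig
from .wiring import (ModelAssembly, N_PER_LEG, PR0, PR1, LD0, LD1, EF0, EF1,
                     RELAY_BASE, MN_BASE, IN_BASE, JOINTS)
from .gates import GateBank, SensorySignals, compute_sensory
from .body import ipsilateral_inhibition
from .control import BehaviorController, Schedule


@dataclass
class TrajectoryRecord:
    """Uniformly sampled joint-angle trajectories plus the event log."""

    time: np.ndarray                  # ms
    angles: np.ndarray                # (n, 3 * n_legs): alpha, beta, gamma per leg
    legs: List[str]
    events: list = field(default_factory=list)
    voltages: Optional[np.ndarray] = None
    failure: Optional[dict] = None

    def leg_angle(self, leg: str, joint: str) -> np.ndarray:
        li = self.legs.index(leg)
        return self.angles[:, 3 * li + JOINTS.index(joint)]

    def beta(self, leg: str) -> np.ndarray:
        return self.leg_angle(leg, "beta")

    # ---- I/O -----------------------------------------------------------
    def columns(self) -> List[str]:
        return [f"{leg}_{j}" for leg in self.legs for j in JOINTS]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.angles, columns=self.columns())
        df.insert(0, "t_ms", self.time)
        return df

    def export(self, path) -> None:
        """Write the trajectory CSV and an event-log JSON sidecar."""
        self.to_frame().to_csv(path, index=False, float_format="%.6f")
        with open(str(path) + ".events.json", "w") as fh:
            json.dump({"legs": self.legs, "events": self.events}, fh, indent=1)


class TrajectoryParseError(ValueError):
    def __init__(self, message, line=None):
        self.line = line
        super().__init__(message if line is None
                         else f"line {line}: {message}")


def import_trajectories(path) -> TrajectoryRecord:
    """Read a trajectory CSV (+ sidecar, if present) back into a record."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # re-raise with a uniform type
        raise TrajectoryParseError(str(exc)) from exc
    if "t_ms" not in df.columns:
        raise TrajectoryParseError("missing t_ms column", line=1)
    t = df["t_ms"].to_numpy(float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise TrajectoryParseError("non-monotone time column",
                                   line=int(bad[0]) + 3)
    cols = [c for c in df.columns if c != "t_ms"]
    legs = []
    for c in cols:
        leg = c.split("_")[0]
        if leg not in legs:
            legs.append(leg)
    for leg in legs:
        for j in JOINTS:
            if f"{leg}_{j}" not in df.columns:
                raise TrajectoryParseError(f"missing column {leg}_{j}", line=1)
    angles = df[[f"{leg}_{j}" for leg in legs for j in JOINTS]].to_numpy(float)
    events = []
    sidecar = str(path) + ".events.json"
    try:
        with open(sidecar) as fh:
            events = json.load(fh)["events"]
    except FileNotFoundError:
        pass
    return TrajectoryRecord(time=t, angles=angles, legs=legs, events=events)


# --------------------------------------------------------------------------
# initial conditions
# --------------------------------------------------------------------------

def _minf(V, p):
    return 1.0 / (1.0 + np.exp(-(V - p.th_m) / p.s_m))


#: per-leg seed phases (fraction of a cycle) approximating the steady
#: coordination of each gait: the back-to-front metachronal wave per
#: side, sides staggered by a third of a cycle (B-type tetrapod) or in
#: antiphase (tripod)
_SEED_PHASES = {
    "tetrapod": {"L3": 0.0, "L2": 1 / 3, "L1": 2 / 3,
                 "R1": 0.0, "R3": 1 / 3, "R2": 2 / 3},
    "tripod": {"L3": 0.0, "L2": 0.45, "L1": 0.9,
               "R3": 0.5, "R2": 0.95, "R1": 0.4},
}


def initial_state(asm: ModelAssembly, mode: str = "identical-sides",
                  gait: str = "tetrapod"):
    """All legs start grounded in early stance.

    ``identical-sides`` gives every leg the same state (the configuration
    of the bilateral-synchronization experiment); ``per-leg phases``
    staggers the adaptation of the LD half-centers along each side,
    close to the metachronal lags of the requested gait, so the wave
    settles within a cycle or two.
    """
    n = asm.arrays.n_neurons
    nl = len(asm.legs)
    V = np.full(n, -60.0)
    q = np.full(n, 0.02)
    for li, leg in enumerate(asm.legs):
        base = li * N_PER_LEG
        for stance in (PR1, LD1, EF1):
            V[base + stance] = -45.0
        q[base + LD1] = 0.25
        if mode == "per-leg phases":
            phase = _SEED_PHASES.get(gait, _SEED_PHASES["tetrapod"])[leg]
            q[base + LD1] = 0.15 + 0.5 * phase
    m = _minf(V, asm.params.cpg)  # harmless approximation for non-CPG cells
    theta = np.empty(3 * nl)
    for li, leg in enumerate(asm.legs):
        role = wiring.leg_role(leg)
        theta[3 * li + 0] = 78.0          # alpha mid-range
        theta[3 * li + 1] = 30.8          # grounded
        theta[3 * li + 2] = 100.0 if role != "hind" else 55.0
    omega = np.zeros(3 * nl)
    return V, m.copy(), q, theta, omega


# --------------------------------------------------------------------------
# the run loop
# --------------------------------------------------------------------------

def run(asm: ModelAssembly, schedule: Optional[Schedule] = None,
        config: Optional[SimulationConfig] = None) -> TrajectoryRecord:
    """Simulate the assembled model under a behavioral-mode schedule."""
    config = config or SimulationConfig()
    if config.dt <= 0 or config.sample_interval <= 0 or config.t_end < 0:
        raise ValueError("dt, sample_interval must be > 0 and t_end >= 0")
    p = asm.params
    A = asm.arrays
    nl = len(asm.legs)
    n_sub = max(1, int(round(config.sample_interval / config.dt)))
    n_steps = int(round(config.t_end / config.sample_interval))

    ctrl = BehaviorController(asm, schedule)
    if schedule is not None:
        conflicts = schedule.validate()
        if conflicts:
            raise ValueError(f"schedule conflicts: {conflicts}")

    V, m, q, theta, omega = initial_state(asm, config.initial_conditions,
                                          gait=ctrl.gait)

    # index caches
    mn_idx = np.concatenate([li * N_PER_LEG + MN_BASE + np.arange(12)
                             for li in range(nl)])
    relay_idx = np.concatenate([li * N_PER_LEG + RELAY_BASE + np.arange(6)
                                for li in range(nl)])
    cpg_idx = np.concatenate([li * N_PER_LEG + np.arange(6)
                              for li in range(nl)])
    beta_j = np.array([3 * li + 1 for li in range(nl)])

    gexc = np.zeros(A.n_neurons)
    ginh = np.zeros(A.n_neurons)
    gates = GateBank(asm.legs, p.gates)

    jgain = A.jgain.copy()
    if not asm.enable_slow:
        jgain[A.jslow] = 0.0

    times = np.arange(n_steps + 1) * config.sample_interval
    out = np.empty((n_steps + 1, 3 * nl))
    volts = (np.empty((n_steps + 1, A.n_neurons))
             if config.record_voltages else None)
    out[0] = theta
    if volts is not None:
        volts[0] = V
    failure = None

    sensors = compute_sensory_all(asm, theta, omega)
    gates.prime(sensors)

    for step in range(1, n_steps + 1):
        t = step * config.sample_interval

        # ---- compose control conductances for this interval ----
        gexc[:] = 0.0
        ginh[:] = 0.0
        gexc[mn_idx] = p.syn.g_MN
        gexc[relay_idx] = gates.relay_drive(ctrl.gate_override)
        gexc[cpg_idx] = ctrl.drives.ravel()
        # ipsilateral interleg pathways (posterior -> anterior levator CPG)
        for post_leg, ant_leg, gmax in ctrl.interleg_pairs:
            s = sensors[post_leg]
            ginh[asm.neuron(ant_leg, LD0)] += ipsilateral_inhibition(
                s.beta, s.dbeta, gmax, p.interleg)
        # contralateral pathways
        ctrl.apply_contralateral(sensors, gexc, ginh)
        ctrl.apply_overrides(gexc, ginh)

        # ---- advance continuous state ----
        step_network(V, m, q,
                     A.nC, A.ngL, A.nEL, A.ngP, A.nEP, A.nthm, A.nsm,
                     A.ntaum, A.ngq, A.nEK, A.nthq, A.nsq, A.ntauq,
                     A.syn_pre, A.syn_post, A.syn_g, A.syn_E, A.syn_grp,
                     ctrl.grp_gain,
                     gexc, ginh, p.syn.E_ex, p.syn.E_inh,
                     p.syn.th_s, p.syn.s_s,
                     theta, omega, A.jmn, A.jlim, jgain, A.jslow,
                     A.jdamp, A.jinert, p.muscle.th_a, p.muscle.s_a,
                     p.muscle.a_floor, config.dt, n_sub)

        if not np.isfinite(V).all() or not np.isfinite(theta).all():
            failure = {"t": float(t), "reason": "non-finite state"}
            out = out[:step]
            times = times[:step]
            if volts is not None:
                volts = volts[:step]
            break

        # ---- discrete layer ----
        sensors = compute_sensory_all(asm, theta, omega)
        gates.set_backward(ctrl.direction == "backward")
        for ev in gates.update(sensors, t):
            ctrl.events.append(ev)
        ctrl.step(t, sensors)

        out[step] = theta
        if volts is not None:
            volts[step] = V

    rec = TrajectoryRecord(time=times, angles=out, legs=list(asm.legs),
                           events=ctrl.events, voltages=volts,
                           failure=failure)
    return rec


def compute_sensory_all(asm: ModelAssembly, theta, omega):
    sensors = {}
    for li, leg in enumerate(asm.legs):
        sensors[leg] = compute_sensory(
            beta=theta[3 * li + 1], dbeta=omega[3 * li + 1],
            gamma=theta[3 * li + 2])
    return sensors
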