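"""Single-unit dynamics: CPG half-centers, motoneurons, premotor INs.

Every model neuron is a nonspiking 3-variable cell (membrane potential
V, slow activation m of a persistent inward current, adaptation q); a
CPG is two such cells coupled by graded mutual inhibition.  Within the
calibrated drive range the pair produces alternating plateau phases
(antiphase); the adaptation gate terminates each plateau, so stronger
drive shortens the period — the mechanism behind the faster tripod
rhythm.  Strongly depolarized cells are nearly insensitive to
inhibition early in the plateau (the inward current dominates) and
increasingly sensitive towards its end, which is why mid-plateau
interleg inhibition cannot terminate an ongoing swing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from ._kernel import step_network
from .params import (NeuronParams, SynapseParams, ModelParams,
                     CPG_NEURON, MN_FAST, MN_SLOW)


@dataclass
class NeuronState:
    V: float = -60.0
    m: float = 0.0
    q: float = 0.0


@dataclass
class CPGUnit:
    """Half-center oscillator: two mutually inhibitory nonspiking neurons."""

    params: NeuronParams = field(default_factory=lambda: NeuronParams())
    syn: SynapseParams = field(default_factory=SynapseParams)
    g_app: Tuple[float, float] = (0.2, 0.2)


@dataclass
class MotoneuronUnit:
    speed_class: str = "fast"       # fast | slow

    @property
    def params(self) -> NeuronParams:
        return MN_SLOW if self.speed_class == "slow" else MN_FAST


def activation(V, th_a=-35.0, s_a=4.0):
    """Muscle activation as a graded function of MN potential."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(V) - th_a) / s_a))


# --------------------------------------------------------------------------
# a tiny-network integrator on the shared kernel
# --------------------------------------------------------------------------

_EMPTY_J = (np.zeros(0), np.zeros(0), np.zeros((0, 4), dtype=np.int32),
            np.zeros((0, 4)), np.zeros((0, 4)),
            np.zeros((0, 4), dtype=np.bool_), np.zeros(0), np.ones(0))


def _integrate(neurons: Sequence[NeuronParams], synapses, gexc_t, ginh_t,
               duration: float, dt: float = 0.05,
               syn_par: Optional[SynapseParams] = None,
               V0: Optional[np.ndarray] = None):
    """Integrate a small neuron network with per-ms control conductances.

    ``gexc_t``/``ginh_t`` are (n_ms, n_neurons) arrays; returns the
    voltage trace sampled at 1 ms.
    """
    sp = syn_par or SynapseParams()
    n = len(neurons)
    cols = {}
    for k in ("C", "g_L", "E_L", "g_P", "E_P", "th_m", "s_m", "tau_m",
              "g_q", "E_K", "th_q", "s_q", "tau_q"):
        cols[k] = np.array([getattr(p, k) for p in neurons])
    if synapses:
        pre, post, g, E = (np.asarray(x) for x in zip(*synapses))
    else:
        pre = post = np.zeros(0)
        g = E = np.zeros(0)
    pre = pre.astype(np.int32)
    post = post.astype(np.int32)
    grp = np.zeros(len(pre), dtype=np.int8)
    grp_gain = np.ones(3)
    theta, omega, jmn, jlim, jgain, jslow, jdamp, jinert = _EMPTY_J

    n_ms = int(round(duration))
    n_sub = int(round(1.0 / dt))
    V = np.full(n, -60.0) if V0 is None else np.asarray(V0, float).copy()
    m = 1.0 / (1.0 + np.exp(-(V - cols["th_m"]) / cols["s_m"]))
    q = np.zeros(n)
    trace = np.empty((n_ms + 1, n))
    trace[0] = V
    for i in range(n_ms):
        step_network(V, m, q, cols["C"], cols["g_L"], cols["E_L"],
                     cols["g_P"], cols["E_P"], cols["th_m"], cols["s_m"],
                     cols["tau_m"], cols["g_q"], cols["E_K"], cols["th_q"],
                     cols["s_q"], cols["tau_q"],
                     pre, post, g.astype(float), E.astype(float), grp,
                     grp_gain, gexc_t[i], ginh_t[i], sp.E_ex, sp.E_inh,
                     sp.th_s, sp.s_s,
                     theta, omega, jmn, jlim, jgain, jslow, jdamp, jinert,
                     0.0, 4.0, 0.0, dt, n_sub)
        if not np.isfinite(V).all():
            raise FloatingPointError(
                f"integration failure at t={i + 1} ms (non-finite state)")
        trace[i + 1] = V
    return trace


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

@dataclass
class CPGResult:
    V: np.ndarray                 # (n_ms+1, 2), 1-ms sampling
    oscillating: bool
    period: Optional[float]       # ms
    phase_diff: Optional[float]   # fraction of a period (plateau midpoints)


def _plateau_midpoints(x, thresh=-40.0):
    above = x > thresh
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    ons = edges[~above[edges]] + 1
    offs = edges[above[edges]] + 1
    mids = []
    for on in ons:
        later = offs[offs > on]
        if later.size:
            mids.append(0.5 * (on + later[0]))
    return np.asarray(mids)


def measure_rhythm(V: np.ndarray, thresh: float = -40.0,
                   settle: int = 3000) -> Tuple[bool, Optional[float],
                                                Optional[float]]:
    """Oscillation flag, period and antiphase measure of a 2-cell trace.

    The phase difference is taken between plateau midpoints of the two
    cells, in units of the period; for an antiphase half-center it is
    0.5 regardless of the duty-cycle asymmetry of the two plateaus.
    """
    x = V[settle:, 0]
    y = V[settle:, 1]
    mids_x = _plateau_midpoints(x, thresh)
    if len(mids_x) < 3 or x.max() - x.min() < 15.0:
        return False, None, None
    period = float(np.mean(np.diff(mids_x)))
    mids_y = _plateau_midpoints(y, thresh)
    if len(mids_y) < 2:
        return True, period, None
    ph = []
    for mx in mids_x[:-1]:
        later = mids_y[mids_y > mx]
        if later.size:
            ph.append(((later[0] - mx) % period) / period)
    return True, period, (float(np.mean(ph)) if ph else None)


def simulate_cpg(drive: Tuple[float, float], duration: float = 12000.0,
                 external_inhibition: Optional[np.ndarray] = None,
                 params: Optional[NeuronParams] = None,
                 syn: Optional[SynapseParams] = None,
                 dt: float = 0.05) -> CPGResult:
    """Simulate one half-center CPG under constant drive.

    ``external_inhibition`` is an optional (n_ms, 2) inhibitory
    conductance signal.  Zero drive leaves the unit quiescent; in the
    calibrated range both cells oscillate with a common period in
    antiphase, and the period decreases with drive.
    """
    p = params or CPG_NEURON
    sp = syn or SynapseParams()
    n_ms = int(round(duration))
    gexc = np.tile(np.asarray(drive, float), (n_ms, 1))
    if external_inhibition is None:
        ginh = np.zeros((n_ms, 2))
    else:
        ginh = np.asarray(external_inhibition, float)
        if ginh.shape != (n_ms, 2):
            raise ValueError("external_inhibition must have shape "
                             f"({n_ms}, 2), got {ginh.shape}")
    synapses = [(0, 1, sp.g_cpg_inh, sp.E_inh), (1, 0, sp.g_cpg_inh, sp.E_inh)]
    V = _integrate([p, p], synapses, gexc, ginh, duration, dt, sp,
                   V0=np.array([-60.0, -55.0]))
    osc, period, phase = measure_rhythm(V, settle=min(3000, n_ms // 3))
    return CPGResult(V=V, oscillating=osc, period=period, phase_diff=phase)


def inhibition_response(drive: Tuple[float, float], pulse_start: float,
                        pulse_duration: float, g_pulse: float,
                        duration: float = 12000.0,
                        params: Optional[NeuronParams] = None,
                        syn: Optional[SynapseParams] = None) -> dict:
    """Apply an inhibitory pulse to cell 0 during one of its plateaus.

    Returns the plateau end times of the perturbed and unperturbed runs
    and whether the plateau persisted (shortening < 5%).  Raises
    ``ValueError`` if the pulse does not fall inside a plateau of the
    unperturbed rhythm.
    """
    if not 0 <= pulse_start < duration:
        raise ValueError("pulse outside simulated window")
    base = simulate_cpg(drive, duration, params=params, syn=syn)
    x = base.V[:, 0]
    above = x > -40.0
    i0 = int(pulse_start)
    if not (above[i0] and above[min(int(pulse_start + pulse_duration),
                                    len(x) - 1)]):
        raise ValueError("pulse not inside a plateau of cell 0")
    on = i0
    while on > 0 and above[on - 1]:
        on -= 1

    def plateau_end(trace, start, sustain=60):
        # first time the cell falls below threshold and stays there:
        # a transient dip during a pulse does not end the plateau
        t = start
        while t < len(trace) - sustain:
            if (trace[t:t + sustain] < -40.0).all():
                return t
            t += 1
        return len(trace) - 1

    off = plateau_end(x, i0)
    n_ms = int(round(duration))
    ginh = np.zeros((n_ms, 2))
    ginh[int(pulse_start):int(pulse_start + pulse_duration), 0] = g_pulse
    pert = simulate_cpg(drive, duration, external_inhibition=ginh,
                        params=params, syn=syn)
    xp = pert.V[:, 0]
    offp = plateau_end(xp, i0)
    full = off - on
    remaining = off - i0
    remaining_pert = offp - i0
    shortening = (off - offp) / full
    return {"plateau_on": on, "plateau_off": off, "plateau_off_perturbed": offp,
            "remaining": remaining, "remaining_perturbed": remaining_pert,
            "shortening_fraction": float(shortening),
            # a pulse may slightly *lengthen* the plateau (hyperpolarization
            # slows the adaptation); only premature termination counts
            "persists": bool(shortening < 0.05)}


def mn_activity(speed_class: str, cpg_drive: np.ndarray,
                premotor_inhibition: np.ndarray,
                params: Optional[ModelParams] = None) -> np.ndarray:
    """Activity trace of one motoneuron under sampled conductance input.

    ``cpg_drive`` and ``premotor_inhibition`` are per-ms excitatory and
    inhibitory conductance signals on a common time grid.  Slow MNs have
    three times the adaptation conductance of fast MNs, hence stronger
    activity adaptation under identical input.
    """
    cpg_drive = np.asarray(cpg_drive, float)
    premotor_inhibition = np.asarray(premotor_inhibition, float)
    if cpg_drive.shape != premotor_inhibition.shape:
        raise ValueError("input signals must share one time grid; got "
                         f"{cpg_drive.shape} vs {premotor_inhibition.shape}")
    mp = params or ModelParams()
    p = mp.mn_slow if speed_class == "slow" else mp.mn_fast
    n_ms = len(cpg_drive)
    V = _integrate([p], [], cpg_drive[:, None], premotor_inhibition[:, None],
                   float(n_ms), syn_par=mp.syn)
    return activation(V[1:, 0], mp.muscle.th_a, mp.muscle.s_a)
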