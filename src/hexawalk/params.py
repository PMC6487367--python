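"""Parameter tables for the six-leg stick-insect walking model.

Units throughout: time in ms, voltage in mV, conductance in uS, capacitance
in nF (so conductance * voltage = current in nA), angles in degrees.

The network architecture (which neuron talks to which) is fixed by
:mod:`hexawalk.wiring`; everything quantitative lives here.  The default
values are a single calibration of the model: they place the
levator-depressor half-center oscillators in a regime where the step period
is ~1.9 s under tetrapod drive and ~1.2 s under tripod drive, with the
swing fraction of the cycle near one third, and they make the joints fast
enough (tens of ms) that the ~200 ms stop manoeuvre is mechanically
possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Dict, Tuple

import yaml


# --------------------------------------------------------------------------
# neurons
# --------------------------------------------------------------------------

@dataclass
class NeuronParams:
    """Membrane parameters of one 3-variable nonspiking model neuron.

    The neuron carries a leak current, a persistent inward current with
    slow activation gate ``m``, and an adaptation (outward) current with
    very slow gate ``q``:

        C dV/dt = -g_L (V-E_L) - g_P m (V-E_P) - g_q q (V-E_K) - I_syn
        dm/dt   = (m_inf(V) - m) / tau_m
        dq/dt   = (q_inf(V) - q) / tau_q

    with Boltzmann steady states ``x_inf(V) = 1/(1+exp(-(V-th_x)/s_x))``.
    """

    C: float = 1.0
    g_L: float = 0.1
    E_L: float = -60.0
    g_P: float = 0.5
    E_P: float = 0.0
    th_m: float = -40.0
    s_m: float = 4.0
    tau_m: float = 15.0
    g_q: float = 0.6
    E_K: float = -80.0
    th_q: float = -38.0
    s_q: float = 4.0
    tau_q: float = 500.0


#: CPG half-center neurons: bistable membrane (large g_P) with slow
#: adaptation that terminates the plateau and sets the step period.
CPG_NEURON = NeuronParams()

#: Motoneurons: no intrinsic plateau (small g_P), faster adaptation.
#: ``g_q`` given per speed class below.
MN_FAST = NeuronParams(g_P=0.1, tau_m=8.0, g_q=0.1, tau_q=150.0)
MN_SLOW = NeuronParams(g_P=0.1, tau_m=8.0, g_q=0.3, tau_q=150.0)  # 3 x fast g_q

#: Premotor and sensory-relay interneurons: graded followers (no
#: latching plateau: their persistent current is kept weak or absent).
IN_PREMOTOR = NeuronParams(g_P=0.05, tau_m=8.0, g_q=0.05, tau_q=300.0)
IN_RELAY = NeuronParams(g_P=0.0, tau_m=8.0, g_q=0.0, tau_q=300.0)


@dataclass
class SynapseParams:
    """Global synaptic transfer and reversal potentials.

    Synapses are instantaneous and graded: the postsynaptic conductance is
    ``g_max * s(V_pre)`` with the sigmoid ``s`` below (no synaptic state
    variables, preserving the 3-ODE-per-neuron count).
    """

    th_s: float = -40.0
    s_s: float = 3.0
    E_ex: float = 0.0
    E_inh: float = -75.0
    #: CPG mutual inhibition
    g_cpg_inh: float = 0.4
    #: CPG neuron -> premotor IN excitation
    g_cpg_in: float = 0.5
    #: premotor IN -> MN inhibition
    g_in_mn: float = 1.0
    #: relay IN -> CPG neuron, per local network (the LD pathway acts
    #: through the same channel during walking and still stand; the
    #: relay sigmoid makes the weak walking gate value a small input and
    #: the large still-stand value a commanding one)
    g_relay_pr: float = 0.3
    g_relay_ld: float = 0.3
    g_relay_ef: float = 0.3
    #: tonic central excitatory drive to every MN (same for all MNs)
    g_MN: float = 0.3
    #: tonic drive to premotor INs (so that inhibition g_d can silence them)
    g_IN_tonic: float = 0.0


# --------------------------------------------------------------------------
# drive (g_app) tables
# --------------------------------------------------------------------------

@dataclass
class DriveTable:
    """Drive conductance pairs (swing-phase neuron, stance-phase neuron)
    for the three local networks of one leg, for one gait."""

    pr: Tuple[float, float] = (0.22, 0.10)
    ld: Tuple[float, float] = (0.20, 0.295)
    ef: Tuple[float, float] = (0.22, 0.10)


#: Gait drive tables.  Only the LD pair differs between gaits: it is the
#: rhythm generator; PR and EF are slaved to the leg's own sensory gates.
DRIVES = {
    "tetrapod": DriveTable(ld=(0.20, 0.295)),
    "tripod": DriveTable(ld=(0.26, 0.32)),
}

#: EF drive for search movements of a front leg (fast symmetric tibia
#: oscillation, period a few hundred ms).
SEARCH_EF_DRIVE = (0.40, 0.40)


# --------------------------------------------------------------------------
# muscles / joints
# --------------------------------------------------------------------------

JOINT_LIMITS = {
    "alpha": (28.0, 128.0),   # protracted .. retracted
    "beta": (30.0, 60.0),     # ground contact .. fully lifted
    "gamma": (45.0, 110.0),   # stretched .. flexed
}

CONTACT_BAND = (30.0, 32.0)   # 30 <= beta < 32 signals ground contact
SWING_THRESHOLD = 32.0        # beta above this: swing phase (classifier)


@dataclass
class MusclePairParams:
    """One antagonistic muscle pair driving one joint (second-order ODE).

    ``J * theta'' = sum_i gain_i * a_i * (lim_i - theta) - c * theta'``

    where ``a_i`` are the four muscle activations (fast/slow x both sides)
    and ``lim_i`` the angle towards which each muscle pulls.  The
    saturating restoring form makes the joint limits attracting
    equilibria rather than hard clips.
    """

    inertia: float = 1.0          # deg ms^2 per unit torque
    damping: float = 0.35         # 1/ms
    gain_fast: float = 0.014      # 1/ms^2 per unit activation
    gain_slow: float = 0.00025    # slow-muscle torque gain (small)
    tau_act_fast: float = 15.0    # fast-muscle activation time constant
    tau_act_slow: float = 150.0   # slow-muscle activation time constant
    #: muscle activation as a function of MN potential, with a small
    #: recruitment threshold (a resting MN produces no force)
    th_a: float = -35.0
    s_a: float = 4.0
    a_floor: float = 0.01


# --------------------------------------------------------------------------
# sensory gates (intraleg coordination)
# --------------------------------------------------------------------------

@dataclass
class GateParams:
    """Binary low/high sensory gates feeding the CPGs via relay INs.

    ``g_beta_pr`` and ``g_beta_ef`` switch low->high when beta falls
    through ``beta_crit`` (shortly before ground contact) and back
    high->low when beta rises through ``beta_crit + hysteresis``.
    ``g_gamma_ld`` follows the same automaton on gamma at ``gamma_crit``.
    Values are the conductances injected into the relay interneurons.
    """

    beta_crit: float = 33.0
    gamma_crit: float = 75.0
    hysteresis: float = 2.0
    pr_low: float = 0.0
    pr_high: float = 0.30
    ef_low: float = 0.0
    ef_high: float = 0.30
    ld_low: float = 0.0
    ld_high: float = 0.03


@dataclass
class StopGateParams:
    """Static gate levels imposed during still stand (per leg role)."""

    pr_front: float = 0.0     # g_beta -> 0: protract
    pr_other: float = 0.5     # g_beta high: retract
    ld_all: float = 0.5       # g_gamma large: robust ground contact
    ef_front_mid: float = 0.0  # very low: stay extended
    ef_hind: float = 0.5      # large: extended via the crossed premotor map


# --------------------------------------------------------------------------
# interleg coordination
# --------------------------------------------------------------------------

@dataclass
class InterlegParams:
    """Ipsilateral inhibitory pathways onto anterior levator CPG neurons.

    The posterior leg's vertical position and movement direction set the
    inhibition through a quadrant rule: while the posterior leg is in
    swing (lifted above the contact band) or being lifted off, the
    anterior leg's levator CPG neuron is inhibited; while the posterior
    leg is grounded, a small tonic level remains.  This produces the
    back-to-front metachronal wave of stepping.
    """

    g_inh3: float = 0.12      # onto prothoracic (front) levator CPG neuron
    g_inh9: float = 0.12      # onto mesothoracic (middle) levator CPG neuron
    tonic_fraction: float = 0.7  # grounded & stationary posterior leg
    lift_threshold: float = 32.0
    #: levation velocity that counts as an ongoing liftoff (well above
    #: the slow-muscle contact-band ripple)
    rising_eps: float = 0.05
    falling_eps: float = 0.02
    #: posterior beta below which its descent releases the anterior leg
    beta_release: float = 40.0
    #: inhibition level during the release window (fraction of g_max);
    #: sits between the escape thresholds of the slow and fast rhythm,
    #: so the release advances liftoff in tetrapod but not in tripod
    release_fraction: float = 0.0


@dataclass
class ContralateralConfig:
    """Contralateral connections (all default on; the two inhibitory
    variants reproduce the configurations in which the tripod transition
    fails and are off by default)."""

    l2_to_r3_excitation: bool = True
    front_pair: bool = True
    hind_pair: bool = True
    pair_mutual_inhibition: bool = True
    l2_to_r2_inhibition: bool = False
    l3_to_r3_inhibition: bool = False
    #: conductance of the L2 -> R3 levator excitation while L2 is lifted
    g_l2r3: float = 0.12
    #: resting transfer of that synapse (a graded synapse never shuts
    #: completely); the single left/right parameter asymmetry of the model
    g_l2r3_rest: float = 0.0005
    #: conductance of the experimental inhibitory variants
    g_contra_inh: float = 0.12


# --------------------------------------------------------------------------
# behavior control
# --------------------------------------------------------------------------

@dataclass
class TransitionRules:
    """Thresholds of the behavioral-mode controllers."""

    #: tripod initiation: leg lifted above this and rising
    beta_min: float = 40.0
    #: tetrapod initiation: d(beta)/dt of middle and hind leg below this
    #: small positive bound (may be negative)
    eps_tet: float = 0.01
    #: backward start: beta of L2 or R2 within delta_back of the 60 deg max
    delta_back: float = 2.0
    #: duration of the "transition initiation" phase during which the
    #: contralateral pathways act, after the first side initiates
    tripod_window: float = 2500.0
    #: pose tolerance for judging stop completion (deg)
    pose_tol: float = 1.0


@dataclass
class SimulationConfig:
    """Integration and output settings."""

    t_end: float = 13000.0
    dt: float = 0.05            # inner fixed integration step (ms)
    sample_interval: float = 1.0  # output sampling / supervision step (ms)
    enable_slow: bool = True
    initial_conditions: str = "identical-sides"
    record_voltages: bool = False
    seed: int = 0               # used only by fixture jitter elsewhere


# --------------------------------------------------------------------------
# the full parameter bundle
# --------------------------------------------------------------------------

@dataclass
class ModelParams:
    cpg: NeuronParams = field(default_factory=lambda: replace(CPG_NEURON))
    mn_fast: NeuronParams = field(default_factory=lambda: replace(MN_FAST))
    mn_slow: NeuronParams = field(default_factory=lambda: replace(MN_SLOW))
    in_premotor: NeuronParams = field(default_factory=lambda: replace(IN_PREMOTOR))
    in_relay: NeuronParams = field(default_factory=lambda: replace(IN_RELAY))
    syn: SynapseParams = field(default_factory=SynapseParams)
    muscle: MusclePairParams = field(default_factory=MusclePairParams)
    gates: GateParams = field(default_factory=GateParams)
    stop_gates: StopGateParams = field(default_factory=StopGateParams)
    interleg: InterlegParams = field(default_factory=InterlegParams)
    contralateral: ContralateralConfig = field(default_factory=ContralateralConfig)
    rules: TransitionRules = field(default_factory=TransitionRules)
    drives: Dict[str, DriveTable] = field(
        default_factory=lambda: {k: replace(v) for k, v in DRIVES.items()})

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "ModelParams":
        """Load parameter overrides from a YAML file of nested namespaces."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        p = cls()
        for ns, values in raw.items():
            if not hasattr(p, ns):
                raise KeyError(f"unknown parameter namespace: {ns!r}")
            target = getattr(p, ns)
            if ns == "drives":
                for gait, tab in values.items():
                    target[gait] = DriveTable(**{k: tuple(v) for k, v in tab.items()})
                continue
            for key, val in values.items():
                if not hasattr(target, key):
                    raise KeyError(f"unknown parameter: {ns}.{key}")
                setattr(target, key, tuple(val) if isinstance(val, list) else val)
        return p


def default_params() -> ModelParams:
    return ModelParams()
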