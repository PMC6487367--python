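"""Structural assembly of the six-leg network.

Index conventions
-----------------
Legs are ordered ``L1, L2, L3, R1, R2, R3`` (front, middle, hind per side).
Each leg contributes 36 neurons:

===========  =====================================================
local index  neuron
===========  =====================================================
0..5         CPG half-center neurons: PR0, PR1, LD0, LD1, EF0, EF1
             (X0 = swing-phase neuron, X1 = stance-phase neuron;
             LD0 is the levator neuron targeted by the interleg and
             contralateral pathways)
6..17        premotor interneurons, one per motoneuron
18..29       motoneurons, fast/slow per muscle, in muscle order
             P, R, L, D, E, F (protractor, retractor, levator,
             depressor, extensor, flexor)
30..35       sensory-relay interneurons: PRa, PRb, LDa, LDb, EFa, EFb
===========  =====================================================

Totals: 6 CPG neurons (3 CPGs), 12 MNs, 12 premotor + 6 relay INs per leg;
times six legs: 18 CPGs, 72 MNs, 108 INs, 216 neurons, 648 first-order
ODEs, plus 18 second-order joint ODEs.

The premotor map realizes the phase semantics: the premotor IN of a
motoneuron is excited by one CPG neuron and inhibits its MN, so the MN is
active in antiphase with that CPG neuron.  Swapping which CPG neuron
drives which premotor IN (presynaptic inhibition of one map, release of
the mirrored one) exchanges the muscle roles; this is how backward
walking re-purposes the PR networks of all legs and the EF networks of
the front and hind legs.  The hind-leg EF map is crossed relative to the
front legs already in forward walking (extensor active during stance:
hind legs push), which is the cross connection that makes a *large*
EF gate value produce the extended tibia during still stand in the hind
legs while the front and middle legs need a *low* one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List

import numpy as np

from .params import ModelParams, ContralateralConfig

LEGS = ["L1", "L2", "L3", "R1", "R2", "R3"]
N_PER_LEG = 36
MUSCLES = ["P", "R", "L", "D", "E", "F"]
MUSCLE_TARGET = {"P": 28.0, "R": 128.0, "L": 60.0, "D": 30.0, "E": 45.0, "F": 110.0}
JOINTS = ["alpha", "beta", "gamma"]

# local CPG neuron indices
PR0, PR1, LD0, LD1, EF0, EF1 = range(6)
IN_BASE, MN_BASE, RELAY_BASE = 6, 18, 30

# synapse groups
GRP_STATIC, GRP_FWD, GRP_BWD = 0, 1, 2


def mn_local(muscle: str, slow: bool) -> int:
    return MN_BASE + 2 * MUSCLES.index(muscle) + (1 if slow else 0)


def in_local(muscle: str, slow: bool) -> int:
    return IN_BASE + 2 * MUSCLES.index(muscle) + (1 if slow else 0)


def leg_role(leg: str) -> str:
    return {"1": "front", "2": "middle", "3": "hind"}[leg[1]]


@dataclass
class NetworkArrays:
    """Flat per-neuron / per-synapse / per-joint arrays for the kernel."""

    n_neurons: int
    nC: np.ndarray
    ngL: np.ndarray
    nEL: np.ndarray
    ngP: np.ndarray
    nEP: np.ndarray
    nthm: np.ndarray
    nsm: np.ndarray
    ntaum: np.ndarray
    ngq: np.ndarray
    nEK: np.ndarray
    nthq: np.ndarray
    nsq: np.ndarray
    ntauq: np.ndarray
    syn_pre: np.ndarray
    syn_post: np.ndarray
    syn_g: np.ndarray
    syn_E: np.ndarray
    syn_grp: np.ndarray
    jmn: np.ndarray
    jlim: np.ndarray
    jgain: np.ndarray
    jslow: np.ndarray
    jdamp: np.ndarray
    jinert: np.ndarray


@dataclass
class ModelAssembly:
    """An assembled model: structure + parameters + index maps."""

    params: ModelParams
    legs: List[str]
    arrays: NetworkArrays
    enable_slow: bool = True
    synapse_list: list = field(default_factory=list)

    # ---- index helpers -------------------------------------------------
    def leg_index(self, leg: str) -> int:
        return self.legs.index(leg)

    def neuron(self, leg: str, local: int) -> int:
        return self.leg_index(leg) * N_PER_LEG + local

    def joint(self, leg: str, joint: str) -> int:
        return self.leg_index(leg) * 3 + JOINTS.index(joint)

    # ---- structural counts --------------------------------------------
    @property
    def counts(self) -> dict:
        nl = len(self.legs)
        return {
            "legs": nl,
            "cpgs": 3 * nl,
            "motoneurons": 12 * nl,
            "interneurons": 18 * nl,
            "neurons": N_PER_LEG * nl,
            "neuronal_first_order_odes": 3 * N_PER_LEG * nl,
            "muscle_second_order_odes": 3 * nl,
            "neuromuscular_units": 3 * nl,
        }

    def summary_json(self) -> str:
        return json.dumps({
            "legs": self.legs,
            "counts": self.counts,
            "synapses": self.synapse_list,
            "slow_muscles_enabled": self.enable_slow,
        }, indent=1)


def _neuron_rows(model: ModelParams, legs: List[str]):
    """Per-neuron membrane-parameter table."""
    n = N_PER_LEG * len(legs)
    cols = {k: np.empty(n) for k in
            ("C", "g_L", "E_L", "g_P", "E_P", "th_m", "s_m", "tau_m",
             "g_q", "E_K", "th_q", "s_q", "tau_q")}

    def put(gidx, p):
        for k in cols:
            cols[k][gidx] = getattr(p, k)

    for li in range(len(legs)):
        base = li * N_PER_LEG
        for loc in range(6):
            put(base + loc, model.cpg)
        for mi in range(6):
            for sl in (0, 1):
                put(base + IN_BASE + 2 * mi + sl, model.in_premotor)
                put(base + MN_BASE + 2 * mi + sl,
                    model.mn_slow if sl else model.mn_fast)
        for loc in range(RELAY_BASE, RELAY_BASE + 6):
            put(base + loc, model.in_relay)
    return cols


def build(model: ModelParams, legs=None, enable_slow: bool = True) -> ModelAssembly:
    """Assemble the network for the given legs (default: all six).

    Raises ``ValueError`` on inconsistent configuration.
    """
    legs = list(LEGS) if legs is None else list(legs)
    for leg in legs:
        if leg not in LEGS:
            raise ValueError(f"unknown leg {leg!r}")
    contra = model.contralateral
    if (contra.l2_to_r2_inhibition or contra.l3_to_r3_inhibition) and not (
            "L2" in legs or "L3" in legs):
        raise ValueError("contralateral variant requested without left legs")

    syn = model.syn
    pre, post, g, E, grp = [], [], [], [], []
    listing = []

    def add(p, o, gmax, Erev, group, label):
        pre.append(p); post.append(o); g.append(gmax); E.append(Erev)
        grp.append(group); listing.append(
            {"pre": int(p), "post": int(o), "g": float(gmax),
             "E": float(Erev), "group": int(group), "label": label})

    for li, leg in enumerate(legs):
        base = li * N_PER_LEG
        role = leg_role(leg)

        # CPG mutual inhibition (half-centers)
        for a, b in ((PR0, PR1), (LD0, LD1), (EF0, EF1)):
            add(base + a, base + b, syn.g_cpg_inh, syn.E_inh, GRP_STATIC,
                f"{leg} cpg {a}->{b}")
            add(base + b, base + a, syn.g_cpg_inh, syn.E_inh, GRP_STATIC,
                f"{leg} cpg {b}->{a}")

        # CPG -> premotor IN excitation.  The IN of muscle X is driven by
        # the CPG neuron of the phase in which X must be *silent*.
        def premap(muscle, cpg_local, group):
            for sl in (0, 1):
                add(base + cpg_local, base + in_local(muscle, sl),
                    syn.g_cpg_in, syn.E_ex, group,
                    f"{leg} cpg->in {muscle}{'S' if sl else 'F'}")

        # PR: protractor swing-active (forward); swapped when backward
        premap("P", PR1, GRP_FWD); premap("R", PR0, GRP_FWD)
        premap("P", PR0, GRP_BWD); premap("R", PR1, GRP_BWD)
        # LD: levator swing-active, always
        premap("L", LD1, GRP_STATIC); premap("D", LD0, GRP_STATIC)
        # EF: front/middle forward = extensor swing-active; hind crossed.
        # Front and hind swap their maps during backward walking.
        if role in ("front", "hind"):
            fwd_cross = role == "hind"
            premap("E", EF0 if fwd_cross else EF1, GRP_FWD)
            premap("F", EF1 if fwd_cross else EF0, GRP_FWD)
            premap("E", EF1 if fwd_cross else EF0, GRP_BWD)
            premap("F", EF0 if fwd_cross else EF1, GRP_BWD)
        else:
            premap("E", EF1, GRP_STATIC)
            premap("F", EF0, GRP_STATIC)

        # premotor IN -> MN inhibition
        for mi, muscle in enumerate(MUSCLES):
            for sl in (0, 1):
                add(base + in_local(muscle, sl), base + mn_local(muscle, sl),
                    syn.g_in_mn, syn.E_inh, GRP_STATIC,
                    f"{leg} in->mn {muscle}{'S' if sl else 'F'}")

        # sensory relay INs -> CPG: relay a excites the stance-phase
        # neuron, relay b inhibits the swing-phase neuron.
        for k, (a_loc, swing, stance, gg) in enumerate((
                (RELAY_BASE + 0, PR0, PR1, syn.g_relay_pr),
                (RELAY_BASE + 2, LD0, LD1, syn.g_relay_ld),
                (RELAY_BASE + 4, EF0, EF1, syn.g_relay_ef))):
            add(base + a_loc, base + stance, gg, syn.E_ex, GRP_STATIC,
                f"{leg} relay-a net{k}")
            add(base + a_loc + 1, base + swing, gg, syn.E_inh,
                GRP_STATIC, f"{leg} relay-b net{k}")

    # joints
    nl = len(legs)
    jmn = np.full((3 * nl, 4), -1, dtype=np.int32)
    jlim = np.zeros((3 * nl, 4))
    jgain = np.zeros((3 * nl, 4))
    jslow = np.zeros((3 * nl, 4), dtype=np.bool_)
    mp = model.muscle
    joint_muscles = {"alpha": ("P", "R"), "beta": ("L", "D"),
                     "gamma": ("E", "F")}
    for li in range(nl):
        base = li * N_PER_LEG
        for ji, jname in enumerate(JOINTS):
            j = li * 3 + ji
            ago, ant = joint_muscles[jname]
            for u, (muscle, sl) in enumerate(
                    ((ago, 0), (ago, 1), (ant, 0), (ant, 1))):
                jmn[j, u] = base + mn_local(muscle, bool(sl))
                jlim[j, u] = MUSCLE_TARGET[muscle]
                jgain[j, u] = (mp.gain_slow if sl else mp.gain_fast)
                if sl and not enable_slow:
                    jgain[j, u] = 0.0
                jslow[j, u] = bool(sl)

    rows = _neuron_rows(model, legs)
    arrays = NetworkArrays(
        n_neurons=N_PER_LEG * nl,
        nC=rows["C"], ngL=rows["g_L"], nEL=rows["E_L"], ngP=rows["g_P"],
        nEP=rows["E_P"], nthm=rows["th_m"], nsm=rows["s_m"],
        ntaum=rows["tau_m"], ngq=rows["g_q"], nEK=rows["E_K"],
        nthq=rows["th_q"], nsq=rows["s_q"], ntauq=rows["tau_q"],
        syn_pre=np.asarray(pre, dtype=np.int32),
        syn_post=np.asarray(post, dtype=np.int32),
        syn_g=np.asarray(g, dtype=np.float64),
        syn_E=np.asarray(E, dtype=np.float64),
        syn_grp=np.asarray(grp, dtype=np.int8),
        jmn=jmn, jlim=jlim, jgain=jgain, jslow=jslow,
        jdamp=np.full(3 * nl, mp.damping),
        jinert=np.full(3 * nl, mp.inertia),
    )
    return ModelAssembly(params=model, legs=legs, arrays=arrays,
                         enable_slow=enable_slow, synapse_list=listing)


def assemble(model: ModelParams | None = None, legs=None,
             enable_slow: bool = True) -> ModelAssembly:
    """Public constructor (default parameters, all six legs)."""
    return build(model or ModelParams(), legs=legs, enable_slow=enable_slow)
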