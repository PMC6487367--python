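"""One leg's sensory signals and intraleg coordination gates.

The leg's own movement generates the sensory signals that close the
intraleg loop: the levation angle beta (vertical position, with the
30-32 deg band signalling ground contact), its angular velocity, and the
tibia angle gamma.  Binary low/high gate conductances derived from these
signals feed the three local CPGs through the sensory-relay
interneurons: the PR and EF gates switch high when beta falls through a
critical value shortly before ground contact (and drive the stance-phase
CPG neurons), the LD gate follows gamma.  Switching is
direction-dependent with hysteresis, so one step cycle produces exactly
one low->high and one high->low transition per gate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .params import GateParams, CONTACT_BAND, ModelParams, DRIVES
from . import wiring


@dataclass
class SensorySignals:
    beta: float
    dbeta: float
    gamma: float
    ground_contact: bool


def compute_sensory(beta: float, dbeta: float, gamma: float) -> SensorySignals:
    """Sensory signals of one leg from its joint state."""
    lo, hi = CONTACT_BAND
    return SensorySignals(beta=beta, dbeta=dbeta, gamma=gamma,
                          ground_contact=bool(lo <= beta < hi))


@dataclass
class GateState:
    """Low/high state of the three gates of one leg."""

    pr_high: bool = True
    ef_high: bool = True
    ld_high: bool = False


class GateAutomaton:
    """Direction-dependent threshold switch with hysteresis.

    Switches low->high when the signal *falls* through ``crit`` and
    high->low when it *rises* through ``crit + hyst``; insensitive to
    crossings in the opposite direction.  ``mirrored=True`` reverses
    both directions (used by the hind legs' LD gate, whose tibia moves
    in counterphase because the hind extensor is the stance muscle).
    """

    def __init__(self, crit: float, hyst: float, high: bool = False,
                 mirrored: bool = False):
        self.crit = crit
        self.hyst = hyst
        self.high = high
        self.mirrored = mirrored
        self._prev: Optional[float] = None

    def prime(self, value: float) -> None:
        self._prev = value

    def update(self, value: float) -> Optional[str]:
        prev = self._prev if self._prev is not None else value
        self._prev = value
        if self.mirrored:
            rise_to_high = (not self.high and prev < self.crit <= value)
            fall_to_low = (self.high and prev > self.crit - self.hyst >= value)
        else:
            rise_to_high = (not self.high and prev > self.crit >= value)
            fall_to_low = (self.high and prev < self.crit + self.hyst <= value)
        if rise_to_high:
            self.high = True
            return "low->high"
        if fall_to_low:
            self.high = False
            return "high->low"
        return None


def update_gates(signals: SensorySignals, prev: GateState,
                 params: GateParams) -> GateState:
    """Functional single-shot form of the gate automaton.

    Uses the previous state plus the instantaneous signal and its
    direction of motion; the stateful :class:`GateBank` is what the
    engine runs, this form is for direct rule inspection.
    """
    new = GateState(prev.pr_high, prev.ef_high, prev.ld_high)
    falling = signals.dbeta < 0
    rising = signals.dbeta > 0
    for attr, crit in (("pr_high", params.beta_crit),
                       ("ef_high", params.beta_crit)):
        high = getattr(prev, attr)
        if not high and falling and signals.beta <= crit:
            setattr(new, attr, True)
        elif high and rising and signals.beta >= crit + params.hysteresis:
            setattr(new, attr, False)
    g_falling = True  # direction resolved inside the stateful automaton
    if not prev.ld_high and signals.gamma <= params.gamma_crit and g_falling:
        new.ld_high = True
    elif prev.ld_high and signals.gamma >= params.gamma_crit + params.hysteresis:
        new.ld_high = False
    return new


class GateBank:
    """All gate automata of an assembly plus their relay-drive vector."""

    def __init__(self, legs: List[str], params: GateParams):
        self.legs = legs
        self.p = params
        self.pr = {leg: GateAutomaton(params.beta_crit, params.hysteresis,
                                      high=True) for leg in legs}
        self.ef = {leg: GateAutomaton(params.beta_crit, params.hysteresis,
                                      high=True) for leg in legs}
        self.ld = {leg: GateAutomaton(params.gamma_crit, params.hysteresis,
                                      mirrored=wiring.leg_role(leg) == "hind")
                   for leg in legs}
        self._backward = False

    def set_backward(self, backward: bool) -> None:
        """Track the walking direction: the LD gate reads the tibia
        angle, whose movement phase follows the active extensor-flexor
        premotor map.  Front and hind legs exchange maps during backward
        walking, so their gate automata exchange direction too."""
        if backward == self._backward:
            return
        self._backward = backward
        for leg in self.legs:
            role = wiring.leg_role(leg)
            if role in ("front", "hind"):
                self.ld[leg].mirrored = (role == "hind") != backward

    def prime(self, sensors: Dict[str, SensorySignals]) -> None:
        for leg in self.legs:
            self.pr[leg].prime(sensors[leg].beta)
            self.ef[leg].prime(sensors[leg].beta)
            self.ld[leg].prime(sensors[leg].gamma)

    def update(self, sensors: Dict[str, SensorySignals], t: float):
        events = []
        for leg in self.legs:
            for name, bank, sig in (("g_beta_PR", self.pr, sensors[leg].beta),
                                    ("g_beta_EF", self.ef, sensors[leg].beta),
                                    ("g_gamma_LD", self.ld, sensors[leg].gamma)):
                flip = bank[leg].update(sig)
                if flip:
                    events.append({"t": float(t), "kind": "gate",
                                   "leg": leg, "gate": name,
                                   "transition": flip})
        return events

    def state(self, leg: str) -> GateState:
        return GateState(self.pr[leg].high, self.ef[leg].high,
                         self.ld[leg].high)

    def relay_drive(self, override) -> np.ndarray:
        """Relay-IN drive conductances, 6 per leg (a/b pairs share the
        gate value).  ``override`` maps leg -> (pr, ld, ef) static values
        imposed by the behavior controller (still stand), or None."""
        p = self.p
        vals = np.empty(6 * len(self.legs))
        for li, leg in enumerate(self.legs):
            ov = override.get(leg) if override else None
            if ov is not None:
                pr, ld, ef = ov
            else:
                pr = p.pr_high if self.pr[leg].high else p.pr_low
                ef = p.ef_high if self.ef[leg].high else p.ef_low
                ld = p.ld_high if self.ld[leg].high else p.ld_low
            vals[6 * li:6 * li + 6] = (pr, pr, ld, ld, ef, ef)
        return vals


def simulate_single_leg(duration: float = 10000.0, gait: str = "tetrapod",
                        leg: str = "L2", drives=None,
                        params: Optional[ModelParams] = None,
                        enable_slow: bool = True):
    """Simulate one isolated leg (intraleg gates active, no interleg input).

    Returns the trajectory record of the single-leg assembly.  A leg on
    its own steps periodically: beta alternates between the contact band
    and swing with a stable period set by the drive level.
    """
    from . import engine
    from .params import SimulationConfig
    p = params or ModelParams()
    if drives is not None:
        from .params import DriveTable
        p.drives = dict(p.drives)
        p.drives[gait] = DriveTable(ld=tuple(drives)) if not hasattr(
            drives, "ld") else drives
    asm = wiring.build(p, legs=[leg], enable_slow=enable_slow)
    from .control import Schedule
    sched = Schedule(initial_gait=gait)
    cfg = SimulationConfig(t_end=duration)
    return engine.run(asm, sched, cfg)
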