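"""Behavioral-mode controller.

Implements the rule layer that turns the walking network into a
repertoire of behaviors: gait transitions (with the initiating-leg
constraints and the same-segment contralateral arbiter), stop and
restart of walking (with the right-leg velocity constraint and the
still-stand pose targets), search movements of the front legs, and the
forward/backward direction switch (presynaptic inhibition of one
CPG-to-premotor map and release of its mirror image).

The controller runs on the supervision grid of the engine: it inspects
the sensory signals once per millisecond, arms commands from the
schedule at their requested times, defers them until their acceptance
constraints hold, and applies parameter changes instantaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import json
import numpy as np

from .params import SEARCH_EF_DRIVE
from .wiring import (ModelAssembly, N_PER_LEG, LD0, IN_BASE, in_local,
                     leg_role, GRP_FWD, GRP_BWD)


# --------------------------------------------------------------------------
# commands and schedules
# --------------------------------------------------------------------------

@dataclass
class ModeCommand:
    """One timed behavioral-mode request."""

    kind: str                       # set_gait | stop | restart | search | direction
    t: float                        # requested time (ms)
    gait: Optional[str] = None      # for set_gait: tripod | tetrapod
    leg: Optional[str] = None       # for search: L1 | R1
    on: bool = True                 # for search
    tibia_drive: Optional[Tuple[float, float]] = None   # for search
    target: Optional[str] = None    # for direction: forward | backward
    force: bool = False             # for direction: skip the acceptance
                                    # constraint (experimental use)

    def validate(self) -> Optional[str]:
        if self.kind == "set_gait" and self.gait not in ("tripod", "tetrapod"):
            return f"unknown gait {self.gait!r}"
        if self.kind == "search" and self.leg not in ("L1", "R1"):
            return f"search leg must be L1 or R1, got {self.leg!r}"
        if self.kind == "direction" and self.target not in ("forward",
                                                            "backward"):
            return f"unknown direction {self.target!r}"
        if self.kind not in ("set_gait", "stop", "restart", "search",
                             "direction"):
            return f"unknown command kind {self.kind!r}"
        return None


@dataclass
class Schedule:
    """Time-sorted list of mode commands plus the initial gait."""

    commands: List[ModeCommand] = field(default_factory=list)
    initial_gait: str = "tetrapod"

    def validate(self) -> list:
        """Static conflict check.

        Returns a list of conflicts, each naming the offending command
        indices.  Backward walking may not overlap a still-stand
        interval (all legs grounded contradicts the lifted-middle-leg
        start constraint); search movements are compatible with
        everything.
        """
        conflicts = []
        last_t = -np.inf
        for i, c in enumerate(self.commands):
            msg = c.validate()
            if msg:
                conflicts.append({"index": i, "conflict": msg})
            if c.t < last_t:
                conflicts.append({"index": i,
                                  "conflict": "commands not time-sorted"})
            last_t = c.t
        # backward-during-stop overlap
        stop_open: Optional[int] = None
        for i, c in enumerate(self.commands):
            if c.kind == "stop":
                stop_open = i
            elif c.kind == "restart":
                stop_open = None
            elif (c.kind == "direction" and c.target == "backward"
                  and stop_open is not None):
                conflicts.append({
                    "index": i, "other": stop_open,
                    "conflict": "backward walking cannot overlap still stand"})
        return conflicts

    # -- JSON round trip ------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({"initial_gait": self.initial_gait,
                           "commands": [vars(c) for c in self.commands]},
                          indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Schedule":
        raw = json.loads(text)
        cmds = [ModeCommand(**{k: (tuple(v) if k == "tibia_drive" and v
                                   else v) for k, v in c.items()})
                for c in raw.get("commands", [])]
        return cls(commands=cmds,
                   initial_gait=raw.get("initial_gait", "tetrapod"))


def validate_schedule(commands: List[ModeCommand]) -> list:
    return Schedule(commands=commands).validate()


# --------------------------------------------------------------------------
# the controller
# --------------------------------------------------------------------------

SIDES = {"L": ("L1", "L2", "L3"), "R": ("R1", "R2", "R3")}


class BehaviorController:
    def __init__(self, asm: ModelAssembly, schedule: Optional[Schedule]):
        self.asm = asm
        p = asm.params
        self.rules = p.rules
        self.schedule = schedule or Schedule()
        self.gait = self.schedule.initial_gait
        self.direction = "forward"
        self.stopped = False
        self.search: Dict[str, Optional[Tuple[float, float]]] = {}
        self.events: list = []
        self.gate_override: Dict[str, tuple] = {}
        self.grp_gain = np.array([1.0, 1.0, 0.0])
        self._force_exc: Dict[int, float] = {}
        self._force_inh: Dict[int, float] = {}

        nl = len(asm.legs)
        self.drives = np.empty((nl, 6))
        self._set_drives_all(self.gait)

        il = p.interleg
        self.interleg_pairs = []
        for side in SIDES.values():
            f, mdl, h = side
            if h in asm.legs and mdl in asm.legs:
                self.interleg_pairs.append((h, mdl, il.g_inh9))
            if mdl in asm.legs and f in asm.legs:
                self.interleg_pairs.append((mdl, f, il.g_inh3))

        self._pending: List[dict] = []
        self._next_cmd = 0
        # tripod-transition machinery
        self._tripod_phase_until = -np.inf
        self._pair_segment: Optional[int] = None
        self._t = 0.0

    # ---- drive table management ---------------------------------------
    def _drive_row(self, gait: str, leg: str) -> np.ndarray:
        tab = self.asm.params.drives[gait]
        row = np.array([tab.pr[0], tab.pr[1], tab.ld[0], tab.ld[1],
                        tab.ef[0], tab.ef[1]])
        return row

    def _set_drives_all(self, gait: str) -> None:
        for li, leg in enumerate(self.asm.legs):
            self.drives[li] = self._drive_row(gait, leg)
        self._reapply_search_drives()

    def _set_drives_side(self, side: str, gait: str) -> None:
        for li, leg in enumerate(self.asm.legs):
            if leg.startswith(side):
                self.drives[li] = self._drive_row(gait, leg)
        self._reapply_search_drives()

    def _reapply_search_drives(self) -> None:
        for leg, drive in self.search.items():
            if drive is not None and leg in self.asm.legs:
                li = self.asm.legs.index(leg)
                self.drives[li, 4:6] = drive

    # ---- engine hooks --------------------------------------------------
    @property
    def contra_phase(self) -> str:
        return ("tripod_transition" if self._t <= self._tripod_phase_until
                else "normal")

    def apply_contralateral(self, sensors, gexc, ginh) -> None:
        cfg = self.asm.params.contralateral
        legs = self.asm.legs
        phase = self.contra_phase
        if cfg.l2_to_r3_excitation and "L2" in legs and "R3" in legs:
            g = cfg.g_l2r3_rest
            if phase == "tripod_transition" and sensors["L2"].beta >= 32.0:
                g += cfg.g_l2r3
            gexc[self.asm.neuron("R3", LD0)] += g
        if (cfg.l2_to_r2_inhibition and "L2" in legs and "R2" in legs
                and sensors["L2"].beta >= 32.0):
            ginh[self.asm.neuron("R2", LD0)] += cfg.g_contra_inh
        if (cfg.l3_to_r3_inhibition and "L3" in legs and "R3" in legs
                and sensors["L3"].beta >= 32.0):
            ginh[self.asm.neuron("R3", LD0)] += cfg.g_contra_inh

    def apply_overrides(self, gexc, ginh) -> None:
        for idx, g in self._force_exc.items():
            gexc[idx] += g
        for idx, g in self._force_inh.items():
            ginh[idx] += g

    # ---- event helper --------------------------------------------------
    def _log(self, t, kind, **detail):
        self.events.append({"t": float(t), "kind": kind, **detail})

    # ---- per-ms step ---------------------------------------------------
    def step(self, t: float, sensors) -> None:
        self._t = t
        cmds = self.schedule.commands
        while self._next_cmd < len(cmds) and cmds[self._next_cmd].t <= t:
            c = cmds[self._next_cmd]
            self._next_cmd += 1
            self._log(t, "command", command=c.kind,
                      detail={k: v for k, v in vars(c).items()
                              if v is not None and k != "kind"})
            self._pending.append({"cmd": c, "state": {}})
        done = []
        for item in self._pending:
            if self._process(item["cmd"], item["state"], t, sensors):
                done.append(item)
        for item in done:
            self._pending.remove(item)

    # ---- command processing --------------------------------------------
    def _process(self, c: ModeCommand, st: dict, t, sensors) -> bool:
        if c.kind == "set_gait":
            if c.gait == "tripod":
                return self._try_tripod(st, t, sensors)
            return self._try_tetrapod(st, t, sensors)
        if c.kind == "stop":
            return self._try_stop(st, t, sensors)
        if c.kind == "restart":
            return self._do_restart(t)
        if c.kind == "search":
            self.set_search(c.leg, c.on, c.tibia_drive, t)
            return True
        if c.kind == "direction":
            return self._try_direction(c.target, st, t, sensors,
                                       force=c.force)
        return True

    # ---- tripod transition ----------------------------------------------
    def try_start_tripod_transition(self, sensors, side: str):
        """Return the initiating leg of ``side`` (front or hind leg,
        lifted above beta_min and rising, same-segment arbiter applied),
        or None."""
        r = self.rules
        front, _, hind = SIDES[side]
        candidates = []
        for leg, segment in ((hind, 3), (front, 1)):
            if leg not in self.asm.legs:
                continue
            if self._pair_segment is not None and segment != self._pair_segment:
                continue  # pair-pathway mutual inhibition
            s = sensors[leg]
            if s.beta > r.beta_min and s.dbeta > 0:
                candidates.append((leg, segment))
        return candidates[0] if candidates else None

    def _try_tripod(self, st, t, sensors) -> bool:
        sides_done = st.setdefault("sides_done", set())
        for side in ("L", "R"):
            if side in sides_done:
                continue
            if not any(leg.startswith(side) for leg in self.asm.legs):
                sides_done.add(side)
                continue
            hit = self.try_start_tripod_transition(sensors, side)
            if hit:
                leg, segment = hit
                self._set_drives_side(side, "tripod")
                sides_done.add(side)
                if self._pair_segment is None:
                    self._pair_segment = segment
                    self._tripod_phase_until = t + self.rules.tripod_window
                self._log(t, "transition_start", to="tripod", side=side,
                          leg=leg, segment=segment)
        if len(sides_done) == 2:
            self.gait = "tripod"
            self._pair_segment = None
            return True
        return False

    # ---- tetrapod transition --------------------------------------------
    def try_start_tetrapod_transition(self, sensors, side: str) -> bool:
        r = self.rules
        _, middle, hind = SIDES[side]
        legs = [x for x in (middle, hind) if x in self.asm.legs]
        if not legs:
            return False
        return all(sensors[x].dbeta < r.eps_tet for x in legs)

    def _try_tetrapod(self, st, t, sensors) -> bool:
        sides_done = st.setdefault("sides_done", set())
        for side in ("L", "R"):
            if side in sides_done:
                continue
            if not any(leg.startswith(side) for leg in self.asm.legs):
                sides_done.add(side)
                continue
            if self.try_start_tetrapod_transition(sensors, side):
                self._set_drives_side(side, "tetrapod")
                sides_done.add(side)
                self._log(t, "transition_start", to="tetrapod", side=side)
        if len(sides_done) == 2:
            self.gait = "tetrapod"
            return True
        return False

    # ---- stop / restart --------------------------------------------------
    def request_stop(self, sensors) -> bool:
        """Acceptance constraint: every right leg is on the ground or
        moving upward (non-negative levation velocity)."""
        legs = [x for x in SIDES["R"] if x in self.asm.legs] or self.asm.legs
        return all(sensors[x].ground_contact or sensors[x].dbeta >= 0.0
                   for x in legs)

    def _try_stop(self, st, t, sensors) -> bool:
        if not self.request_stop(sensors):
            if not st.get("deferred_logged"):
                self._log(t, "stop_deferred")
                st["deferred_logged"] = True
            return False
        sg = self.asm.params.stop_gates
        for leg in self.asm.legs:
            role = leg_role(leg)
            pr = sg.pr_front if role == "front" else sg.pr_other
            ef = sg.ef_hind if role == "hind" else sg.ef_front_mid
            self.gate_override[leg] = (pr, sg.ld_all, ef)
        self.stopped = True
        self._log(t, "stop_accepted")
        return True

    def _do_restart(self, t) -> bool:
        if not self.stopped:
            self._log(t, "restart_ignored", reason="not stopped")
            return True
        self.gate_override.clear()
        self.stopped = False
        self._log(t, "restart")
        return True

    # ---- search movements -------------------------------------------------
    def set_search(self, leg: str, on: bool,
                   tibia_drive: Optional[Tuple[float, float]], t=0.0) -> None:
        """Hold a front leg protracted and lifted while its tibia
        oscillates at the drive-determined frequency."""
        if leg not in ("L1", "R1"):
            raise ValueError("search movements are a front-leg behavior "
                             f"(L1 or R1), got {leg!r}")
        if leg not in self.asm.legs:
            raise ValueError(f"{leg} not part of this assembly")
        li = self.asm.legs.index(leg)
        base = li * N_PER_LEG
        held = {"R": "exc", "D": "exc",   # retractor/depressor MNs silenced
                "P": "inh", "L": "inh"}   # protractor/levator MNs released
        if on:
            drive = tuple(tibia_drive) if tibia_drive else SEARCH_EF_DRIVE
            self.search[leg] = drive
            for muscle, action in held.items():
                for sl in (0, 1):
                    idx = base + in_local(muscle, bool(sl))
                    if action == "exc":
                        self._force_exc[idx] = 0.6
                    else:
                        self._force_inh[idx] = 1.2
            self.drives[li, 4:6] = drive
            self._log(t, "search_on", leg=leg, tibia_drive=list(drive))
        else:
            self.search[leg] = None
            for muscle in held:
                for sl in (0, 1):
                    idx = base + in_local(muscle, bool(sl))
                    self._force_exc.pop(idx, None)
                    self._force_inh.pop(idx, None)
            self.drives[li] = self._drive_row(self.gait, leg)
            self._log(t, "search_off", leg=leg)

    # ---- walking direction -------------------------------------------------
    def set_direction(self, target: str, sensors) -> str:
        """Immediate-mode direction change; returns accepted|deferred|rejected."""
        st: dict = {}
        ok = self._try_direction(target, st, self._t, sensors)
        return st.get("result", "accepted" if ok else "deferred")

    def _try_direction(self, target, st, t, sensors, force=False) -> bool:
        if target == "forward":
            self.grp_gain[GRP_FWD] = 1.0
            self.grp_gain[GRP_BWD] = 0.0
            if self.direction != "forward":
                self.direction = "forward"
                self._log(t, "direction", target="forward")
            st["result"] = "accepted"
            return True
        # backward
        if self.stopped:
            self._log(t, "direction_rejected", target="backward",
                      reason="still stand")
            st["result"] = "rejected"
            return True
        r = self.rules
        near_max = [force]
        for leg in ("L2", "R2"):
            if leg in self.asm.legs:
                near_max.append(sensors[leg].beta >= 60.0 - r.delta_back)
        if not any(near_max):
            if not st.get("deferred_logged"):
                self._log(t, "direction_deferred", target="backward")
                st["deferred_logged"] = True
            st["result"] = "deferred"
            return False
        self.grp_gain[GRP_FWD] = 0.0
        self.grp_gain[GRP_BWD] = 1.0
        self.direction = "backward"
        self._log(t, "direction", target="backward")
        st["result"] = "accepted"
        return True
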