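"""Gait-diagram analysis: swing extraction, coordination-pattern
classification, irregularity detection, and transition-start scans.

A leg is in swing while its levation angle beta is above the contact
band; the classifier works entirely on the per-leg swing intervals.
Coordination patterns are defined by which contralateral (or, for
tripod, within-triple) leg pairs swing together:

* tripod: triples L1-L3-R2 and L2-R1-R3 alternate;
* tetrapod B: pairs L1-R2, L2-R3, L3-R1 swing together, staggered by a
  third of a cycle; tetrapod C is its left-right mirror image;
* bilateral synchrony: same-segment pairs L1-R1, L2-R2, L3-R3;
* "new" pattern: L1-R3 and L3-R1 swing together while L2 and R2 lift
  alone.

A label is assigned when its defining pairs overlap strongly
(intersection-over-minimum >= 0.5 on average) and all other pairs
overlap weakly (<= 0.25); ties go to the highest defining-pair overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .params import SWING_THRESHOLD

LEGS6 = ["L1", "L2", "L3", "R1", "R2", "R3"]

#: defining pair sets per label (overlap pairs expected to swing together)
PATTERN_PAIRS = {
    "tripod": [("L1", "L3"), ("L1", "R2"), ("L3", "R2"),
               ("L2", "R1"), ("L2", "R3"), ("R1", "R3")],
    "tetrapod_B": [("L1", "R2"), ("L2", "R3"), ("L3", "R1")],
    "tetrapod_C": [("R1", "L2"), ("R2", "L3"), ("R3", "L1")],
    "bilateral_sync": [("L1", "R1"), ("L2", "R2"), ("L3", "R3")],
    "new_pattern": [("L1", "R3"), ("L3", "R1")],
}

#: phase offsets (fraction of cycle) used by the fixture generator
PATTERN_PHASES = {
    "tripod": {"L1": 0.0, "L3": 0.0, "R2": 0.0,
               "L2": 0.5, "R1": 0.5, "R3": 0.5},
    "tetrapod_B": {"L3": 0.0, "R1": 0.0, "L2": 1 / 3, "R3": 1 / 3,
                   "L1": 2 / 3, "R2": 2 / 3},
    "tetrapod_C": {"R3": 0.0, "L1": 0.0, "R2": 1 / 3, "L3": 1 / 3,
                   "R1": 2 / 3, "L2": 2 / 3},
    "bilateral_sync": {"L3": 0.0, "R3": 0.0, "L2": 1 / 3, "R2": 1 / 3,
                       "L1": 2 / 3, "R1": 2 / 3},
    "new_pattern": {"L1": 0.0, "R3": 0.0, "L3": 0.5, "R1": 0.5,
                    "L2": 0.25, "R2": 0.75},
}


@dataclass
class StepIntervals:
    """Ordered half-open swing intervals [liftoff, touchdown) of one leg,
    in ms.  A swing still open at the end of the trace has touchdown
    ``inf``."""

    leg: str
    intervals: List[Tuple[float, float]] = field(default_factory=list)

    def durations(self) -> np.ndarray:
        return np.array([b - a for a, b in self.intervals])

    def closed(self) -> List[Tuple[float, float]]:
        return [(a, b) for a, b in self.intervals if math.isfinite(b)]


def extract_swings(beta: np.ndarray, time: Optional[np.ndarray] = None,
                   threshold: float = SWING_THRESHOLD,
                   hysteresis: float = 0.0, min_duration: float = 20.0,
                   leg: str = "") -> StepIntervals:
    """Swing intervals from a uniformly sampled beta trace.

    Liftoff at the upward crossing of ``threshold + hysteresis``,
    touchdown at the downward crossing of ``threshold``; intervals
    shorter than ``min_duration`` (contact-band ripple) are discarded.
    """
    beta = np.asarray(beta, float)
    if beta.size == 0:
        raise ValueError("empty beta trace")
    t = np.arange(beta.size, dtype=float) if time is None else np.asarray(time)
    up = threshold + hysteresis
    intervals = []
    in_swing = beta[0] > up
    start = t[0] if in_swing else None
    for i in range(1, beta.size):
        if not in_swing and beta[i - 1] <= up < beta[i]:
            in_swing = True
            start = t[i]
        elif in_swing and beta[i - 1] >= threshold > beta[i]:
            in_swing = False
            if t[i] - start >= min_duration:
                intervals.append((float(start), float(t[i])))
    if in_swing and t[-1] - start >= min_duration:
        intervals.append((float(start), math.inf))
    return StepIntervals(leg=leg, intervals=intervals)


def extract_all(record, threshold: float = SWING_THRESHOLD,
                hysteresis: float = 0.0,
                legs: Optional[Sequence[str]] = None) -> Dict[str, StepIntervals]:
    legs = list(legs or record.legs)
    return {leg: extract_swings(record.beta(leg), record.time,
                                threshold, hysteresis, leg=leg)
            for leg in legs}


# --------------------------------------------------------------------------
# pairwise overlap and classification
# --------------------------------------------------------------------------

def _clip_intervals(sw: StepIntervals, w0: float, w1: float):
    out = []
    for a, b in sw.intervals:
        a2, b2 = max(a, w0), min(b, w1)
        if b2 > a2:
            out.append((a2, b2))
    return out


def _total(iv):
    return sum(b - a for a, b in iv)


def _intersection(iv1, iv2):
    tot = 0.0
    for a1, b1 in iv1:
        for a2, b2 in iv2:
            lo, hi = max(a1, a2), min(b1, b2)
            if hi > lo:
                tot += hi - lo
    return tot


def overlap_matrix(swings: Dict[str, StepIntervals],
                   window: Tuple[float, float],
                   legs: Sequence[str] = tuple(LEGS6)) -> pd.DataFrame:
    """Pairwise swing overlap (intersection over the smaller total swing
    time) inside the window; symmetric, values in [0, 1]."""
    legs = list(legs)
    n = len(legs)
    M = np.zeros((n, n))
    clipped = {leg: _clip_intervals(swings[leg], *window) for leg in legs}
    for i in range(n):
        M[i, i] = 1.0
        for j in range(i + 1, n):
            ti, tj = _total(clipped[legs[i]]), _total(clipped[legs[j]])
            if min(ti, tj) <= 0:
                val = 0.0
            else:
                val = _intersection(clipped[legs[i]], clipped[legs[j]]) / min(ti, tj)
            M[i, j] = M[j, i] = val
    return pd.DataFrame(M, index=legs, columns=legs)


@dataclass
class GaitLabel:
    label: str
    overlap: pd.DataFrame
    window: Tuple[float, float]
    score: float = 0.0
    reason: str = ""


def classify(swings: Dict[str, StepIntervals], window: Tuple[float, float],
             min_overlap: float = 0.5, max_cross: float = 0.25,
             min_cycles: int = 2) -> GaitLabel:
    """Assign a coordination-pattern label to the swing data in a window."""
    legs = [leg for leg in LEGS6 if leg in swings]
    if len(legs) < 6:
        return GaitLabel("unclassified", pd.DataFrame(), window,
                         reason="need all six legs")
    for leg in legs:
        n = len(_clip_intervals(swings[leg], *window))
        if n < min_cycles:
            return GaitLabel("unclassified",
                             overlap_matrix(swings, window), window,
                             reason=f"{leg} has {n} swings in window "
                                    f"(need >= {min_cycles})")
    M = overlap_matrix(swings, window)
    best = None
    for label, pairs in PATTERN_PAIRS.items():
        defining = [M.loc[a, b] for a, b in pairs]
        pair_set = {frozenset(p) for p in pairs}
        cross = [M.loc[a, b] for i, a in enumerate(legs)
                 for b in legs[i + 1:] if frozenset((a, b)) not in pair_set]
        # defining pairs must overlap strongly on average; the rest must
        # stay weak on average (single stray pairs up to 2x the bound are
        # tolerated, mirroring the "not perfect, but still large" cases)
        if (np.mean(defining) >= min_overlap
                and np.mean(cross) <= max_cross
                and max(cross) <= 2 * max_cross):
            score = float(np.mean(defining))
            if best is None or score > best.score:
                best = GaitLabel(label, M, window, score=score)
    return best if best else GaitLabel("unclassified", M, window,
                                       reason="no pair set matches")


def mirror_swings(swings: Dict[str, StepIntervals]) -> Dict[str, StepIntervals]:
    """Left-right mirror image (L1<->R1 etc.)."""
    out = {}
    for leg, sw in swings.items():
        other = ("R" if leg[0] == "L" else "L") + leg[1]
        out[other] = StepIntervals(leg=other, intervals=list(sw.intervals))
    return out


# --------------------------------------------------------------------------
# irregularity detection
# --------------------------------------------------------------------------

@dataclass
class LiftEvent:
    leg: str
    liftoff: float
    duration: float
    permanent: bool


def detect_prolonged_lift(swings: Dict[str, StepIntervals], horizon: float,
                          threshold: float = 1000.0) -> List[LiftEvent]:
    """Flag swings lasting >= 1000 ms.

    A swing still open at the horizon counts (as permanent) only once it
    has already exceeded the threshold there — an ordinary swing caught
    in progress by the end of the trace is not an irregularity.
    """
    events = []
    for leg, sw in swings.items():
        for a, b in sw.intervals:
            if math.isinf(b):
                if horizon - a >= threshold:
                    events.append(LiftEvent(leg, a, horizon - a, True))
            elif b - a >= threshold:
                events.append(LiftEvent(leg, a, b - a, False))
    return events


# --------------------------------------------------------------------------
# synthetic fixture traces
# --------------------------------------------------------------------------

def synth_traces(pattern: str, period: float = 1800.0, duty: float = 0.25,
                 jitter: float = 0.0, seed: int = 0, n_cycles: int = 6,
                 dt: float = 1.0, stance_level: float = 31.0,
                 swing_level: float = 55.0):
    """Idealized 6-leg beta traces realizing a coordination pattern.

    Swing onsets follow the pattern's phase table; ``jitter`` adds
    independent Gaussian onset noise (ms) per swing.  With zero jitter
    the extract-classify round trip recovers ``pattern`` exactly.
    Returns (time, {leg: beta trace}).
    """
    if pattern not in PATTERN_PHASES:
        raise ValueError(f"unknown pattern {pattern!r}; options: "
                         f"{sorted(PATTERN_PHASES)}")
    if not 0.0 < duty < 1.0:
        raise ValueError("duty must be in (0, 1)")
    rng = np.random.default_rng(seed)
    t_end = (n_cycles + 1) * period
    t = np.arange(0.0, t_end, dt)
    traces = {}
    for leg in LEGS6:
        beta = np.full(t.size, stance_level)
        phase = PATTERN_PHASES[pattern][leg]
        for k in range(n_cycles + 1):
            on = (k + phase) * period + (rng.normal(0.0, jitter)
                                         if jitter > 0 else 0.0)
            off = on + duty * period
            beta[(t >= on) & (t < off)] = swing_level
        traces[leg] = beta
    return t, traces


# --------------------------------------------------------------------------
# transition-start scan
# --------------------------------------------------------------------------

def exact_recurrence(flags: Sequence[bool], step: float,
                     min_corr: float = 0.5) -> Optional[float]:
    """Dominant recurrence period of a boolean sequence.

    Returns the smallest positive lag at which the autocorrelation of
    the (centred) sequence has a local maximum above ``min_corr`` —
    for an exactly periodic sequence this is the exact period.  None if
    the sequence is constant or aperiodic over its length.
    """
    f = np.asarray(list(flags), dtype=float)
    n = len(f)
    if n < 4 or np.all(f == f[0]):
        return None
    f = f - f.mean()
    corr = np.array([np.dot(f[:n - p], f[p:]) /
                     max(1e-12, np.sqrt(np.dot(f[:n - p], f[:n - p]) *
                                        np.dot(f[p:], f[p:])))
                     for p in range(0, n // 2 + 1)])
    for p in range(1, len(corr) - 1):
        if corr[p] >= min_corr and corr[p] >= corr[p - 1] and \
                corr[p] >= corr[p + 1]:
            return p * step
    return None


def scan_transition_starts(params=None, window: Tuple[float, float] = (6000.0, 8000.0),
                           step: float = 50.0, post_window: float = 4000.0,
                           legs_of_interest: Sequence[str] = ("L1", "R1"),
                           enable_transition: bool = True,
                           enable_slow: bool = True,
                           t_tripod: float = 3000.0) -> dict:
    """Tripod-to-tetrapod transition-start scan.

    One full simulation per start time: the model transitions into
    tripod at ``t_tripod`` (the documented transition procedure, so the
    contralateral tripod phase is the one the model itself produces),
    the transition back to tetrapod is requested at the start time, and
    a start is irregular for a leg iff that leg shows a prolonged
    (>= 1000 ms or permanent) lift after the transition.  The default
    window spans well over one tripod cycle.  Returns the per-start
    regular/irregular map, counts, and the recurrence period of the
    regular-interval pattern.
    """
    from .params import ModelParams, SimulationConfig
    from .wiring import build
    from .control import Schedule, ModeCommand
    from . import engine
    if step <= 0:
        raise ValueError("step must be positive")
    p = params or ModelParams()
    starts = np.arange(window[0], window[1] + 0.5 * step, step)
    rows = []
    for t0 in starts:
        cmds = [ModeCommand("set_gait", t_tripod, gait="tripod")]
        if enable_transition:
            cmds.append(ModeCommand("set_gait", float(t0), gait="tetrapod"))
        sched = Schedule(commands=cmds, initial_gait="tetrapod")
        asm = build(p, enable_slow=enable_slow)
        cfg = SimulationConfig(t_end=float(t0) + post_window)
        rec = engine.run(asm, sched, cfg)
        sw = extract_all(rec)
        analysed = {leg: StepIntervals(leg, [iv for iv in sw[leg].intervals
                                             if iv[0] >= t0])
                    for leg in legs_of_interest}
        lifted = {e.leg for e in detect_prolonged_lift(
            analysed, horizon=float(rec.time[-1]))}
        rows.append({"start_ms": float(t0),
                     **{f"{leg}_regular": leg not in lifted
                        for leg in legs_of_interest}})
    df = pd.DataFrame(rows)
    summary = {}
    for leg in legs_of_interest:
        flags = df[f"{leg}_regular"].tolist()
        summary[leg] = {
            "regular": int(sum(flags)),
            "irregular": int(len(flags) - sum(flags)),
            "recurrence_ms": exact_recurrence(flags, step),
        }
    return {"map": df, "summary": summary}
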