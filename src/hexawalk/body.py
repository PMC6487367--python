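"""Six-leg assembly helpers: interleg and contralateral pathway rules.

The ipsilateral pathways are inhibitory and terminate on the levator CPG
neurons of the next anterior segment (prothoracic target with
conductance g_inh3, mesothoracic with g_inh9).  Their activity is a
deterministic function of the posterior leg's vertical position and
movement direction.  The contralateral layer consists of the four
connections of the full model: the L2 -> R3 levator excitation and the
two bidirectional same-segment pathways (front pair, hind pair) with
mutual inhibition between them, which act only while a transition to
tripod is being initiated.  Two further inhibitory variants (L2 -> R2,
L3 -> R3) reproduce the configurations in which the tripod transition
fails; they are off by default.
"""

from __future__ import annotations

from typing import Dict

from .params import InterlegParams, ContralateralConfig
from .wiring import assemble, ModelAssembly  # re-exported API


def ipsilateral_inhibition(beta: float, dbeta: float, g_max: float,
                           params: InterlegParams) -> float:
    """Inhibition conductance onto the anterior levator CPG neuron.

    Quadrant rule over the posterior leg's (position band, velocity
    sign): full inhibition while the posterior leg is lifting off or
    high in swing; zero while it descends below the release angle
    (clearing the anterior leg to lift as the posterior regains
    ground); a small tonic hold otherwise.  Holding the anterior leg
    down while its posterior neighbour is in the air staggers liftoff
    into the back-to-front wave; the release window during the
    posterior's descent sets the phase at which the anterior escapes.
    """
    falling = dbeta < -params.falling_eps
    if beta >= params.lift_threshold:
        if falling and beta < params.beta_release:
            return params.release_fraction * g_max
        return g_max
    if dbeta > params.rising_eps:
        return g_max
    if falling:
        return params.release_fraction * g_max
    return params.tonic_fraction * g_max


def contralateral_drive(sensors: Dict[str, "SensorySignals"],
                        phase: str, config: ContralateralConfig,
                        active_pair_segment: int | None = None) -> dict:
    """Synaptic drive set of the contralateral layer for one instant.

    ``phase`` is ``"normal"`` or ``"tripod_transition"``; during normal
    walking the pair pathways and the L2 -> R3 excitation are
    ineffective (only the resting transfer of the L2 -> R3 synapse
    remains).  ``active_pair_segment`` (1 = front, 3 = hind) is the
    segment whose bidirectional pathway has been activated first; the
    mutual inhibition then suppresses the pathway of the other segment.
    Returns excitatory/inhibitory conductances keyed by target.
    """
    out = {"R3_levator_exc": 0.0, "R2_levator_inh": 0.0,
           "R3_levator_inh": 0.0, "front_pair_active": False,
           "hind_pair_active": False}
    if config.l2_to_r3_excitation:
        g = config.g_l2r3_rest
        if phase == "tripod_transition" and sensors["L2"].beta >= 32.0:
            g += config.g_l2r3
        out["R3_levator_exc"] = g
    if config.l2_to_r2_inhibition and sensors["L2"].beta >= 32.0:
        out["R2_levator_inh"] = config.g_contra_inh
    if config.l3_to_r3_inhibition and sensors["L3"].beta >= 32.0:
        out["R3_levator_inh"] = config.g_contra_inh
    if phase == "tripod_transition":
        if config.front_pair:
            out["front_pair_active"] = (
                active_pair_segment in (None, 1)
                or not config.pair_mutual_inhibition)
        if config.hind_pair:
            out["hind_pair_active"] = (
                active_pair_segment in (None, 3)
                or not config.pair_mutual_inhibition)
    return out
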