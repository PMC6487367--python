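# Model and methods

## Scope

`hexawalk` is a mechanistic network model of stick-insect walking: six
legs, each with three local control networks (protractor–retractor PR,
levator–depressor LD, extensor–flexor EF), coupled by intraleg sensory
gating, ipsilateral interleg pathways, and four sparse contralateral
connections.  The model is kinematic — joint angles only; there is no
body translation, ground-reaction mechanics, or Hill-type muscle model.

## Neurons and synapses

All 216 neurons are nonspiking and share one 3-variable formulation:
membrane potential V, a slow activation gate m of a persistent inward
current, and a slow adaptation gate q of an outward current.  CPG
neurons carry a strong persistent current (g_P = 0.5 µS), giving
plateau potentials, and strong adaptation (g_q = 0.6 µS, τ_q = 500 ms)
that terminates each plateau; a half-center is two such cells coupled
by graded mutual inhibition (0.4 µS).  Motoneurons and interneurons are
graded followers (small g_P, so they cannot latch).  Slow MNs differ
from fast MNs only in a threefold adaptation conductance.  Synapses are
instantaneous and graded — postsynaptic conductance g·s(V_pre) with a
sigmoidal transfer s — deliberately without synaptic state variables so
that the network contributes exactly 216 × 3 = 648 first-order ODEs.

The half-center rhythm is of adapting-relaxation type: drive g_app sets
the period (≈1890 ms at the tetrapod drive pair (0.20, 0.295) µS,
≈1110 ms at the tripod pair (0.26, 0.32)), decreasing monotonically
along the line between the two drive tables.  The antiphase of the two
cells is measured between plateau midpoints, which makes the 0.5
phase difference independent of the duty-cycle asymmetry.  Plateaus
show depolarization block of inhibition: a mid-plateau 100-ms pulse at
the interleg conductance (0.12 µS) changes the plateau duration by
< 5 %, while the same pulse arriving near the plateau's natural end
terminates it early.  At 0.15 µS the block breaks down, which is why
the interleg conductances are calibrated at 0.12 µS.

## Muscles and joints

Each joint obeys one second-order ODE,

    J θ″ = Σᵢ gainᵢ aᵢ (limᵢ − θ) − c θ′ ,

where each muscle pulls toward its own limit angle with torque
proportional to activation and remaining excursion.  This saturating
form makes the joint limits attracting equilibria — the limits cannot
be overshot, and the static equilibrium is the activation-weighted mean
of the muscle target angles (protractor 28°, retractor 128°, levator
60°, depressor 30°, extensor 45°, flexor 110°).  Fast-muscle activation
is an instantaneous sigmoid of MN potential with a small recruitment
threshold (a resting MN produces no force); slow-muscle activation
reads the slow MN's adaptation gate q — a slow, calcium-like
accumulation signal already among the neuronal state variables — so the
much longer slow-muscle activation time constant costs no extra
equations and the printed 648 + 18-equation architecture is exact.  The
slow pathway is weak (2 % of the fast gain): it produces the visible
small-amplitude ripple of the stance baseline without ever lifting β
out of the 30–32° contact band, and disabling it (the fast-only
configuration) changes no structural counts.  Joint speed (gain 0.014,
damping 0.35/ms → settle times well under 200 ms) is calibrated so the
stop manoeuvre can complete in its ≈200 ms budget.

## Intraleg coordination

The LD half-center is the step-rhythm generator; β (levation) follows
it through the levator/depressor MNs.  The leg's own movement generates
the sensory signals: β, its angular velocity, γ, and the binary ground
contact (30° ≤ β < 32°).  Binary gates switch at critical angles with
direction dependence and 2° hysteresis (β_crit = 33°, γ_crit = 75°):
the PR and EF gates go high when β falls through β_crit (shortly before
ground contact) and drive the stance-phase CPG neurons through the
sensory-relay interneurons, so retraction coincides with stance and
protraction with swing.  The hind legs' EF premotor map is crossed
(extensor is their stance muscle — they push), and their γ-gate
automaton is mirrored accordingly; this crossed map is also what makes
a *large* EF gate value produce the stretched tibia in the hind legs
during still stand while the front and middle legs need a *low* one.
The γ→LD gate is deliberately weak (an order of magnitude below the
PR/EF gates): strong enough to be a real feedback channel, weak enough
not to destabilize the rhythm generator.

## Interleg coordination

Inhibitory pathways run from each leg to the levator CPG neuron of the
next anterior leg (hind→middle g_inh9, middle→front g_inh3, both
0.12 µS), modulated by the posterior leg's (β, dβ/dt) quadrant:

| posterior leg state            | inhibition |
|--------------------------------|-----------|
| lifting off or high in swing   | full      |
| descending below β = 40°       | zero (release window) |
| grounded, stationary           | 0.7 × full (blocking hold) |

The tonic hold is strong enough that an anterior leg can escape only
during the posterior's descent.  Liftoff is therefore pinned to the
release window, and the metachronal lag equals the posterior's swing
fraction: ≈1/3 cycle in tetrapod (duty 0.30) and ≈1/2 cycle in tripod
(duty 0.45–0.50) — one rule, two gaits.  The same pinning makes the
in-phase configuration self-correcting (a leg lifting just before its
posterior neighbour gets caught by the hold on the next cycle).

Contralaterally the model carries exactly four connections: an
excitatory pathway from the β-signal of L2 to the levator CPG neuron of
R3 (the single left/right parameter asymmetry; its graded synapse keeps
a small 0.0005 µS resting transfer), bidirectional same-segment pair
pathways between the front legs and between the hind legs, and mutual
inhibition between those two pair pathways.  The pair pathways carry no
explicit neurons; they are realized as a two-state arbiter in the
transition controller that restricts the second side's tripod
initiation to the same segment as the first.  All contralateral action
is confined to the initiation of the transition to tripod; during
steady gaits the pathways are ineffective, so the contralateral phase
of a steady gait is set by the transition that created it (and the
sides are neutrally stable against slow relative drift — as in the
reference account, where the bilaterally synchronous gait persists
only because nothing perturbs it).

## Behavioral modes

* **Gait transitions.**  Tripod initiation requires a front or hind leg
  (never the middle one) lifted above β_min = 40° and rising; the side
  that satisfies this first switches all its g_app drives to the tripod
  table instantaneously, and the pair arbiter forces the other side to
  initiate at the same segment.  During the initiation window (2.5 s)
  the L2→R3 excitation pulls R3 toward L2's phase, which breaks the
  left-right symmetry and sets the tripod's antiphase.  The transition
  to tetrapod is per-side and needs no contralateral signal: when the
  middle and hind legs' levation velocities both fall below ε, the
  side's drives switch to the tetrapod table.  Both B- and C-type
  tetrapods emerge, depending on the phase at which the command lands.
* **Stop and restart.**  A stop is accepted only when every right leg
  is grounded or moving upward.  It is executed through the intraleg
  gate channels alone: static large LD gate values lock the depressors
  (robust ground contact), PR gates are zeroed in the front legs
  (protract to 28°) and raised elsewhere (retract to 128°), EF gates
  zeroed in front/middle and raised in the hind legs (all tibiae
  stretch to 45°).  The full pose is reached in ≈170–190 ms.  Restart
  simply removes the static values; no constraint is needed.
* **Search movements.**  For L1/R1: the depressor and retractor MNs
  are silenced by tonically exciting their premotor INs and the
  levator/protractor MNs released by inhibiting theirs (the g_d
  channel), holding the leg at α = 28°, β = 60°, while the EF CPG
  drive is raised to a fast symmetric pair, oscillating the tibia at a
  few hundred ms period, independently per leg.  The other legs'
  rhythm is untouched (periods stay within 1 %).
* **Backward walking.**  The CPG→premotor maps of all PR networks and
  of the front/hind EF networks exist in two mirrored copies gated by
  presynaptic inhibition; the direction switch silences one copy and
  releases the other, exchanging swing/stance roles of α (and the
  front/hind tibia roles) while the β rhythm continues unchanged.  The
  γ-gate automata of front and hind legs exchange direction together
  with the EF maps.  Backward starts are accepted only while L2 or R2
  is lifted within 2° of its 60° maximum.

## Numerical method

Fixed-step explicit integration (dt = 0.05 ms, well below the fastest
membrane time constant) in a compiled kernel, supervised on a 1-ms grid
on which the discrete layer runs: gate automata, the interleg rule, the
contralateral logic, and the mode controller.  One millisecond is two
orders of magnitude below every behavioral time scale, and the
supervision grid doubles as the output sampling.  The scheme was chosen
over an adaptive event-detecting solver because the hybrid system
carries dozens of state-dependent discrete conditions, and a fixed grid
makes determinism exact: repeated runs agree bitwise, the
no-contralateral configuration is exactly left-right symmetric, and
halving dt changes step periods by < 1 %.  Drive-table switches are
applied between supervision steps, i.e. instantaneously on the
behavioral time scale.  Simulation costs about 0.2 s per simulated
second on one core.

## Calibration summary

Published accounts of this model family state the architecture but not
a complete parameter set, so all conductances, thresholds, and time
constants here are one calibration chosen to reproduce the documented
behavioral repertoire:
periods ≈1.75 s (tetrapod) / ≈1.1 s (tripod); swing duty ≈0.30 / 0.47;
metachronal lags ≈1/3 / ≈1/2 cycle; stop in under 200 ms; search and
backward modes that leave the β rhythm intact.  The defaults live in
`hexawalk.params` and can be overridden per namespace from YAML.

## Known limitations and deviations

* **Restart symmetry.**  After a still stand longer than ≈1 s the CPG
  adaptation (τ_q = 500 ms) has converged, so the hind legs lift again
  in the same millisecond and the emerging pattern is bilaterally
  synchronous tetrapod.  The reference behavior — restart always led by
  R3 with a C-type tetrapod — does not emerge in this calibration; it
  plausibly requires slower adaptation that preserves phase memory
  through the stand.  Short stands (< 1 s) do restart asymmetrically
  and resume B-type.
* **Failed-variant details.**  With the experimental L2→R2 inhibition
  no proper coordination pattern arises (as in the reference), but R3
  keeps stepping instead of freezing; with L3→R3 inhibition the sides
  drift apart instead of returning to bilateral synchrony.  Both
  details likely involve posterior-directed sensory modulation that is
  outside this model's interleg wiring (posterior→anterior only).
* **Transition irregularities.**  Ill-timed transitions disturb single
  legs here as skipped cycles (prolonged stance), not as the prolonged
  lifts of the reference account; the lift-based irregularity scan
  therefore reports all starts regular.
* **Backward-transition robustness.**  The β rhythm is untouched by the
  direction swap, and with the middle-leg constraint no backward start
  fails in this calibration (the reference reports ≈0.3); without the
  constraint ≈0.13 of starts fail.  The forward-restore failure rate
  (≈0.17) is in the reference range.
* Curve walking, velocity-dependent gait selection, and intermediate-
  pattern taxonomy are out of scope.
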