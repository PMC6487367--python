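# hexawalk

A neuromechanical network model of six-legged (stick-insect) walking,
built as a tested, importable simulator.  The model couples

* **18 central pattern generators** — half-center oscillators of two
  mutually inhibitory nonspiking neurons, one per antagonistic muscle
  pair (protractor–retractor, levator–depressor, extensor–flexor) per
  leg;
* **72 motoneurons** (fast and slow per muscle) driven through **108
  inhibitory premotor and sensory-relay interneurons** — 216 neurons
  with three state variables each, i.e. 648 first-order ODEs;
* **18 joints**, one second-order ODE each, driven by the antagonistic
  muscle pairs: the thorax–coxa angle α ∈ [28°, 128°], the levation
  angle β ∈ [30°, 60°] (30° ≤ β < 32° signals ground contact), and the
  femur–tibia angle γ ∈ [45°, 110°].

Each neuron follows

    C dV/dt = −g_L (V−E_L) − g_P m (V−E_P) − g_q q (V−E_K) − I_syn
    dm/dt = (m∞(V) − m)/τ_m ,   dq/dt = (q∞(V) − q)/τ_q

with a persistent inward current (gate *m*) that supports plateau
potentials and a slow adaptation current (gate *q*) that terminates
them; stronger drive g_app shortens the cycle, which is why the tripod
gait is faster than the tetrapod.  Sensory signals generated by the
leg's own movement (β, dβ/dt, γ) switch binary low/high gate
conductances that close the intraleg loop, and inhibitory
interleg pathways onto the levator CPGs of anterior legs (conductances
g_inh3, g_inh9) stagger liftoff into the back-to-front metachronal wave.
Four sparse contralateral connections act only while a transition to
tripod is initiated.  A behavioral-mode controller implements gait
transitions, stop/restart with a still-stand pose, front-leg search
movements, and backward walking by presynaptic re-mapping of the
CPG-to-premotor connections.  A gait-analysis toolkit extracts swing
phases (β above the contact band) and classifies the coordination
pattern (tripod, tetrapod B/C, bilateral synchrony, the rare "new"
pattern) from pairwise swing overlaps.

Intended for researchers in motor control and locomotion modeling who
want a reproducible, scriptable version of this class of
CPG–muscle–sensory models.

## Worked example

```python
import hexawalk as hw
from hexawalk.control import ModeCommand

asm = hw.assemble()                      # 18 CPGs, 72 MNs, 108 INs
cmds = [ModeCommand("set_gait", 3000.0, gait="tripod"),
        ModeCommand("set_gait", 7600.0, gait="tetrapod")]
rec = hw.run(asm, hw.Schedule(cmds, initial_gait="tetrapod"),
             hw.SimulationConfig(t_end=13000))
swings = hw.extract_all(rec)
print(hw.classify(swings, (4200, 7600)).label)    # tripod
lab = hw.classify(swings, (9300, 12600))
print(lab.label, round(lab.score, 2))             # tetrapod_B 0.8
```

The first window classifies as `tripod`: the triples L1-L3-R2 and
L2-R1-R3 swing alternately.  After the transition command the model
settles into `tetrapod_B` — the contralateral pairs L1-R2, L2-R3 and
L3-R1 swing together, staggered by a third of a cycle — with a mean
defining-pair swing overlap of 0.8.  `examples/` contains one short
narrative script per capability (single CPG, single leg, gait
transitions, stop and search, backward walking, the classifier); each
prints the quantities it computes and what they mean.

A thin CLI wraps the same functions:

```bash
hexawalk simulate --out traj.csv --t-end 13000
hexawalk classify --traj traj.csv --window 9300:12600
hexawalk scan --window 6000:8000 --step 50 --out scanmap.csv
```

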