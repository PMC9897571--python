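# insectleg

A neural controller for a single insect leg, built entirely from
rectified leaky-integrator neurons, together with the open-loop
stimulation experiments that probe its context-dependent reflexes and
emergent rhythms.  It is aimed at computational neuroscientists and
roboticists studying decentralized walking control in stick insects and
related hexapods — in particular the question of whether the rhythmic
motor output seen under pharmacological activation requires dedicated
central pattern generators, or can emerge from circuitry that exists
for a different reason.

## The model

Every unit obeys first-order low-pass dynamics with a piecewise-linear
output,

    tau_lp dx/dt = -x + input + bias,    output = clamp(x, 0, ceiling)

and some units carry an additional first-order high-pass stage
(`hp(t) = input - lowpass(input; tau_hp)`) that makes them *phasic*:
they respond to change and reject steady input.

Three circuit motifs are composed into one leg controller:

- **Bistable monopoles** (Stand–Walk, Forward–Backward, Swing–Stance):
  winner-take-all pairs with constant drive and *tonic* (low-pass only)
  cross-inhibition.  They latch one behavioural state per pair and
  cannot oscillate.  Sensory gates route load, campaniform-sensilla
  (CS) femur-bending and femoral-chordotonal-organ (fCO) signals into
  the Swing/Stance choice; tactile stimulation selects the walking
  direction; state Stand silences the global velocity command.
- **Stance/swing branch routing**: a ring-net stage maps leg posture
  (anterior/posterior alpha angle), walking direction and turning angle
  θ onto the antagonist that propels the leg (e.g. forward + anterior
  → retractor and flexor; the inner front leg of a 75° turn → flexor,
  the outer leg → a weak extensor drive), and a height controller maps
  femur–tibia flexion onto levator/depressor independently of walking
  direction.
- **Premotor soft-WTA nets** (one per joint): two excitatory branch
  units, two *phasic* (high-pass) inhibitory units, crossed inhibition
  onto the motor neurons.  The phasic inhibition minimizes
  co-contraction but adapts away, so the net has no rhythm of its own.
  Constant excitation of both branches — emulating pilocarpine applied
  to the ganglion — turns each net into a relaxation oscillator whose
  period and half-phase asymmetry follow the injection levels.

All experiments are open loop: the leg is fixed, coordination signals
from other legs are cut, and motor output is recorded but never moves
the leg.  Everything is deterministic; identical runs produce
byte-identical traces.

## A worked example

```sh
python examples/03_pilocarpine_rhythms.py
```

prints, with the frozen default calibration:

```
alpha: injection 3.0/6.0 mV -> protractor 3.60 s, retractor 6.60 s, period 10.30 s
beta: injection 13.0/3.0 mV -> levator 2.63 s, depressor 1.63 s, period 4.79 s
gamma: injection 5.0/5.0 mV -> flexor 2.07 s, extensor 2.07 s, period 4.23 s
gamma without injection: max output 0.000000 mV (no rhythm)
```

Each line is one joint's premotor net under constant two-branch
injection: the stronger-driven branch holds the longer half-phase
(retractor 6.6 s vs protractor 3.6 s at 6 vs 3 mV), equal injections
give equal half-phases, and with zero injection the net stays silent —
slow joint rhythms appear without any dedicated oscillator circuit.
The other examples show the reflex reversal of the alpha joint under
femur bending (`01`), the active reaction of the gamma joint and its
absence in the outer leg during curve walking (`02`), and entrainment
and phase reset of the rhythms by rhythmic sensory input (`04`).

The same functionality is available from a shell:

```sh
insectleg catalog                      # list the 11 scenarios
insectleg run --scenario exp31_fw --out traces/
insectleg analyze --trace traces/exp31_fw.csv --channel retractor --period
insectleg calibrate                    # re-derive the premotor constants
```

## Layout

| path | contents |
|---|---|
| `src/insectleg/core.py` | units, filters, fixed-step network engine |
| `src/insectleg/motivation.py` | monopoles, sensory gating, context |
| `src/insectleg/joints.py` | premotor nets, ring net, height control |
| `src/insectleg/stimuli.py` | CS, fCO and injection generators |
| `src/insectleg/experiments.py` | scenario catalog and runner |
| `src/insectleg/analysis.py` | periods, reflex classes, reset/entrainment |
| `src/insectleg/calibrate.py` | one-time premotor calibration |
| `src/insectleg/traceio.py`, `cli.py`, `config.py` | persistence, CLI, config |
| `docs/methods.md` | model assumptions, parameters, limitations |
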