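# Methods

## Unit model and integration

All neurons are rectified leaky integrators: `tau_lp dx/dt = -x + input
+ bias`, output clamped to `[0, 100] mV`.  This is the usual non-spiking
reduction used for stick-insect premotor circuitry; activations are
population rates expressed in millivolts so that injection levels can be
stated directly in the units of the pilocarpine-emulation inputs.
Phasic units prepend a first-order high-pass stage, `hp = input -
lowpass(input; tau_hp)`, which passes transients unchanged and rejects
steady input; the rectification of the downstream integrator discards
the negative lobe.

Integration is explicit Euler with synchronous update (all input sums
from the previous step's outputs) at `dt = 0.01 s`.  The rhythms of
interest live at 2–11 s and the fastest time constant is `tau_lp =
0.05 s`, so the step is 5× below the fastest dynamics and ~150× below
the slowest.  Halving `dt` changes settling traces by well under 1% RMS
and shifts oscillator periods by ~0.15%.  For limit-cycle traces the
*pointwise* RMS comparison is not meaningful over long runs — any O(dt)
period shift accumulates into phase drift — so convergence of the
oscillators is stated in terms of the measured period.  There is no
randomness anywhere; reruns are byte-identical.

## Motivation layer

Each behavioural pair (Stand–Walk, Forward–Backward, Swing–Stance) is a
four-unit flip-flop: two excitatory units under constant drive, each
exciting a tonic inhibitory partner that inhibits the opposite
excitatory unit (cross-inhibition weight 2).  Because the inhibition is
tonic, the winner holds indefinitely — the pair latches and cannot
oscillate; at exact input ties the previous winner persists
(hysteresis).  A tonic drive unit (20 mV) feeds Stand/Walk; Walk feeds
the other two pairs at gain 0.25 (5 mV drive each), so winning Stand
silences the whole walking system, and a dedicated velocity unit is
fully inhibited by Stand.  Sensory gates (load, CS bending, slow fCO
ramps) project onto Swing or Stance at twice the pair's constant drive,
which guarantees that a sustained event always flips the pair (in
≲0.3 s) while leaving the latch stable otherwise.  Scenario runs start
with Walk, the scenario's walking direction, and Swing active.

## Branch routing

During stance the ring-net stage routes the velocity-scaled drive
(15 mV at full velocity) to retractor (forward) or protractor
(backward), and to flexor or extensor by the posture rule (anterior
alpha + forward → flexor; inverted in the posterior range).  For curve
walking the inner leg keeps the full flexor drive while the outer leg
receives a weak drive (3 mV) that shifts linearly from flexor to
extensor with the turning angle, fully extensor from 75°.  During swing
a stereotyped drive (10 mV) goes to the antagonists opposite the stance
set; the internal swing-trajectory network is deliberately not
reconstructed.  The swing drive requires sensory evidence at the swing
gate, not merely state Swing — experiments begin in Swing with no
stimulus, and in that condition the branches must stay silent so that
pure-injection runs measure the premotor dynamics alone.

The beta (levator/depressor) drive is one signed scalar: the height
controller's deviation term (1 mV/deg of femur–tibia angle above or
below the 60° reference) plus a levator-ward bias (+10 mV) in swing and
a depressor-ward bias (−15 mV) in stance, rectified onto exactly one
antagonist.  The fCO apodeme position maps to femur–tibia flexion at
100 deg/mm (default ramps span ±0.25 mm around rest), so slow
elongation raises the effective angle and converts the stance-phase
depressor bias into a levator drive.  The beta pathway takes no input
from the direction pair, which makes its traces bit-identical under
forward and backward walking by construction.

A structural rule applies to all routing: **drives are one-sided** —
at any instant at most one antagonist of each pair receives branch
input.  With purely phasic lateral inhibition in the premotor nets,
*any* sustained two-sided drive would oscillate; one-sidedness is what
confines emergent rhythmicity to the pilocarpine condition.

## Premotor nets and the emergent oscillation

Each joint's premotor net has two excitatory branch units, two phasic
inhibitory units (gain 1 from their branch unit; lateral inhibition
`w_ab`, `w_ba` onto the opposite branch) and two motor neurons that
receive their own branch at gain 1 and the opposite branch at a crossed
inhibitory gain `k` (0.5 for alpha and gamma, 0.8 for beta).  The
crossed projection suppresses the weaker branch's motor output during
the winner's phase; without it the loser's premotor activity creeps
back as the phasic inhibition decays, and antagonist co-activation
exceeds the soft-WTA bound for up to a quarter of each cycle.  The
beta joint's strongly asymmetric injections (13/3 mV) need the higher
crossing gain.

With constant injection `p_a, p_b > 0` on both branches, the net
becomes a relaxation oscillator: the winner's phasic inhibition decays
with `tau_hp`, the loser recovers, and a fast positive-feedback switch
hands the phase over.  To first order a branch's ON duration is
`tau_hp · ln(w · p_own / p_other)`: the period scales with `tau_hp`,
the stronger-driven branch holds the longer half-phase, and raising one
injection lengthens that branch's half-phase monotonically.  A
symmetric net cannot break symmetry deterministically, so the
first-listed branch carries a fixed 0.01 mV initial state; with zero
injection this seed simply decays.

### Calibration

`tau_hp`, `w_ab`, `w_ba` per joint are free constants fitted **once**
(`insectleg calibrate`) so that the default injections reproduce the
target rhythms — half-phases 3.7/6.7 s (alpha, 3/6 mV), 2.8/1.8 s
(beta, 13/3 mV), 2.1/2.1 s (gamma, 5/5 mV) and periods 10.2/4.6/4.2 s —
then frozen in `config.PMN_CALIBRATION`.  A symmetric single-gain net
cannot reach the alpha joint's half-phase ratio (it saturates near
0.62 vs the required 0.55), which is why the two lateral gains are
calibrated independently.  The target set is over-determined: with
one-sided motor outputs the inter-onset period necessarily exceeds the
half-phase sum by the two switching gaps, while the alpha targets
already sum past their period (3.7 + 6.7 > 10.2).  The fit therefore
equalizes the three residuals, shaving a third of the measured excess
off each half-phase target; the frozen constants land within 0.03–0.19 s
of every target.  Symmetric drives are refit with an exactly symmetric
net so equal injections give equal half-phases to machine precision of
the measurement grid.

## Stimuli and the sensory velocity gate

CS bending is a square wave (default 6 s period, bend 2/3 of the cycle:
4 s Stance, 2 s enforced Swing; the oscillation experiments use 3.6 and
10.8 s).  fCO stimulation is a trapezoidal ramp-and-hold of the apodeme
(default 1 mm/s over ±0.25 mm; periods 3.6 and 7.0 s in the oscillation
experiments).  Elongation ramps at or below 2 mm/s are routed to the
assistance pathway (activating Stance); ramps strictly faster than
6 mm/s are tagged resistance-pathway and routed nowhere (the resistance
motor response itself is out of scope); the 2–6 mm/s band is a dead
zone.  A velocity exactly on a gate boundary falls into the slower
class.  Rostral bending mirrors caudal but couples to Swing, with the
return coupling at half weight — a stated assumption, as the biological
coupling is described only as weak.  Pilocarpine is a constant port
injection from scenario onset; no pharmacokinetics.

## Analysis conventions

Oscillations are measured by threshold onsets at 50% of a channel's
maximum (robust for clamped piecewise-linear outputs): period = mean
inter-onset interval, half-phase = mean above-threshold duration, at
least two full cycles required for a valid estimate; startup transients
are skipped (15 s in 60 s free-running measurements, 4 s in entrainment
checks).  Reflex outcomes compare the antagonists' mean activation over
the stimulus-phase windows: ratio ≥ 2 and mean ≥ 5 mV is a clear
outcome, smaller ratios or means are weak, and near-silent or tied
channels are neutral.  Entrainment means the measured period is within
5% of the stimulus period.  Phase reset is declared when the latency
from stimulus transition to the next onset is fixed across transitions
(SD below 10% of the intrinsic period); the t = 0 transition is
excluded because no ongoing phase exists yet.  The fixed-latency
criterion is a package convention — the source experiments report reset
only qualitatively.

## What the scenarios do and do not show

The scenario catalog reproduces fixed-leg, deafferented, open-loop
preparations: stimulus timing is imposed, Stance/Swing cycles are
enforced by the stimulus, and motor output never feeds back.  Passing
these tests shows that the circuit produces the observed
context-dependent reflex signs, the absence of intrinsic rhythmicity,
and sensory entrainment/reset of injected rhythms under exactly these
idealized conditions.  It does not demonstrate closed-loop walking,
interleg coordination, the biomechanics of femur bending, biological
variability (no noise is modelled), or the nonlinear position
dependencies reported for the beta joint at large angular ranges.
Standing (negative-feedback height control), searching movements and
the hind leg's deafferented reversal are likewise outside this
package's scope.

## Numerical choices and degenerate inputs

`dt` must be smaller than every low-pass time constant (explicit-Euler
stability; enforced).  Non-finite inputs abort with the offending unit
named; NaN states abort with the step index.  Zero-amplitude stimuli
produce no events; event lists and stimulus series are generated from
the same interval arithmetic and are therefore mutually consistent by
construction.  Default run lengths are 12 s for reflex scenarios, 36 s
for oscillation scenarios (≥3 cycles of the slowest rhythm), 60 s for
free-running rhythm measurements, and 100 s for no-oscillation checks.
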