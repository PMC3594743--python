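# Methods

This note documents the model implemented in `actdisc`, the choices made
where the design was genuinely open, and what the simulations do and do not
establish.

## Overview

The simulated task reproduces a two-manipulandum operant protocol: an agent
free to move in a square arena encounters an *active* (red) and an
*inactive* (white) block on opposite walls. Completed interactions with the
red block may deliver a brief light flash — the only "reinforcer" — under a
variable-interval (VI) or fixed-ratio-1 (FR1) schedule; white interactions
never have consequences. An experiment comprises 5 habituation days (no
flashes ever) and 10 response-contingent days, one 15-minute session per
day, with learning state (cortico-striatal weights, the outcome-prediction
model, habituation levels) carried over between days. Ten replicates are run
per condition, differing only in random seed.

The scientific core is the interplay of three processes:

1. **selection** — a basal-ganglia/thalamocortical circuit arbitrating
   between three action subsystems on the basis of their salience;
2. **novelty salience** — a phenomenological prediction of the phasic
   outcome whose *uncertainty* is fed back as extra salience for the active
   block, creating a transient repetition bias;
3. **dopamine-gated plasticity** — a sensory-prediction-error dopamine
   signal driving a BCM-style rule at the cortico-striatal synapses, which
   shifts how easily the active channel is selected.

## Selection network

Each of the ten populations (sensory cortex, motor cortex, D1- and
D2-striatum, STN, GPe, GPi/SNr, VL thalamus, TRN, brainstem) holds one
leaky-integrator unit per channel,

    tau da/dt = -a + I,      y = clip(a - eps, 0, 1),

integrated by forward Euler with `dt = 10 ms` and `tau = 40 ms` (`dt > tau`
is rejected as an unstable configuration). The wiring follows the classic
rate-coded selection architecture: cortex drives striatum and STN; focused
D1 inhibition and diffuse (cross-channel) STN excitation converge on
GPi/SNr, forming an off-centre/on-surround competition; the D2/GPe loop
regulates total excitation; GPi/SNr gates VL (and TRN), closing a
thalamo-cortical loop with a sub-unity motor-cortex recurrence; a brainstem
population per channel combines cortical excitation with pallidal
inhibition, and a channel is behaviourally expressed while its brainstem
rate exceeds `phi = 0.5`.

The inter-nucleus gains and thresholds are not uniquely determined by the
architecture; they were tuned, once, against a selection-competence battery:

* from rest, on a salience grid over [0, 1]^2, the selected channel (if any)
  is always the one with the largest salience;
* a lone channel is expressed above salience ~0.2;
* an engaged channel is sticky — behavioural maintenance through the
  thalamo-cortical loop means interruption requires a clearly higher rival
  salience (a rival 0.8 vs an incumbent 0.4 switches; a rival only slightly
  above the incumbent transiently suppresses both) — matching the intended
  semantics that a sufficiently high exploration drive can interrupt an
  ongoing interaction;
* the expression threshold moves with the plastic cortico-striatal weights
  (≈ ±0.1 of salience for ±10% weight change), which is the handle through
  which plasticity shapes behaviour;
* GPi/SNr is tonically active at rest and permutation symmetry across
  channels is exact.

Tonic dopamine enters only as a constant multiplicative factor on
cortico-striatal transmission: `w (1 + lambda)` at D1 and `w (1 - lambda)`
at D2, `lambda = 0.2`. Gaussian input noise (sd 0.1) on the sensory-cortex
drive smooths the expression threshold and resolves ties.

Before an experiment the motor weights are calibrated: a ladder of symmetric
values is swept and the first that passes the battery — and makes each
action selectable at a moderate lone salience — is adopted (0.55 with the
default gains). Sensory-cortex weights start at exactly zero; anything they
acquire is a learned stimulus-driven selection bias.

## Prediction, salience, habituation

The flash is a binary feature `y_f`; its latent prediction `y*` (one per
block; the white block's never leaves zero) is updated recursively with
`k = 0.95`: a flash gives `y* <- 1 - k (1 - y*)` (the first-ever flash sets
`y* = 0.2`), an omission of a predicted flash gives `y* <- k y*`. Between
events the latent prediction is constant, and it is never unlearned at day
boundaries. After n consecutive post-first flashes the closed form is
`y* = 1 - 0.8 k^n`, which the tests verify to 1e-12.

Novelty salience is `S_nov = 0.5 - |y* - 0.5|`: zero for firm predictions in
either direction, maximal (0.5) at complete uncertainty. The active block's
total salience is `S_int + S_nov`.

Intrinsic salience starts at `S_init = 0.45` per block and habituates
geometrically: within a day by `gamma_b = 0.95` after each completed
interaction with that block; across days the start value is `gamma_a = 0.95`
times the *previous day's start* (not its end), so salience partially
recovers overnight — dishabituation. Exploration salience is redrawn once
per second from Uniform(0, 0.8), i.e. mean 0.4 and sd 0.8/sqrt(12) ≈ 0.231.

## Phasic dopamine

At an evaluated red interaction the collicular response is `[y_f - y*]+`
and the canceling signal is `[y* - y_f]+`; their difference equals the
sensory prediction error `y_f - y*` identically (tested on a grid). Both
are 0.2-s triangular pulses feeding an SNc leaky integrator
(`tau = 40 ms`) with gains `a+ = 2` and `a- = 1`, and the unnormalized,
below-rectified output is read as the simulated dopamine level:

    d = max(0, a_snc + 0.2),

giving a resting level of 0.2, bursts above it, and dips that approach zero
but never go below. The two branch boundaries of the output function are
reconciled as a single rectification at -0.2 with no saturation (continuity,
plus the requirement that the output be interpretable as a concentration).
A fully predicted flash produces no excursion. With the pathway disabled
("no-pDA" conditions) `d` is held at rest and no plasticity events occur.

**Event timing.** The flash is physically triggered by the bump (the first
contact of the interaction sequence), so the prediction update and the
dopamine burst are processed at bump time — a flash that was seen counts for
learning even if the sequence is subsequently interrupted. The *omission* of
a predicted flash can only be recognized once the interaction has completed
without one, so dips are processed at sequence completion. Responses are
counted at completion in both cases.

## Plasticity

The rate-coded learning rule is

    dw/dt = eta * y * (y - theta) * x,     theta = <y^2> * C(d),
    C(d) = -(A-(d) * tau_ratio + A+(d)) * c_gain,

with pre-rate `x` (motor or sensory cortex), post-rate `y` (D1 or D2 MSN of
the active channel), and `<y^2>` an exponential moving average (time
constant 5 s) of the squared post-rate. The signed pair coefficients
`A+`/`A-` are specific to receptor class and dopamine level and are blended
by the saturating function `alpha(d) = 4d / (1 + 4d)`:

| pair              | A+     | A-     | consequence                        |
|-------------------|--------|--------|------------------------------------|
| D1, high dopamine | +0.85  | -0.25  | strong LTP, weak LTD -> C < 0      |
| D1, low dopamine  | +0.25  | -1.0   | C > 0: dips depress the GO pathway |
| D2, high dopamine | -1.0   | -0.25  | C > 0: bursts depress NO-GO        |
| D2, low dopamine  | +1.0   | +1.0   | uniform LTP -> C < 0: dips         |
|                   |        |        | strengthen NO-GO                   |

Only the sign pattern and strong/weak ordering of these coefficients are
constrained by the underlying physiology; the magnitudes, the lumped rate
`eta = 0.002`, and the scale factor `c_gain = 80` were
calibrated, once, so that the behavioural consequences of roughly a hundred
phasic events over the response-contingent phase span the operating range of
the selection network (weight excursions of order 10-30% of the calibrated
value). `tau_ratio = tau-/tau+ = 1` absent contrary information.

Updates are gated to a 0.4-s window starting at each phasic event — the
duration over which the pulse-driven dopamine transient actually deviates
from rest. (A longer window mostly samples resting dopamine, whose blended
coefficients are near-balanced but not zero, and the accumulated
resting-level drift was found to erase the burst/dip signature; the window
was therefore matched to the transient.) Within a window the pre/post rates
are those sampled at event onset (an eligibility-trace reading: the rates
that caused the outcome are the ones credited), and `<y^2>` is likewise
frozen at onset. Weights are clipped to [0.2, 1.5] for the motor inputs —
the floor keeps every action physically performable — while sensory weights
have floor 0, since zero is their natural resting point. An optional flag
enables weak plasticity between events at tonic dopamine; it is off by
default, consistent with flat inter-event weight trajectories.

## Arena and embedding

The arena is kinematic: a differential-drive disc agent (radius 2.8,
wheelbase 5.3) in a 60 x 60 box, positions clamped at walls and blocks, no
mass or friction. Blocks (10 x 2) sit at the centres of opposite walls. A
block is perceived when within a 120° forward cone and range 32; the flash
(0.2 s) is a bright point light perceived regardless of heading.

Each interaction subsystem is a small state machine: orient -> approach ->
bump -> back off (0.55 s) -> stop (0.4 s) -> slow re-approach; the second
contact completes the interaction. Deselection at any point resets the
sequence. The explore subsystem wanders with heading redraws every 3 s and
steers toward the arena centre when close to a wall or block; it never emits
interactions. When several subsystems are selected their wheel commands are
averaged; with none selected the agent halts. Speeds and stage durations
were chosen so that a full interaction takes roughly 4-10 s (bout-start to
completion, including interruptions), giving per-session interaction counts
in the tens.

The VI schedule arms after exponential intervals (mean 120 s, drawn within
each session); an armed flash is consumed by the next red bump, and
premature bumps go unreinforced. FR1 is always armed. White bumps never
flash.

## Protocol, metrics, reproducibility

Sessions are 900 s; counts are binned into three 5-min epochs. An *active
response* is a completed red interaction (flash or not), an *inactive
response* a completed white interaction. `r_peak` is the ratio of the peak
across response-contingent days of the run-averaged daily active count to
the run-averaged mean daily inactive count over that phase, rounded half-up.
Weight trajectories are reported for the active-response channel (the only
one whose weights ever change).

All randomness in a session — network noise, explore-salience draws, wander
headings, VI intervals — comes from one stream seeded deterministically from
(base seed, replicate, day), making outputs bitwise reproducible; the
reproducibility test asserts byte-identical CSVs. The closed-loop engine is
a compiled (numba) kernel; a full 15-day replicate runs in about a second,
and the four-condition, 10-replicate acceptance computation in a few
minutes on one CPU.

## What the simulations show, and known limitations

With the default parameters the model reproduces the qualitative structure
of intrinsically motivated operant behaviour: no red/white asymmetry during
habituation; a response-contingent rise in active responding that peaks on
the first contingent day under FR1 (novelty spikes and collapses as the
flash becomes predicted) but later under VI (sparse unpredictable flashes
keep the prediction uncertain, sustaining novelty salience across days);
steeper within-session decline under FR1; *more* active responding without
phasic dopamine than with it under VI (dip-dominated events depress D1 and
potentiate D2, raising the active channel's expression threshold) and the
reverse under FR1 (burst-driven D1-LTP with a transient overshoot); and
weight trajectories that are flat without phasic dopamine.

Limitations to keep in mind:

* The arena is a simplified kinematic stand-in for a physical robot: no
  camera or infrared sensor models, no contact dynamics. Behavioural
  *counts* therefore depend on geometry and speed constants that have no
  single principled value; they were fixed once so that session counts and
  their salience-sensitivity are in a realistic range, and all appear in the
  config.
* The FR1 conditions produce peak-to-inactive ratios somewhat above the VI
  ones relative to what the in-vivo-style analysis would suggest: in this
  reconstruction the first contingent day's novelty transient drives about
  as many interactions per day as VI's sustained plateau, because both are
  limited by the same engagement capacity, whereas a stronger VI/FR1
  separation would require the inactive baseline to differ more between
  schedules than the agent's time budget alone produces. The orderings
  between dopamine conditions are robust; the absolute FR1 ratios run high.
* The prediction model is phenomenological (a scalar recursion), not a
  neural network; the command units are procedural code by design.
* Only three channels and a single phasic feature are modelled; there is no
  reward sensitization, no action chunking, and no separate limbic loop.
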