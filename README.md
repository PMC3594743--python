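# actdisc

An embodied computational-neuroscience model of *intrinsically motivated
action discovery*: how an animal, without food or water reward, can come to
repeat an action whose only consequence is a surprising sensory event, and
how that repetition fades as the event becomes predictable.

The package simulates a differential-drive agent in a 60 x 60 arena with two
blocks on opposite walls. Bumping the red (active) block can trigger a brief
light flash — under a variable-interval schedule (VI, availability re-arms
after exponential intervals with mean 2 min) or a fixed-ratio schedule (FR1,
every bump flashes). Bumping the white (inactive) block never has
consequences. An experiment is 5 habituation days followed by 10
response-contingent days, each day a 15-min session, repeated over 10
independent replicates.

## The model

**Action selection.** Three action channels (explore, interact-red,
interact-white) run through a rate-coded basal-ganglia / thalamocortical
network of leaky-integrator populations, `tau da/dt = -a + I` with
`tau = 40 ms` and a piecewise-linear squashing of activation to rate. The
D1-striatum -> GPi/SNr pathway with diffuse STN excitation implements an
off-centre/on-surround competition; the winning channel's tonic inhibition
is released, its thalamo-cortical loop builds up, and the action is expressed
when its brainstem output exceeds `phi = 0.5`. Tonic dopamine `lambda = 0.2`
scales cortico-striatal transmission by `1 + lambda` (D1) and `1 - lambda`
(D2).

**Prediction and novelty salience.** The flash is a binary feature `y_f`
with a latent prediction `y*` updated after interactions with the red block:
`y* <- 1 - k (1 - y*)` on a flash (first flash sets 0.2), `y* <- k y*` on an
omission of a predicted flash, `k = 0.95`. Novelty salience is the tent map
`S_nov = 0.5 - |y* - 0.5|` — maximal when the outcome is completely
uncertain. Intrinsic block salience habituates geometrically
(`gamma_b = 0.95` per interaction within a day; day starts recover to
`gamma_a = 0.95` times the previous day's start). Exploration is driven by a
salience drawn from Uniform(0, 0.8) (mean 0.4, sd 0.23) once per second.

**Phasic dopamine.** At each evaluated red interaction, a collicular pathway
carries `[y_f - y*]+` and a canceling pathway `[y* - y_f]+` (so their
difference is exactly the sensory prediction error `y_f - y*`), as 0.2-s
triangular pulses with gains `a+ = 2`, `a- = 1` into an SNc integrator whose
unnormalized output is the simulated dopamine level `d = max(0, a_snc + 0.2)`
— resting level 0.2, bursts above, dips rectified at zero.

**Plasticity.** Cortico-striatal weights follow a dopamine-dependent BCM
rule, `dw/dt = eta y (y - <y^2> C(d)) x`, where `C(d)` blends
receptor-specific coefficient pairs measured at low and high dopamine via
`alpha(d) = 4d / (1 + 4d)`. Dips drive D1-LTD and D2-LTP (suppressing the
GO pathway); bursts drive strong D1-LTP (facilitating it). Updates are gated
to a short window at each phasic event.

## Worked example

```
$ actdisc run --schedule fr1 --pda --runs 2 --seed 1 --out results --quiet
schedule=fr1 pda=True r_peak=9 peak_day=1 flashes=76
outputs written to results/
```

This runs two replicates of the full 15-day FR1 experiment with the phasic
dopamine pathway enabled. `r_peak=9` is the peak mean daily active-response
count during response contingency divided by the mean daily inactive count
over that phase, rounded to the nearest integer; `peak_day=1` says the
responding peaked on the *first* response-contingent day (the signature of
reliable reinforcement: novelty salience spikes and collapses quickly as the
flash becomes predicted); `flashes=76` is the total number of delivered
flashes across both replicates. The output directory contains
`responses.csv` (per run/day/block/epoch counts), `events.csv` (one row per
completed interaction, with prediction, salience, dopamine excursion and
weight snapshots), `weights.csv` (per-day weight trajectories) and
`summary.json`; every file carries the config hash and seed.

Other entry points: `actdisc calibrate` (motor-weight calibration session)
and `actdisc selftest` (selection-competence battery plus exact unit-level
checks). All parameters can be overridden from a YAML file via `--config`.

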