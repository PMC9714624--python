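# colligaze

A spiking neural-network model of the midbrain superior colliculus (SC)
motor map driving an eye-head gaze-feedback controller, with the analysis
tools used to characterise it: movement-field fitting, phase trajectories,
rate-velocity correlations and main-sequence kinematics.

## The science

Rapid gaze shifts redirect the line of sight (gaze `G = E + H`, eye-in-head
plus head-on-neck) toward a target. The SC contains a topographic motor map
in which a neuron's anatomical position `u` encodes its preferred gaze
amplitude through a logarithmic afferent magnification

```
u = B_u · ln((ΔG + A)/A),          A = 3.0°, B_u = 1.4 mm
```

`colligaze` models one dimension of this map as a two-layer network of 200 +
200 adaptive exponential integrate-and-fire (AdEx) units on 0–5 mm. A
separable Gaussian-in-space, gamma-in-time input current recruits a localised
input population that drives the SC layer one-to-one; SC units interact
through a soft winner-take-all Mexican-hat scheme (narrow Gaussian
excitation, broad inhibition, site gain `S = 1 − 0.04·u²`). The adaptation
time constant (60→30 ms) and feedforward weight (10→4 nS) fall linearly from
the rostral to the caudal pole, so rostral (small-saccade) units fire short
high-frequency bursts and caudal units longer, lower-rate bursts, while each
recruited population emits a nearly constant number of spikes. The initial
eye-in-head position `E0` multiplies the adaptation time constant and the
lateral weights through a single affine gain `α(E0) = −0.005·E0 + 0.018`.

The population output is decoded by dynamic linear ensemble coding: each
spike of a unit at coordinate `u` adds a fixed gaze increment
`m = κ·A·(exp(u/B_u) − 1)` ("spike gaze vector"), so the running sum ΔG(t) is
the desired gaze trajectory and its smoothed derivative the desired gaze
velocity. `κ` is calibrated so a 15° target decodes to exactly 15°.

Downstream, a common gaze-feedback loop integrates desired-minus-achieved
gaze velocity into a motor error, converts it to a craniocentric error, soft
limits the desired eye position to the ±30° oculomotor range, and drives
linear eye (`B_E = 60 s⁻¹`) and head (`B_H = 20 s⁻¹`) burst generators. The
vestibulo-ocular reflex, its gain suppressed while the gaze error is large,
couples head velocity back into the eye; the head starts after a delay
`ΔT_H = 70 − 0.72·|ΔG| − E0` ms with recruitment gain
`g_H = 0.5·(1 + tanh(0.05·E0))` and a sluggish second-order plant.

Analyses quantify each unit's static movement field
`N = N0·(1 + ε·E0)·exp(−(u−u0)²/2σ_p²)`, the dynamic movement field
(cumulative spike count tracking the back-shifted fractional gaze
displacement), and the amplitude / peak-gaze-velocity main sequence.

## Worked example

```
$ colligaze simulate --target-amplitude 15 --eye-position 0 --out out/
wrote out/raster_15deg_e0+0.tsv
central unit spikes: 21, population spikes: 458
```

The central unit of the recruited population fires 21 spikes and the whole
population 458 — the model's signature spike-count invariance (≈20 per
central unit, ≈450 per population, at any amplitude and eye position).

```
$ colligaze gaze-shift --amplitude 25 --e0 -10 --out out/
decoded amplitude: 22.93 deg; terminal gaze displacement: 22.70 deg
```

A 25° target from a 10° contralateral eye position decodes to 22.93° (the
eye-position gain slightly reshapes the population) and the feedback loop
lands gaze within 1% of the decoded amplitude, splitting the movement
between a fast eye saccade and a delayed head contribution.

```
$ colligaze movement-field --unit-amplitude 20 --out out/
N0=25.85 spikes, u0=3.00 mm, sigma_p=0.18 mm, eps=0.0026/deg,
static r=0.995, dynamic r=0.874
```

The full movement-field protocol (amplitudes 5–55° in 2° steps, three eye
positions, 78 simulated gaze shifts) fits the 20°-unit's static field with
r = 0.995 and an eye-position sensitivity ε = 0.0026 spikes/deg, and tests
the dynamic linear phase relation pooled over all trials.

Other subcommands: `main-sequence`, `calibrate`, `run` (multi-condition
experiments from a YAML spec, with reproducible manifests).

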