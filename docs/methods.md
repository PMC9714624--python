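# Methods

This note documents the model equations as implemented, the parameters that
matter and where their values come from, the numerical choices, and the
places where the implementation had to make a design decision of its own.
It also states plainly which published operating points the shipped
configuration reproduces and which it does not.

## Network model

### Units

All 400 units (200 input-layer, 200 collicular) are adaptive exponential
integrate-and-fire neurons with two state variables, membrane potential `V`
and adaptation current `q`:

```
C dV/dt = −g_L (V − E_L) + g_L η exp((V − V_T)/η) − q + I_syn + I_ext
τ_q dq/dt = a (V − E_L) − q
```

A spike is registered when `V` reaches the threshold `V_T`; the membrane is
reset to `V_r` and `q` jumps by `b`. No refractory period beyond the reset is
modelled. Input-layer units are identical, non-interacting, and driven only
by the external current; SC units receive conductance-based synapses
(`I_syn = g_exc (E_e − V) + g_inh (E_i − V)`) whose conductances decay
exponentially (τ_exc = 3 ms, τ_inh = 20 ms) and jump by the connection
weight on each presynaptic spike.

The intrinsic constants (C = 150 pF, g_L = 10 nS, E_L = −70 mV, η = 2 mV,
V_T = −50 mV, V_r = −52 mV, a = 10 nS, b = 132 pA, E_e = 0 mV,
E_i = −85 mV) are **not published values**: they were re-tuned in this
package, by the brute-force grid search the `calibration` module implements,
against the population constraints the model must satisfy — about 20 spikes
for the central unit of the recruited population, about 450 spikes for the
population, a burst starting ≈20 ms after input-current onset, peak firing
rate decreasing and burst duration increasing from rostral to caudal target
sites. The reset 2 mV below threshold supports the high intra-burst rates
(500–1000 spikes/s) these constraints require.

### Map gradients and lateral connectivity

Per the published design, the feedforward weight falls linearly from 10 nS
(rostral) to 4 nS (caudal) and the adaptation time constant from 60 ms to
30 ms. Lateral weights follow a Mexican-hat difference-of-Gaussians:
excitation `0.16 nS · exp(−d²/2σ_exc²)` with σ_exc = 0.3 mm, inhibition
`(1 − 1.15·exp(−d²/2σ_inh²))` with σ_inh = 0.15 mm, clamped at zero where
the formula turns negative, zero on the diagonal. Both are scaled by the
site gain `S = 1 − 0.04 u²` and the eye-position gain `(1 + α(E0))`,
`α(E0) = −0.005·E0 + 0.018`.

Two readings of the site-gain index are possible; this package applies `S`
to the **sender's outgoing** synapses. The receiver-side reading was
implemented first and rejected: it equalises population totals across
amplitudes but leaves the central unit's count tracking the feedforward
ramp, destroying the spike-count invariance. With sender-side scaling the
whole recruited population's lateral interaction strength is set by the
target site, which, combined with a slow-tailed input pulse (rostral units
self-terminate through adaptation while fast-recovering caudal units keep
firing into the tail), produces near-invariant counts.

### Input

The external current is separable: a spatial Gaussian (σ_pop = 0.64 mm)
centred on the target's image point times a gamma-shaped pulse
`t^γ e^{−βt}` (γ = 3, β = 37 s⁻¹), normalised to peak 1 so that I0
(14 000 pA) is the realised maximum. γ, β, σ_pop and I0 are free parameters
fixed by the constraint search; the pulse rises over ≈20 ms (setting the
burst lag) and decays slowly enough for caudal units to reach their count.

### Integration

Forward Euler at dt = 0.01 ms with exact exponential conductance decay;
spikes take effect on the next step, making the update order unambiguous
and runs bit-reproducible. The spike-initiation exponent is clipped at 20
(the membrane resets at threshold anyway). Convergence is tested, not
assumed: halving dt leaves single-unit spike counts identical and moves
spike times by well under 0.1 ms.

## Decoding

Each spike of a unit at coordinate `u` contributes
`m = κ·A·(exp(u/B_u) − 1)` degrees. The cumulative sum is sampled on a 1 ms
analysis grid (exact, resolution-independent accumulation); the desired
gaze velocity is its Savitzky–Golay derivative. The filter default is
window 15, order 2: a cubic window-21 filter rings on the volley-stepped
cumulative sum (negative velocity dips beyond −100 deg/s and a ≈1.4% error
in the recovered displacement), while the quadratic window-15 filter keeps
the velocity non-negative and conserves the displacement integral to
machine precision. κ = 0.0024697 makes the decoded 15° condition exact.

## Gaze controller

Per 0.1 ms step: the comparator integrates desired minus fed-back gaze
velocity into `G_ERR`; `H_ERR = G_ERR + E` is the craniocentric error; the
desired eye position is `30·tanh(0.03·H_ERR)`; the eye burst generator
outputs `60 s⁻¹` times the eye motor error; the VOR
(`g_V = clip(1 − tanh(0.03·G_ERR), 0, 1)`) subtracts actual head velocity;
the head path, gated `ΔT_H = max(0, 70 − 0.72·|ΔG| − E0)` ms after eye
onset, commands `20 s⁻¹ · g_H · H_ERR` through a second-order plant
(250/150 ms). `E(t)` feeds back from the neural integrator (the velocity
command's integral); the 200/20 ms ocular plant only produces the reported
mechanical eye trace. Outputs are delayed by the common 10 ms efferent
delay.

Four elements are this package's own design, added because the equations
above do not close into a well-posed simulation on their own:

- **Saccadic off-latch.** The burst generator output is forced to zero and
  the VOR to 1 once `|G_ERR|` falls below 0.2° (and the collicular drive has
  ended); it reopens if the error regrows. Without it the burst path keeps a
  nonzero drive whenever the eye is eccentric after the shift and gaze
  drifts indefinitely. Only the loop's ON event is specified upstream.
- **Fixation anchor.** The tanh limiter outputs only 21.5° at a 30°
  argument, so it cannot hold an eccentric fixation: opening the loop from
  |E0| ≳ 15° would fire a spurious re-centring burst. An offset equal to
  `E0 − limiter(E0)` is added to the limiter output, decaying with
  τ = 200 ms and hard-clipped at the mechanical bound. Identical to the
  plain limiter at E0 = 0 and asymptotically.
- **Head-loop damping.** The head velocity command through the sluggish
  plant, coupled to the eye by the VOR, forms an underdamped loop
  (gain × lag ≈ 2.5): undamped simulations overshoot by tens of degrees and
  drag the eye far outside its range. A velocity-feedback term
  (−5·Ḣ, dimensionless gain, tuned on the isolated head loop for critical
  damping) stabilises it. Positional-servo re-readings of the head equations
  were tried and rejected: a latched displacement target breaks
  large-amplitude accuracy, a tracking target collapses as the eye
  re-centres.
- **Mechanical eye stop.** The globe cannot pass ±30° whatever the VOR
  commands; excess velocity is absorbed by the stop. The loop identity
  `Ė_DES = Ė + g_V·Ḣ` holds exactly on every sample where the eye is off
  its stop.

The simulated horizon is 2 s: most shifts complete within 300–600 ms, but
large shifts from far-contralateral eye positions close their final degrees
slowly (see Limitations).

## Analyses

Firing rates are Gaussian-kernel estimates (σ = 4 ms) on the 1 ms grid.
Movements are detected with a 20 deg/s velocity criterion and 5 ms
hysteresis; onset is the first qualifying crossing, offset the last.
The static movement field is fitted by trust-region nonlinear least squares
with five starts for the optimal coordinate (ties broken by lowest
residual). The dynamic movement field is the fitted static count scaled by
the 10 ms back-shifted fractional desired displacement, pooled against
simulated cumulative counts sampled every 10 ms from burst/gaze onset to
gaze offset. Rate-velocity correlations resample both profiles onto the
movement window, normalise to their maxima, and shift the rate by the 10 ms
neural lead. All thresholds are configurable.

The protocols mirror the published designs: movement fields from amplitudes
5–55° in 2° steps × E0 ∈ {−20, 0, +20}; spike-count sweeps over amplitudes
{15, 30, 45} × E0 ∈ −40…+40 in 10° steps; main sequence over 5–60° in 5°
steps × E0 ∈ {−30, −10, 0, +10, +30}. One network simulation (300 ms at
0.01 ms with 400 units) takes ~0.15 s; the full movement-field protocol
about half a minute.

## What the model reproduces, and what it does not

Reproduced with the shipped configuration (all recomputed by
`scripts/acceptance.py` and the test suite):

- the afferent map coordinates (2.05 / 2.85 / 3.73 mm for 10/20/40°);
- ~20 spikes for a unit at its own optimal amplitude (mean 20.3 over the
  10/20/40° units) and ~450 population spikes (mean 450.6 over the sweep);
- burst onset ≈19 ms after input onset; peak rate decreasing and burst
  duration increasing with target amplitude;
- positive eye-position sensitivity of burst counts with ε ≈ 0.0023–0.0054
  spikes/deg increasing rostral→caudal, matching the published per-unit
  values closely;
- decode linearity, 5%-accurate gaze for nearly all conditions, the
  eye/head division of labour and its E0 dependence (contralateral starts:
  faster gaze, larger eye, later and smaller head), head-onset delay
  behaviour, and the main-sequence increase below 40°.

Not reproduced — documented here rather than hidden:

- the tight 18–21 spike-count band across the full E0 range (this
  reconstruction spans 13–24: the count sensitivity to the eye-position
  gain is about twice the published one);
- the ≈20% contra→ipsi peak-rate modulation (measured ≈3%: with the
  published parameter ranges no pathway — adaptation, lateral weights, or
  recurrence at 0.16 nS — moves the early-burst rate that far; the
  published figure evidently depends on the unavailable supplementary
  constants);
- head displacements of ≈25°/≈5° at gaze offset for 55°/35° shifts
  (measured ≈32°/≈13°: the published 250/150 ms head plant moves little in
  the first 100 ms, and the tanh limiter caps the eye near 23.5° for a 35°
  craniocentric target, which makes a 5° head share arithmetically
  impossible under the published constants);
- the peak-velocity *drop* beyond 40° (peak velocity saturates but stays
  monotone: the slow head never shapes the velocity peak);
- the 0.98 dynamic movement-field correlation and 0.92/0.69 rate-velocity
  correlations (measured 0.87 and 0.31/0.20: the simulated gaze shifts are
  slower and longer than the bursts, stretching the phase relation);
- the ≈0.47 mm fitted tuning width (measured ≈0.18 mm; note that a
  Gaussian profile with σ_p = 0.47 mm, N0 = 20 and 200 units on 5 mm sums
  to ≈940 population spikes, so the published width, count and total are
  not mutually consistent — this reconstruction sides with the count and
  the total).

## Limitations

One-dimensional, horizontal movements only; no membrane noise, no
perturbations (blinks, head torques), no torsion or 3D kinematics. The
synthetic protocols exercise idealised stimuli: real collicular bursts are
noisy and the published recordings show trial-to-trial variability the
deterministic model cannot produce, so passing tests demonstrate the
internal consistency of the model, not fidelity to any particular animal's
data. Gaze shifts of ~60° from far-contralateral eye positions converge
slower than 5% accuracy within the 2 s horizon, because the printed head
gain `g_H(−30°) ≈ 0.05` nearly disables the head while the eye is capped by
the published range limiter.
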