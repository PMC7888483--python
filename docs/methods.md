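# Methods

## Model

### Channel kinetics

Each neuron carries `N_ChR2` independent channelrhodopsin-2 (ChR2/H134R)
channels described by a three-state Markov scheme — closed (C), open (O),
desensitized (D) — whose population fractions evolve deterministically.
With C = 1 − O − D the dynamics reduce to

    dO/dt = ε p(t) φ(t) (1 − O − D) − Γ_d(V) O
    dD/dt = Γ_d(V) O − Γ_r D

* φ(t) = σ_ret λ_max / (h c w_loss) · E(t) converts light intensity
  E (W/m²) into a photon flux at the retinal chromophore
  (σ_ret = 12·10⁻²⁰ m², λ_max = 470 nm, w_loss = 1.3);
* ε = 0.5 is the quantum efficiency of opening;
* p(t) = 1 − exp(−(t − t_light)/τ_ChR2), τ_ChR2 = 1.3 ms, delays opening
  after each pulse onset (the activation clock t_light resets at every
  onset; between pulses E = 0 and the light terms vanish);
* Γ_d(V) = Γ_d,0 (1 − 0.0056 mV⁻¹ (V + 70 mV)) with Γ_d,0 = 126.74 s⁻¹ is
  the voltage-dependent desensitization rate, clamped at zero (it would
  go negative only above ≈ +108 mV, far beyond the spiking threshold);
* Γ_r = 8.38 s⁻¹ is the recovery rate.

Open channels pass the depolarizing photocurrent
I_ChR2 = −(V − E_ChR2) N_ChR2 g_ChR2 O with g_ChR2 = 100 fS.  The
literature gives no reversal potential for this current; we default
E_ChR2 = 0 mV (the standard value for the unselective ChR2 cation
conductance) and expose it in the configuration.

The time-averaged opening rate of a rectangular pulse train with peak
intensity Ê, frequency f and pulse duration t_pulse has the closed form

    ⟨Γ_o⟩ = ε φ̂ f (t_pulse + τ_ChR2 (e^(−t_pulse/τ_ChR2) − 1)),

linear in both Ê and f; `chr2net opening-rate` tabulates it.

### Membrane and background input

The membrane is a leaky integrate-and-fire unit,
C_m dV/dt = −g_m (V − V_rev) + I_syn + I_ChR2, with τ_m = 10 ms,
g_m = 0.1 µS (hence C_m = 1 nF, which the tables leave implicit),
V_rev = −65 mV, threshold −55 mV, reset −70 mV, refractory period 3 ms.
During refractoriness the membrane is clamped at the reset potential.
Threshold crossings are detected at step boundaries and the spike time is
the post-step sample.

Background synaptic bombardment from outside the simulated circuit is an
Ornstein–Uhlenbeck current, τ_syn dI/dt = I₀ − I + σ_wn ξ(t), with
τ_syn = 5 ms and σ_wn = 0.01 nA interpreted as the amplitude of
unit-intensity white noise, so the stationary distribution is Gaussian
with SD σ_wn/√(2 τ_syn) = 0.1 nA.  This is the only reading under which
the tabulated mean current produces a firing baseline of a few hertz at
all: treating σ_wn as the stationary SD leaves the neuron silent.  The
update is the distributionally exact discretization, so OU statistics do
not depend on the step size.  `calibrate_I0` bisects I₀ against measured
unstimulated rate (single-neuron or network context) and absorbs any
residual convention differences; with our scheme a 5 Hz single-neuron
baseline corresponds to I₀ ≈ 0.910 nA, about 0.5% below the published
0.914576 nA (which yields ≈ 5.4–5.5 Hz here).

### Network

3600 excitatory neurons on a 60 × 60 grid plus 900 inhibitory neurons;
every ordered pair is independently connected with probability p_c
(0.5–1.5%), identically for all four connection classes.  A presynaptic
spike adds J_ij/τ_syn to the target's input current, which decays with
the exact factor exp(−dt/τ_syn), so the integrated postsynaptic current
equals the coupling charge J_ij (E→E 0.110, E→I 0.190, I→E −0.340,
I→I −0.540 pC).  There are no synaptic delays or transmission failures.
Inhibitory neurons share the excitatory intrinsic parameters, have no
spatial position, express no channels and receive no light; all neurons
get independent OU inputs.  Light reaches only the excitatory grid, with
per-neuron peak intensity Ê exp(−r²/(2σ_light²)), σ_light = 8 grid
units, centered at ((√N_E − 1)/2, (√N_E − 1)/2) = (29.5, 29.5) so the
peak sits symmetrically between the four central neurons.  (One figure
caption in the source literature illustrates σ_light = 12; the tabulated
value 8 is the default, and it is configurable.)

## Numerics

Explicit Euler for channel and membrane at a common step: 0.01 ms for
single-neuron work, 0.1 ms for networks.  The channel state is clipped
back to the probability simplex if a step overshoots (counted and
warned; does not occur at the default steps).  The per-step light drive
ε p(t) φ(t) is precomputed from the pulse schedule; pulse onsets are
aligned to the simulation clock.  The inner loop is compiled with numba;
noise is pre-drawn in chunks from a seeded numpy Generator, and results
are bit-identical for a given (seed, config) and independent of the
chunk size.  The single-neuron batch driver and the network driver share
the same compiled kernel, so at p_c = 0 the network reproduces isolated
neurons exactly — this is tested.

Synaptic spike delivery happens at the end of the step in which the
spike is detected, i.e. the evoked current first acts one step later;
at 0.1 ms against τ_syn = 5 ms this is negligible.

## Measurement layer

* Firing rates: sliding boxcar counts (window default 1 ms for
  pulse-shape statistics — fine enough to resolve the ≥ 4 ms response
  features; not stated in the source, exposed as a parameter).
  Per-neuron time-averaged rates are spike counts over the analysis
  window divided by its duration.
* Steady-state pulse statistics: cycles after a 100 ms onset skip are
  phase-aligned at pulse onsets and averaged; the response minimum and
  maximum are the extrema of the mean cycle and the pulse duration is
  its full width at the level halfway between them (an alternative
  "half of absolute maximum" convention would differ; the halfway
  reading matches the published min/max arrows).  Crossings are linearly
  interpolated; the cycle is treated as circular, and with multiple
  crossing pairs the widest contiguous region containing the maximum is
  used.  Flat cycles (e.g. duty cycle 1) yield an undefined, flagged
  FWHM.
* Spatial profile: weighted nonlinear least squares (scipy
  `curve_fit`) of ν(r) = (ν_max − ν_base) exp(−r²/(2σ_FR²)) + ν_base
  against all per-neuron (signed radius, mean rate) points with a
  uniform 0.2 Hz tolerance; initialized at (σ_light, max, min) with up
  to 5 jittered restarts, parameters bounded non-negative and the width
  bounded by the grid span.  Flat profiles are returned flagged instead
  of fitted.  The signed radius (sign of x − x_c; + on the center line,
  which cannot occur on an even grid with a half-integer center) only
  spreads the radial profile over a line for fitting and display.
* Pulse locking: fraction of (trial, pulse) pairs with at least one
  spike within a 10 ms window after pulse onset, compared against the
  chance level 1 − exp(−rate · window) of an unstimulated neuron.

## Study conditions and scaled-down problem sizes

The published protocol uses 20 s runs, 900 trials for single-neuron
statistics and 10 trials for networks.  The package defaults keep the
20 s / 4 ms-pulse protocol; the test suite and the acceptance script run
reduced sizes chosen once as adequate for the respective claims:
100 trials for the frequency-trend sweep, 20 × 20 s trials for baseline
rates and locking, and 5 s × 2 trials per grid point (with per-p_c
recalibrated I₀, 2 s calibration runs) for the network spatial sweep.
Connectivity is redrawn per trial with trial-indexed seeds; noise
streams are independent per trial.

## What the generated data does and does not show

All data are generated by the model itself under the tabulated
parameters; there is no external dataset.  Passing tests therefore show
internal consistency with the stated kinetic/membrane/network model and
its analytic limits, and reproduction of the published summary
statistics under the published parameters — not agreement with any
biological recording.  Real tissue adds light scattering, heterogeneous
expression, conduction delays, synaptic failures and non-LIF membrane
dynamics, all deliberately outside this model.

## Known limitations and open choices

* The three-state scheme cannot produce biexponential photocurrent
  decay, light-assisted recovery or inward rectification (four-state
  extensions, deliberately excluded).
* The response minimum of the firing rate is a deep post-pulse dip
  produced by spike synchronization; at 5 mW/mm² its depth is nearly
  identical for 5–20 Hz stimulation (differences of a few tenths of a
  hertz), so the rise of the minimum with frequency is resolved as a
  trend across the full frequency range rather than strictly between
  every adjacent low-frequency pair.
* The fitted baseline ν_base rises slightly between 1 and 2 mW/mm²
  before recurrent inhibition dominates; its published monotone decline
  with intensity holds from about 2 mW/mm² upward, where we test it.
* Expression is implemented as an identical channel count per excitatory
  neuron ("on average 60,000/300,000" in the source; no distribution is
  given).  An optional spread was considered and omitted as
  unconstrained.
* The baseline-rate residual at the published I₀ (≈ 5.4–5.5 Hz instead
  of 5.0) is documented above; all network results use the package's own
  calibration rather than the printed constant.
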