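# Methods

## Model

`shepnet` simulates a Wilson–Cowan-type rate network on a discretized
tonotopic axis. Each location `x` (octaves) carries four state variables:
the normalized rates `r_up`, `r_down`, `r_I` of two direction-selective
excitatory populations and one inhibitory population, and the facilitation
level `F` of the inhibitory synapses originating at `x`. The equations are
listed in the README; this note records assumptions, parameter meanings and
the numerical and design choices.

Core assumptions:

* **Deterministic dynamics.** No noise process enters the ODEs; across-trial
  variability comes exclusively from the random pitches of context tones.
* **Strictly one-sided inhibitory footprints.** `E_up` receives inhibition
  only from equal-or-higher characteristic frequencies, `E_down` only from
  equal-or-lower ones (the `y = 0` sample belongs to both one-sided kernels;
  on an even ring the antipodal sample — displacement exactly half the
  circumference — is likewise shared, preserving exact discrete mirror
  symmetry). Unit-area normalization is applied after sampling, so the
  discrete sum × Δx equals 1 exactly.
* **Facilitation is presynaptic.** The factor `(1 + γ_f F)` (and any
  heterogeneous `a_ie` profile) multiplies the inhibitory rate at the
  presynaptic location before the spatial convolution.
* **Idealized afferent drive.** A tone of pitch class `x0` drives the
  network with `exp(−(x−x0)²/σ_in²)` — note there is no factor 2 in the
  exponent, so `σ_in` is an e-folding half-width, not a standard deviation —
  gated by raised-cosine ramps. No cochlear filtering or loudness model.

## Parameters

| symbol | meaning | default |
|---|---|---|
| τ_e, τ_i | rate relaxation times | 20 ms, 30 ms |
| τ_fr, τ_fd | facilitation rise / decay | 100 ms, 2000 ms |
| θ_e, k_e | E-sigmoid threshold / slope | 0.5, 0.1 |
| θ_i, k_i | I-sigmoid threshold / slope | 0.3, 0.2 |
| a_ee, a_ei, a_ie | synaptic gains | 0.7, 2.0, 1.5 |
| γ_f | facilitation gain on inhibition | 2.0 |
| γ_e, γ_i | input gains | 0.6, 0.2 |
| σ_ee, σ_ei | Gaussian footprint widths | 0.02, 0.08 oct |
| σ_ie | one-sided exponential scale | 0.3 oct |
| σ_in | tone drive width | 0.1 oct |
| τ_r | on/offset ramp time constant | 5 ms |

The *broad inhibitory tuning* regime (`NetworkParams.broad()`) atomically
overrides σ_ee = 0.05, σ_ei = 0.2 oct and a_ee = 1.5 (wider E→E and E→I
footprints with recurrent excitation raised to keep firing comparable);
everything else is unchanged. Narrow tuning is the default everywhere.

Paradigm timing defaults: 100-ms tones, 50-ms inter-tone interval (also the
tritone pause), 500-ms gap between a bias sequence and the test pair. Bias
pitches are drawn from a continuous uniform distribution on the open
half-octave above (Up) or below (Down) T1; a configurable semitone sub-grid
is available since the granularity used in the human experiments is not
fixed by the model.

## Gain function

The gain is the normalized logistic
`S(x) = s0·(1/(1+exp((θ−x)/k)) − x0)`, `x0 = 1/(1+exp(θ/k))`,
`s0 = 1/(1−x0)`, so `S(0) = 0` (rest is a genuine fixed point) and `S → 1`.
The slope parameter divides the argument — the standard logistic convention;
multiplying by `k` would invert the meaning of the printed slopes. The raw
normalized logistic is slightly negative for negative net input (down to
`−s0·x0 ≈ −0.0067` for the E populations), which would let strongly
inhibited units sit just below zero rate. Because the firing rates are
defined on [0, 1], the implementation floors `S` at 0; the floor is inactive
for all non-negative inputs, and with it every rate and `F` remain in [0, 1]
for any stimulus (verified as a test invariant). `sigmoid(..., floor=False)`
exposes the raw strictly-increasing form.

## Numerics

* **Grid.** Ring: 100 points, Δx = 0.01 oct (one octave, periodic). Line
  grids use the same Δx and must carry ≥ 3·σ_ie margin beyond the outermost
  stimulus component; edges are absorbing (zero-padded convolution, no edge
  renormalization — the margin makes edge effects irrelevant, which the
  chord experiments respect by construction).
* **Convolutions** are Riemann sums with weight Δx, evaluated as
  precomputed real-FFT products (circular on the ring, zero-padded on the
  line). A brute-force O(n²) direct-sum oracle cross-checks them in the test
  suite at 1e-12.
* **Time stepping.** Classical RK4 with step-doubling error control: a full
  step is compared against two half steps; the Richardson local-error
  estimate `(y_half − y_full)/15` is held below `atol + rtol·|y|`
  per component with atol = rtol = 1e-5. The half-step solution is kept (no
  extrapolation), so the method is plain 4th order. Max step 1 ms (keeps
  recorded traces dense enough for windowed readout), min step 1e-4 ms
  (underflow raises a diagnostic with the failure time). Steps never cross
  tone onsets/offsets or readout-window edges. Batched trials that share
  event timing are integrated in lockstep; the controller uses the worst
  error across the batch, so batching never loosens accuracy.
* **Readout.** Window means are accumulated online with the trapezoid rule
  on accepted steps (window edges are integrator breakpoints, so no
  interpolation error enters); `D = 0` with an explicit warning when the
  summed response is below 1e-9. Windows are closed `[onset, offset]`, and
  the spatial integral runs over the whole domain.

## Design choices on underdetermined points

* **Ramp form.** `ramp(t) = ((cos(π(t/τ_r+1))+1)/2)²`, rising smoothly 0→1
  over τ_r; the squared raised cosine is C¹ at both ends, which is the
  property that matters for click-free gating.
* **Descending choices.** Only the ascending rule (`D > 0.1`) is canonical;
  by the model's exact up/down symmetry descending is defined as
  `D < −0.1`, and non-ascending trials (including ambiguous ones) stay in
  the psychometric denominator.
* **Facilitation "off".** Static inhibitory synapses are realized as
  γ_f = 0, equivalent to freezing `F ≡ 0`.
* **Tuning-curve lean.** The published shape claim is a *lean* of the curve
  toward lower (E_up) or higher (E_down) pitch classes. The weighted
  third-moment skewness of the simulated curves is dominated by the far
  tail and can contradict the visible lean, so `tuning_skewness` reports
  the normalized response-mass imbalance about the unit's pitch class
  (positive = leaning lower). Signs and exact antisymmetry are tested.
* **Heterogeneous `a_ie`.** Exposed as an arbitrary per-location profile or
  callable; the demo profile is a Gaussian bump (default center 6 st,
  e-folding half-width 2 st, amplitude 0.5 over base 1.5), whose steepest
  slopes at center ± width/√2 locate the predicted D extrema. Amplitude and
  width are free since only the shape is constrained.
* **Pair-response maps** randomize initial conditions with one
  random-pitch pre-tone per run (10 runs averaged), placed one inter-tone
  interval before T1.
* **WTA weights.** The reduction's weights and inputs have no canonical
  values. The shipped scan utility (`wta.scan_symmetric`) searched symmetric
  sets for the three-state competition layout; the chosen defaults
  ω_ee = 0.75, ω_ei = 1.0, ω_iu = ω_id = 1.0, In_e = 0.65, In_i = 0
  (τ_E = 20 ms, τ_I = 30 ms, sigmoids shared with the network) give U and D
  stable and S a saddle *and* converge in the full 3-variable system —
  many sets that pass the planar criteria develop slow limit cycles around
  the dominance states when the inhibitory dynamics are restored, so 3-D
  convergence was part of the selection. Stability is classified on the
  reduced planar system (instantaneous `I`), with the full 3-D Jacobian as
  a cross-check. The asymmetric demonstration uses ω_id = 1.2, inside the
  verified window where a single U state remains and attracts the origin.

## What the synthetic stimuli do and do not emulate

The generator produces the idealized drive fields of the paradigms —
tritone pairs with uniformly drawn bias sequences, sequential tone pairs of
any step, and pure-tone chords with a shifted test tone — plus optional WAV
renderings (flat-envelope octave stacks) for demonstration. It does not
model peripheral filtering, loudness, masking, or listener-specific pitch
reference effects; passing tests therefore validate the network mechanism
under the stated drive model, not a full auditory pathway.

## Problem sizes used in routine runs

Sweeps resolve the reported extrema with 0.25-st bias-pitch grids and
0.02-oct frequency-shift grids. The psychometric buildup uses 100 trials
per N_bias point in routine runs (binomial SEMs are reported and the full
400-trial protocol is a parameter away). Step-response, tuning and
pair-map protocols use the full printed layouts. These sizes resolve every
qualitative and quantitative claim the tests assert.

## Known limitations

* The ring discretization fixes pitch resolution at 0.12 st; extrema
  locations inherit the sweep-grid resolution.
* Line-topology chords require the stated margins; components closer than
  ~3·σ_ie to an edge would see truncated recurrent input.
* The model is deterministic; psychometric spread comes only from stimulus
  sampling, so P(up) saturates harder than human data at large N_bias.
* No reaction times or drift-diffusion readout — decisions are window
  averages.
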