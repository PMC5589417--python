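# Methods

This note documents the model, the numerical choices, and the calibration
behind `silentwm`, in the order the package's modules use them.

## Ring attractor with short-term plasticity (`silentwm.network`)

The network is a one-dimensional continuous attractor: N rate neurons at
equally spaced preferred angles θ ∈ [−π, π) with periodic boundary,
recurrent excitation through a translation-invariant truncated-cosine
kernel, and a single global inhibitory pool. Each excitatory synapse
carries short-term facilitation u (release probability, baseline U,
recovery time τ_f) and depression x (available resources, recovery time
τ_d); synaptic efficacy is proportional to u·x. Because τ_f ≫ τ_d, a
transiently active assembly leaves a facilitation trace that outlives its
firing by seconds — the substrate of activity-silent maintenance.

Default parameters (all exposed on `NetworkParams`):

| parameter | default | units | role |
|---|---|---|---|
| N | 100 | – | neurons on the ring |
| τ | 0.008 | s | current/firing-rate time constant |
| J₁, J₀, B | 12, 1, 2.2 | – | kernel amplitude, uniform floor, width factor |
| J_EI, J_IE | 1.9, 1.8 | – | inhibitory loop couplings |
| I_b | −0.1 | Hz | background current |
| δ₁, δ₂ | 0.3, 9 | Hz | background / stimulus noise amplitude |
| U | 0.3 | – | baseline release probability |
| τ_f, τ_d | 4, 0.3 | s | facilitation / depression time constants |
| α | 1.5 | – | gain smoothing, R(h) = α·ln(1+e^{h/α}) |
| ρ | 0.0716·N/(2π) | rad⁻¹ | neuronal density (calibrated, see below) |
| dt | 0.001 | s | integration step (part of the protocol definition) |
| noise_dt | 0.001 | s | hold time of the noise currents |

`U` is not constrained by the other printed constants; 0.3 is the standard
value in the short-term-plasticity literature and is exposed in the
configuration.

### Integration scheme

Currents (h_E, h_I) advance by explicit Euler with step dt. The
facilitation and depression equations are linear in u (resp. x) given the
instantaneous rate but become stiff during population spikes (u·R·dt ≈ 1 at
dt = 1 ms); they are therefore advanced by exponential Euler — the exact
solution of the conditionally linear equation over one step — which keeps
u ∈ [U, 1] and x ∈ (0, 1] without overshoot at any step size. Divergence
of any state component raises an error naming the component.

### Noise

The printed noise amplitudes (δ₁ = 0.3 background, δ₂ = 9 during external
stimuli) are treated as fluctuating *input currents* in the same units as
the stimulus amplitudes: a standard-normal draw per neuron, scaled by δ,
entering the current update exactly like I_e, redrawn every `noise_dt`
(1 ms) and held in between. Holding the draws for a fixed physical time
makes the noise process — and hence the simulated statistics — independent
of the integration step. Two modes mirror the two ways the study conditions
can be run: `continuous` (δ₁ always on, δ₂ during stimuli; default) and
`input_only` (δ₂ only). Both yield the same regime statistics here, because
the trial-to-trial variability is dominated by the δ₂ mask noise: a ±9 Hz
jitter riding on a 62 Hz mask.

We deliberately do **not** scale the noise as a √dt diffusion term. Under
that scaling δ₁ = 0.3 corresponds to a current fluctuation with standard
deviation ≈ 2.4 sustained over the 3 s delay, which ignites the bump on
essentially every trial regardless of mask amplitude and erases the
regime dichotomy the model is built to exhibit; read as input-current
fluctuations, the same printed amplitudes reproduce it.

### Calibration of ρ and the target width

The neuronal density ρ multiplies the recurrent integral and is only
identifiable jointly with the synaptic amplitudes; the naive choice
ρ·Δθ = 1 makes the rest state explosively unstable with the printed
couplings. ρ and the spatial width of the Gaussian target input are
therefore calibrated, once, against the published operating point of the
delayed-response protocol, with three simultaneous requirements:

1. noiseless bisection of the mask amplitude between 50 Hz (reactivating)
   and 65 Hz (silent) converges near 62 Hz;
2. with the mask fixed at 62 Hz and noise on, roughly half of the trials
   contain spontaneous delay reactivations;
3. both per-regime response histograms peak at zero positional error.

The shipped values are ρ = 0.0716·N/(2π) and width 0.35 rad (SD). At this
point the noiseless critical amplitude is 64.8 Hz, the noisy reactivating
fraction at 62 Hz is ≈ 0.48–0.51 across seeds, and both histograms are
modal at offset 0. Narrower targets (≤ 0.25 rad) leave a facilitation
profile whose noisy maximum is displaced by ~1 position, shifting the
reactivating-regime histogram mode off zero: the first spontaneous
reignition lands at the displaced maximum and rewrites the trace there.

### The critical amplitude is a bifurcation point

The regime boundary in mask amplitude is a bifurcation of the noiseless
dynamics, and an O(dt) change in effective recurrent gain moves it by
several Hz. The simulated regime statistics are therefore defined *at* the
default step dt = 1 ms, which should be treated as part of the protocol
(like the stimulus timings), not as a numerical knob. Trace-level
observables away from the bifurcation converge under step refinement
(delay-period rasters of a smooth maintenance trial agree to ≈ 1.5%
relative L2 between dt = 0.5 ms and 0.25 ms, with at-least-linear error
decay); this is what the self-convergence test checks.

## Simulation protocol (`silentwm.protocol`)

Timings: target 390 Hz for 50 ms at a grid location, 17 ms gap, spatially
uniform mask for 200 ms (62 Hz default), 3 s delay, uniform 10 Hz recall
for 50 ms. The state starts at rest (h_E = I_b, u = U, x = 1, h_I = 0)
200 ms before target onset.

*Regime classification.* A trial is `reactivating` iff the peak rate in
the delay window (mask offset + 50 ms to recall onset, excluding
transients) exceeds a threshold. The default threshold is scale-free: the
midpoint between the baseline rate gain(I_b) and the peak bump rate during
a noiseless target presentation with the same parameters, computed once
per parameter set and overridable in Hz. Delay reactivations are
population spikes only a few milliseconds wide, so classification always
uses undecimated rasters.

*Readout.* The recalled angle is the argument of Σ_θ R̄(θ)·e^{iθ} with R̄
the time-averaged rate over the recall pulse. A mean resultant length
below 10⁻³ (spatially uniform activity) flags the readout invalid rather
than returning an arbitrary angle.

*Critical amplitude.* Bisection on the noiseless model; the bracket
endpoints must classify as reactivating (low) and silent (high), otherwise
the search aborts — this also guards the monotonicity assumption.

*Batched experiments.* `run_experiment` integrates trials in vectorized
batches (one matrix product per step across the whole batch), recording
only the per-trial delay peak and the recall-window rate profile; 4000
trials take ~1.5 min on one CPU. Target locations are drawn from the
20-position task grid.

## Behavioral mixture model (`silentwm.mixture`)

Signed offsets n = ((response − target + 10) mod 20) − 10 give 20 bins
−10…+9; the asymmetric extreme bin (−10) lies outside the ±2 region and
never affects the memory distribution. The guess rate is the mean of the
outside-region histogram rescaled by N (15 outside bins for N = 20, a = 2),
clamped to [0, 1] because finite samples can push the raw value past 1.
The memory distribution subtracts the uniform floor, truncates to ±2,
zeroes residual negative mass and renormalizes; precision is its SD (1
position = 18°). When p̂ ≈ 1 the memory distribution is undefined and the
fit reports precision as undefined rather than a number. Fits require at
least 5 trials per histogram. Eligibility uses a 1-df Pearson χ² of the
correct/incorrect split against chance 25%, one-sided: significantly
*below*-chance performance does not qualify.

## Circular–linear correlation (`silentwm.circstats`)

The statistic is the multiple correlation of the signal on (sin θ, cos θ):
ρ² = (r_xs² + r_xc² − 2 r_xs r_xc r_sc)/(1 − r_sc²), verified against an
explicit least-squares oracle to 10⁻¹⁰. It is invariant to affine
transforms of the signal and global rotations of the angles; degenerate
inputs (zero-variance signal, collinear sin/cos) are rejected or flagged
NaN. The empirical baseline shuffles the trial-to-label assignment once
per permutation and reuses it across all channels and time points of a
map, preserving the spatial/temporal covariance of the null; Δρ is the
observed map minus the null mean (1000 permutations by default, seeded).
A-priori windows: 100–300 ms, 300–600 ms, 0.6–1.55 s, 1.55–2.53 s;
baseline −200 to −50 ms.

## Decoding (`silentwm.decoding`)

Stratified cross-validation: 5 folds for categorical labels, 2 for
circular (stratified over the 20 discrete positions). Per training fold
and train time: one-way-ANOVA feature selection keeping the top 50% of
channels (ties broken by feature index; undefined F ranks last),
z-scoring with training-fold statistics, then a linear SVM
(inverse-class-frequency weights) for categories or two linear
support-vector regressions predicting sin θ and cos θ, recombined with
atan2, for angles. Regularization is fixed at C = 1 — not tuned per fold,
keeping runs deterministic. Categorical performance is the ROC AUC of the
decision values across all held-out trials (midrank ties); circular
performance is π/2 minus the mean absolute wrapped error (chance 0,
perfect π/2). Temporal generalization tests every classifier at every
other time sample; cross-condition generalization applies each fold's
classifier to the entire independent test set and averages predictions
(arithmetically for decision values, as unit vectors for angles) before
scoring. An optional baseline correction subtracting the mean score over
the −200 to −50 ms samples of the same train-time row is available but
off by default, since the exact form of such corrections is convention.

## Synthetic data (`silentwm.synth`)

*Behavior.* Trials follow the mixture family by construction: targets
uniform on 20 positions; with probability p_guess (per visibility rating,
defaults 0.8/0.45/0.15/0.05 for ratings 1–4) the response is uniform,
otherwise target plus a discretized zero-mean Gaussian truncated to ±2
positions (the family's support assumption; note truncation shrinks the
realized SD below the nominal parameter). Visibility ratings are drawn
with probabilities 0.45/0.2/0.2/0.15, a threshold-masking-like mix with
almost half unseen trials.

*Epochs.* trials × channels × time arrays at 250 Hz (−0.2 to 2.5 s
default) containing Gaussian sensor noise, a linear sin/cos angle code on
a random channel subset inside a configurable window, and an additive
category topography inside another window, both with raised-cosine ramps
and trial-to-trial amplitude jitter. Ground truth (channels, windows) is
recorded in the metadata for assertions.

What the generators do **not** emulate: oscillatory content, realistic
sensor covariance or forward fields, autocorrelated noise, eye-movement
artifacts, nonstationary codes. Passing tests therefore demonstrate the
estimators' correctness and calibration on data satisfying their own
assumptions, not robustness to real-recording pathologies.

## Known limitations

- The regime statistics (critical amplitude, reactivating fraction) are
  properties of the discrete-time system at dt = 1 ms; refining the step
  moves the bifurcation and would require recalibrating ρ.
- ρ and the target width are calibrated to the published operating point,
  not derived; other (ρ, width) pairs give the dichotomy at other mask
  amplitudes.
- The noiseless reactivation cadence (~4 spikes per 3 s delay) depends on
  the unprinted U; the shipped default is the literature standard.
- Single-item memory only; no distractor input is modelled in the network
  (the analysis modules accept distractor labels, the simulator does not
  implement a second stimulus).
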