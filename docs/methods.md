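# Methods

## Problem setting

Epiretinal electrical stimulation through one electrode of a dense
multi-electrode array (MEA) evokes spikes in nearby retinal ganglion cells,
but the injected current also produces a stimulation artifact that can last
~2 ms, overlap the 0.4–0.6 ms response latency of the cells, and dwarf the
spikes — especially on the stimulating electrode, where it can also be
nonlinear in the stimulus amplitude. `dynsort` separates evoked spikes from
the artifact by exploiting their distinct *spatiotemporal* propagation
across the array, modeled with linear dynamical systems.

## Models

**EI model (per neuron).** The electrical image (EI) of neuron *n* — its
mean spatiotemporal spike footprint — is represented by a discrete-time
linear system

    x_n[t+1] = A_n x_n[t] + B_n u_n[t],      y_n[t] = C_n x_n[t],

whose states are the voltages on the neuron's *relevant electrodes* (those
with peak |EI| ≥ 10% of the global peak by default). C_n is therefore a
selection matrix and the output is identically zero elsewhere. The input
template r_n has two unit pulses: one placed one sample before the spike
first emerges anywhere on the footprint (it seeds the depolarization), one
at the dominant-electrode trough (it seeds the repolarization rise).
Placing pulses at phase *onsets* matters: a pulse must arrive while the
true state is still ≈ 0 so that B_n can inject the full transient; a
pulse placed mid-phase leaves the zero-state simulation unable to launch.

**Identification (both model families).** Because the states are observed,
identification is a multi-output ridge regression of x[t+1] on
(x[t], u[t]) (default ridge 1e-3 µV²), with two additions:

1. *Causality clamp*: EI samples up to the first pulse are set to zero in
   the fit. Synthetic and real EIs have a sub-threshold onset tail; without
   the clamp the regression lets A "explain" the growth out of that tail,
   which a zero-state simulation can never reproduce (observed simulation
   error ≈ 100%).
2. *Simulation-error refinement*: the regression minimizes one-step
   residuals, but errors compound over the ~2–3 ms transient. A subsequent
   L-BFGS polish (adjoint/backpropagation gradients, default 2000
   iterations) minimizes the error of the trajectory actually simulated
   from rest — which is the real objective: the template-driven model
   should reproduce the EI. On the synthetic preparations this lowers
   SNRMSE from ~0.2–0.35 to 0.01–0.04.

Fit quality is reported as SNRMSE — RMS(EI − prediction)/RMS(EI) over the
relevant electrodes.

**Artifact model.** Same state-space form on the electrodes within
`artifact_radius` (default 240 µm) of the stimulating electrode; the
stimulating electrode itself is *structurally excluded* (never a state,
never an output, never in an error metric) because its artifact is largest
and amplitude-discontinuous. The input template r_a has three unit pulses
at the stimulation onset (t = 0, 1, 2), scaled by the stimulus amplitude q
at use (u_a = q·r_a); the pulse gains are absorbed into B_a. The model is
identified by pooling trial-averaged recordings over the lower half of the
amplitude grid (averaging only estimates the artifact where stimulation
rarely evokes spikes), with a 10% trimmed mean per sample to resist
evoked-spike contamination. Linearity in q is exact by construction, so
the simulation-error refinement collapses the pooled multi-amplitude
objective onto a single unit-amplitude target (the q²-weighted average of
avg_q/q); without the refinement, averaging noise in the one-step fit
compounds to ~15% simulation error over the 2+ ms transient, which is
exactly the structured residual that would otherwise leak into the input
estimates of neurons near the stimulating electrode. Fit quality is
ANRMSE, normalized like SNRMSE.

**Aggregate model.** All EI models (ascending neuron id) plus the artifact
model are stacked block-diagonally; the array output is the *sum* of
sub-model outputs plus i.i.d. Gaussian measurement noise (superposition).
There is no process noise.

## Input estimation

Spike inference inverts the aggregate model. At each step t the estimator
takes the measurement window y[t..t+L] (default L = 10 samples = 0.5 ms),
subtracts the free response of the propagated state estimate and the known
artifact contribution (stimulation timing and amplitude are known), and
solves one regularized least squares for all EI inputs in the window,
keeping the step-t block. Rows belonging to corrupted electrodes (by
default the stimulating electrode) are deleted; identifiability requires
the current-step input map to keep full column rank 2N, which the dense
array's redundancy provides.

Two design points:

* *Joint window inputs, not future-zero.* Estimating only the current
  step's input while assuming the rest of the window silent biases the
  estimate whenever the template's second pulse falls inside the window of
  the first; joint estimation keeps noiseless recovery exact for any number
  of simultaneously firing neurons.
* *Innovation state correction.* Open-loop propagation of the estimated
  inputs is unstable under noise (input errors feed the state through B and
  grow through the error dynamics A − B·(MΦ)). A second stage fits a
  ridge-regularized state correction (default state ridge 1.0) to the
  *leftover* window residual, after the estimated inputs' contribution is
  removed. On noiseless data the leftover is zero, so exactness is
  untouched.

The input ridge default is 300 µV², interpretable as measurement-noise
variance (≈1 µV²) divided by a small prior input variance; it was
calibrated on synthetic true/false score-separation experiments — the same
way the original workflow tunes its hyperparameters on synthetic data —
with the binding case being a neuron sitting directly behind the
stimulating electrode, whose peak electrode is excluded from estimation.
Because detection scores against estimator-matched references (below), the
shrinkage bias this ridge introduces costs detection nothing, while it
strongly suppresses the noise that collinear window columns would otherwise
amplify. Exactness tests use ridge 0 (rank deficiency there is a hard
error, never a silent pseudo-inverse).

## Spike detection

A spike is called for neuron n when the similarity between its estimated
input block and its template, maximized over candidate latencies (default
0–30 samples), reaches θ = 0.5. Two similarity variants exist:

* `similarity`: cosine between the estimated block and the raw template
  shifted by each latency (score in [−1, 1]; a numerically zero estimate
  scores 0 by convention).
* matched references (used by the pipeline): cosine against *the template
  as seen through the estimator* — the estimator's own noiseless response
  to that neuron firing alone at that latency. Since the estimator is
  linear, this is exactly the systematic part of a noisy estimate, making
  the score invariant to the ridge bias and temporal smearing the estimator
  introduces. With an exact (ridge 0) estimator the reference *is* the
  shifted template and the two variants coincide.

For small instances an exhaustive oracle enumerates every neuron subset ×
latency combination, scores each by residual sum of squares on the
non-excluded electrodes, and breaks ties toward fewer spikes, then lower
latencies. It is used purely as an independent check of the detector.

At most one spike per neuron per trial is considered: the 2.75 ms analysis
window is shorter than typical inter-spike intervals.

## Activation analysis

Per neuron–electrode pair, detections are aggregated into an activation
curve (spiking probability vs amplitude). The 50% threshold comes from a
maximum-likelihood logistic fit in *log* amplitude (the grid is
log-spaced): p(q) = σ((ln q − ln q50)/s), optimized by Nelder–Mead on the
Bernoulli likelihood; all-0/all-1 outcomes are flagged unconverged rather
than raised, and the threshold is undefined unless the curve reaches 50%.
K-fold validation (K = 5, stratified by amplitude) refits the artifact
model on K−1 folds and sorts the held-out fold, so every trial is scored by
a model that never saw it. Threshold sets are compared by R²; the default
is squared Pearson correlation, with an identity-line variant
(1 − SS_res/SS_tot about y = x) also available.

## Synthetic data

The generator emulates the recorded preparation:

* geometry: rectangular MEA grids (default 16×32 = 512 electrodes, 60 µm
  pitch, 20 kHz sampling);
* EIs: a difference-of-Gaussians biphasic waveform (dominant trough, 45%
  overshoot) traveling along a polyline axon at 30 µm/sample, amplitude
  decaying as exp(−d/35 µm) from the path, global peak 40–120 µV (the
  workflow discards EIs under 30 µV), ±10% per-electrode gain jitter;
* artifact: per unit amplitude, a fast (τ = 5 samples) plus slow (τ = 40
  samples ≈ 2 ms tail) geometric decay starting one sample into the
  window, spatial envelopes exp(−d/40 µm) for the fast and
  exp(−d/64 µm) at 25% weight for the slow component, peak 100 µV/µA.
  Giving the two components slightly different spatial spreads (a
  physically plausible capacitive-vs-faradaic distinction) makes the truth
  exactly representable by the voltage-state artifact model; with a single
  shared decay length the trajectory is spatially rank-1 and no such model
  can reproduce a two-exponential mix. `slow_decay_scale=1.0` recovers the
  rank-1 variant;
* protocol: 39 log-spaced amplitudes 0.1–4.1 µA on the second phase,
  25 repeats, charge-balanced triphasic 2:−3:1 pulses of 50 µs/phase;
* responses: Bernoulli spiking with logistic probability in log amplitude,
  latency uniform on 8–12 samples (0.4–0.6 ms), additive i.i.d. Gaussian
  noise (default 1 µV), post-stimulus analysis window 55 samples (2.75 ms).

Not emulated: colored/spatiotemporally correlated background noise,
spontaneous spikes from undetected cells, axon-bundle activation, electrode
saturation, and amplitude discontinuities on the stimulating electrode.
Passing the synthetic suites therefore demonstrates correctness of the
machinery under the stated model assumptions, not robustness to every
artifact of real recordings.

## Validation studies and problem sizes

The studies in `dynsort.validation` (also driven by
`scripts/acceptance.py`) use: a 16×16 array with 8–10 neurons for the
noiseless-inversion, noise-sensitivity and threshold-recovery studies; a
6×6 array with 4 neurons for the oracle-agreement study (200 noisy trials
at 1 µV plus 40 noiseless); 39 amplitudes × 25 repeats for the
artifact-trend and threshold studies; 10 neuron–electrode pairs with true
thresholds log-spaced over 0.8–3.2 µA (slope 0.1 in log amplitude) for
threshold recovery, with 5-fold validation on the first 3 pairs. True
thresholds sit in the grid interior so both sub- and supra-threshold trials
exist and the low-amplitude fitting half stays mostly spike-free. The
noise-sensitivity study packs its neurons around the array center
(overlapping footprints) because the multi-neuron estimation penalty is a
cross-talk effect that requires shared electrodes, and it reports RMSE over
the full stacked input vector with paired noise fields across conditions.

## Numerical choices and degenerate inputs

Double precision throughout; exactness assertions at 1e-8 or tighter.
Ridge 0 with a rank-deficient design is always a hard error. Models with
spectral radius above 1 + tol raise a warning (transients may still be fine
over a 55-sample window; edge-of-array neurons fit worst). Cosine scores of
numerically zero estimates are 0 by convention. Trial averages use
`scipy.stats.trim_mean`; K-fold splits are seeded and stratified;
enumeration oracles pre-sort hypotheses so the first minimum implements the
tie-break.

## Known limitations

Single stimulating electrode only (no multi-channel composition); no
real-time/streaming mode; linear models only; detection thresholds are
calibrated on synthetic separation rather than human-curated labels; the
estimator's ridge values are global, not per-neuron.
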