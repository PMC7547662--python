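# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the limitations of the `decidecode` package. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Task and stimulus model

The task is a contrast discrimination against a fixed 50%-contrast
reference: ten contrast samples (100 ms each) drawn i.i.d. from
N(0.5 ± δ, σ) with σ chosen per trial from {0.05, 0.1, 0.15} and the
offset δ controlled adaptively. Draws outside [0, 1] are redrawn
per sample (rejection rather than clipping, which would bias the mean).
The *realized* mean of the ten draws defines the stimulus category
(stronger iff mean > 0.5), and correctness is judged against it.

The stimulus is a radially drifting circular grating: blending value
a(x, y) = ½ + ½ sin(π (d − s) / (2r)) with eccentricity d, drift phase s
(degrees) and spatial parameter r = 0.75° (period 4r = 3°), blended as
l = a(0.5 − c/2) + (1 − a)(0.5 + c/2) so the rendered Michelson contrast
outside the 1.5° uniform-gray annulus equals the requested c. The phase
advances at 4/3 °/s (expanding or contracting), frame rate 60 Hz,
truncation at 11.3°. Note the π is an angular-frequency factor in the
numerator: placing it in the denominator would give a spatial period of
4π²r ≈ 30°, i.e. less than half a cycle on screen, and no phase could
then realize the full contrast range between annulus and truncation
radius — incompatible with a 0.5-contrast reference grating.

## Staircase

QUEST with a Weibull psychometric in log10 contrast-offset units: grid
[−3, −0.3] (271 points), slope β = 3.5, guess rate 0.5, lapse 0.02, and
an anchoring constant that puts p(correct | x = threshold) at the 75%
target. Each trial is placed at the posterior mean (QUEST's mean rule);
the posterior is a pointwise Bayes update. A `degenerate` flag marks
posteriors whose mass piles onto a grid edge. For a matched simulated
Weibull observer, seed-averaged accuracy over trials 2001–3000 of a
3000-trial run sits within ±0.02 of 0.75 (tested).

## Observer

A linear accumulator: DV = Σᵢ wᵢ(cᵢ − 0.5) + N(0, σ_int); choice =
sign(DV) with optional lapses; confidence = |DV| ≥ criterion; RT (from
test offset) shifted-lognormal, independent of the decision. Defaults:
primacy weights wᵢ = exp(−0.15 (i − 1)) — the minimal generative account
of a declining psychophysical kernel — and σ_int = 0.15, which puts the
staircase-converged offset (δ ≈ 0.03, closed-form Gaussian accuracy)
well inside the QUEST grid. RT parameters (shift 0.4 s, log-mean 0.383,
log-sd 0.35) put 5% of mass below the 1.225-s exclusion boundary so the
filter is exercised; the boundary itself is read strictly ("faster
than"), so an RT of exactly 1.225 s survives. The movement-contamination
boundary for spectral analyses is 1.225 − 0.25/2 = 1.1 s.

## Neural generator

Raw power on a trial × ROI × hemisphere × frequency × time grid (epoch
−0.25…1.35 s, step 1/60 s; frequency grid 1–9 Hz step 1 + 10–145 Hz
step 5, or a coarse 15-bin version with the same coverage for
simulation studies):

* **Visual gamma (40–75 Hz):** modulation (γ₀ + γ₁·cᵢ·e^{−a(σ)(i−1)})
  convolved with a gamma-shaped (shape-2) impulse response of unit peak
  at the 190-ms encoding latency; adaptation rate a(σ) = σ per the
  configured map {0.05→0.05, 0.1→0.1, 0.15→0.15}, making the response
  decay depend on the trial's contrast variance. Identical in both
  hemispheres (full-field stimulus).
* **Motor/parietal low band (≤20 Hz):** lateralized build-up
  ±½·g_m·C̃(t), where C̃ is the cumulative evidence Σ_{i: onset_i+190ms≤t}
  wᵢ(cᵢ−0.5) normalized by its final-sample SD; the hemisphere
  contralateral to the hand mapped to "stronger" carries the positive
  sign (mapping counterbalanced across subjects).
* **Visual low band:** choice-signed feedback a_f · sign(choice) ·
  R(t − Δ), where R(t) = Σ_{i≤k(t)} wᵢ² / Σ wᵢ² is the *normalized
  build-up shape* (the SNR profile of the motor signal — a step ramp
  from 0.19 s) and Δ = 150 ms is the feedback delay. Sharing R between
  the motor and visual signals is what makes Δ identifiable by lagged
  cross-correlation at single-bin precision.
* Multiplicative lognormal noise exp(σ_n Z − σ_n²/2) per trial/bin
  (mean-corrected), σ_n = 0.2; the baseline interval holds baseline +
  noise only.

Gains (g_m = 0.25, a_f = 0.03, γ₁ = 1, γ₀ = 0.5, baseline 10) were
calibrated once, by signal-to-noise arithmetic against the magnitudes
such experiments report: M1 choice AUC building to ~0.65–0.7, V1
kernels ~0.55–0.63, strong gamma contrast encoding. What the generator
does *not* emulate: 1/f spectra, oscillatory phase, sensor noise
covariance, source leakage between ROIs (the leakage-reference analysis
bounds an effect the generator injects only through shared signals),
eye/muscle artifacts, or non-linear contrast response functions.
Passing tests therefore validate the *analysis machinery and its
statistical properties*, not the physiology.

## Analysis conventions

* ROC AUC via Mann–Whitney U with ties counted 0.5; orientation: > 0.5
  means larger values precede "stronger" choices.
* Kernels: two SDT cells (hit/miss, FA/CR) computed separately and
  averaged; empty cells propagate as NaN, never imputed. Residual
  kernels regress power on the same sample's contrast per position
  (OLS); residualization is idempotent.
* Choice decoding: per category, stratified 10-fold CV (seeded), z-score
  from training folds only, minority class upsampled by random
  repetition to parity (training set only), linear SVM C = 1, AUC from
  decision values on the held-out fold; folds with a missing class are
  skipped. The fine-grained scheme adds PCA to 95% cumulative variance,
  an L1 SVM (C = 10/n_features) with |w| < 1e-5 pruning, then an L2 SVM
  (C = ½), all fitted on training data.
* Contrast decoding: ridge with nested 3-fold selection of α ∈
  {0.1, 1, 10}; score = Pearson r between held-out predictions and
  targets, averaged over folds. The "accumulated contrast" target is the
  running mean of the true sample contrasts up to sample i. The summary
  across the ten per-sample curves is their pointwise upper envelope.
* Cross-correlation: M1 AUC on [0, 0.8] s against the visual kernel on
  [ℓ, 0.8 + ℓ] for ℓ ∈ −215…215 ms on the kernel's 1/60-s grid; overlap
  truncated at the kernel support (no padding), lags with < 3
  overlapping bins are missing; the peak is the argmax of the
  subject-mean correlation. The M1 decoder must run on the *same*
  1/60-s grid — decoding on a strided grid aliases the lag residue
  classes and biases the peak. The M1 kernel used as the zero-lag
  leakage reference is computed on *lateralized* M1 power (the motor
  choice signal cancels in a hemisphere average).
* Baseline normalization: condition-independent baseline per frequency
  (mean over trials × [−0.25, 0) s), output in percent change. Band
  power extraction: mean over a band's center bins at the nearest time
  bin, ties toward the earlier bin. Gamma = centers 50–65 Hz, low
  frequency = center 10 Hz.
* Multitaper TFR: sliding DPSS windows, 0.25 s / ±8 Hz below 10 Hz and
  0.1 s / ±20 Hz above, K = 2TW − 1 = 3 tapers, hop 1/60 s, edges NaN.
  Power evaluated at the exact analysis frequency (DFT vector), not the
  nearest FFT bin.
* TFCE: Σ_h extent^0.5 · h² · dh with dh = max|stat|/100, thresholds
  k·dh, positive and negative tails enhanced separately; adjacency
  2-neighborhood in 1-D, 4-neighborhood in 2-D; 1-D maps use a
  vectorized run-labeling path (verified against the explicit
  threshold loop). Permutation null: per-subject sign flips,
  max-|TFCE| statistic, p = (1 + #{null ≥ obs}) / (n_perm + 1);
  n_perm ≥ 500 enforced.
* Hierarchical AUC model: sampled with emcee's affine-invariant
  ensemble (two independent ensembles × 3000 iterations by default,
  first half discarded). Each ensemble is one chain for split-R̂
  (draw-major pooling of walkers), gate R̂ < 1.05; non-convergence
  flags the result but summaries are still returned.
* Logistic fits (choice model, α×γ interaction model) use a tiny L2
  penalty (1e-6 on z-scored predictors) so perfect separation stays
  finite; the interaction model averages band power over samples 1–5
  and 6–10 at the 190-ms latency, z-scores before forming products,
  and reports temporal asymmetries β_{n,2} − β_{n,1}.

## Randomness and determinism

One run seed expands into named substreams ("trials", "observer",
"neural", "decoding", "stats") via `SeedSequence` spawn keys; no global
RNG is used, and every stochastic operation requires an explicit
generator. Identical seed + config give byte-identical trial tables,
tensors and result files (tested).

## Problem sizes used in the test suite

Simulation studies are sized for a single-CPU run: staircase convergence
is seed-averaged over 10 × 3000 trials; the null-kernel check uses 15 ×
2000 trials; feedback-delay recovery uses 6 cohorts × 12 subjects × 800
analyzed trials (bias of the group peak lag asserted below one 1/60-s
bin), with a lighter 2-cohort × 10-subject variant across delays of
50/100/200 ms; FWER control uses 500 simulated null datasets × 500
permutations; Bayesian recovery uses 8–20 replicate cohorts at reduced
draw counts. Each simulated subject's first 100 staircase trials are
treated as calibration and excluded from neural analyses, mirroring a
separate training session.

## Known limitations

* The generator's band-level construction bypasses the multitaper path
  in the main pipeline; the TFR code is exercised on synthetic
  narrow-band time series in its own tests.
* The accumulator observer has no bound, leak or time-varying noise;
  primacy is put in through the weights, so kernel-shape results are
  recovery checks, not model comparisons.
* Choice decoding is evaluated per time bin (no temporal
  generalization), and the "cortex-wide" scheme is the per-ROI scheme
  looped over an ROI list — no cortical geometry is modeled.
* With ~300–800 trials per synthetic subject the per-cohort peak-lag
  estimate is noisy; only its bias across cohorts is constrained to one
  time bin.
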