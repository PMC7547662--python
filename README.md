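# decidecode

Analysis pipeline for perceptual-decision information in behavior and in
regionally specific MEG-like spectral power — with a synthetic generator of
the task, the observer and the neural signals, so every stage runs and is
testable without any recordings.

## The scientific problem

In a two-interval contrast discrimination, an observer watches ten 100-ms
contrast samples fluctuate around a mean titrated to 75% accuracy and
reports whether the test was stronger or weaker than a 50%-contrast
reference. Behavior and cortical population activity then carry three
distinguishable kinds of decision information:

1. **Evidence weighting.** The *psychophysical kernel* is, per sample
   position *i*, the ROC area (AUC) comparing single-trial contrasts
   c_trl,i between the two choices *within* each stimulus category (hits
   vs misses, false alarms vs correct rejects, averaged) — conditioning on
   the category factors the physical stimulus out. AUC > 0.5 at early
   positions with a negative slope across positions is primacy: early
   evidence weighs more.
2. **Stimulus and decision-variable encoding.** Band-limited power encodes
   the instantaneous sample contrast (gamma, 40–75 Hz, in visual cortex,
   with variance-dependent adaptation and a ~190 ms encoding latency),
   while parietal/motor regions carry a hemisphere-lateralized build-up
   proportional to the running evidence sum Σᵢ wᵢ(cᵢ − 0.5). Linear SVMs
   on the 1–145 Hz spectral pattern decode choice per time bin; ridge
   regression decodes sample contrast and its running mean.
3. **Endogenous choice signals.** Applying the kernel recipe to band power
   at each sample's latency ("neural-activity kernels", the population
   analogue of choice probability) and regressing out the sample contrast
   separates the stimulus-driven component (gamma: residual kernels
   collapse to 0.5) from the endogenous one (low-frequency, <20 Hz:
   residualization changes nothing). The time-resolved low-frequency
   kernel lags the build-up of choice decoding in M1 by a delay that a
   lagged cross-correlation (−215…215 ms, positive = M1 leads) recovers,
   against a same-region zero-lag "leakage reference" upper bound.

Group inference uses a hierarchical Bayesian model — subject AUCs at time
*t* as StudentT(μ_t, σ_t, γ) with μ_t ~ N(0.5, 1), σ_t ~ U(0, 5),
γ ~ Exp(mean 29) + 1 — plus threshold-free cluster enhancement (TFCE,
H = 2, E = 0.5) sign-flip permutation tests and Benjamini–Hochberg FDR.

The synthetic generator closes the loop: a QUEST staircase titrates a
noisy primacy-weighted accumulator observer to 75% correct, and the power
tensors are built so that every analysis above has a known ground truth
(adaptation rates, encoding latency, feedback delay, build-up gains).

## Worked example

```bash
python examples/visual_kernels_and_feedback.py
```

prints (6 simulated subjects × 700 analyzed trials):

```
V1 gamma kernel  (overall):  [0.55  0.55  0.56  0.533 0.527 0.507 0.509 0.512 0.507 0.49 ]
V1 gamma kernel  (residual): [0.512 0.529 0.545 0.528 0.524 0.504 0.506 0.512 0.51  0.492]
V1 low-freq kernel (overall):  [0.513 0.502 0.539 0.551 0.578 0.591 0.593 0.588 0.626 0.603]
V1 low-freq kernel (residual): [0.51  0.502 0.538 0.55  0.577 0.589 0.591 0.588 0.626 0.605]

cross-correlation peak lag: 167 ms (generator feedback delay: 150 ms; positive = M1 leads)
```

Read: gamma kernels are above chance early and collapse once contrast is
regressed out (stimulus-driven); low-frequency kernels rise late and
survive residualization (endogenous); and the cross-correlation recovers
the injected 150-ms M1 → V1 feedback delay to within one 1/60-s time bin.
The other scripts in `examples/` cover cohort simulation, psychophysical
kernels (group slope ≈ −0.02 AUC/position), M1 choice decoding (AUC
ramping ~0.5 → ~0.7), and group inference (posterior + TFCE).

A full orchestrated run (trials.tsv, results.json, manifest with config
hash) is available as a library call or thin CLI:

```bash
decidecode run --seed 1 --n-subjects 3 --n-trials 320 --out-dir results/run1
```

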