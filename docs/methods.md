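# Methods

`pupilload` analyses task-evoked pupillary responses (TEPR) in a visual
digit-span task: participants fixate for 2 s, then see 3, 5 or 8 digits at
one per second (difficulty low/medium/high) and hold them briefly in
working memory. Cognitive load dilates the pupil by a few tenths of a
millimetre on top of a several-millimetre resting diameter, so every trial
is summarised by change scores against its own prestimulus baseline.

## Features

For a trial with cleaned prestimulus diameters and stimulus-phase
diameters PS_1..PS_n (mm) at times t_1..t_n (s from stimulus onset):

- **BLPS** — mean prestimulus diameter. The per-trial reference; it should
  carry no difficulty signal because fixation precedes the task.
- **MPDC** — mean(PS) − BLPS.
- **PCPS_i / APCPS** — (PS_i − BLPS)/BLPS and its mean. By construction
  APCPS·BLPS = MPDC exactly; the identity is asserted in tests at 1e−12.
- **PPD / PD** — max(PS), and max(PS) − BLPS. PD ≥ MPDC always.
- **E_pupil** — Shannon entropy of the discretised PS distribution.
  Diameters are binned at 0.01 mm (configurable) anchored at the trial
  minimum and entropy is taken in bits. The bin width matches typical
  eye-tracker quantisation; treating the trace as a discrete variable
  without binning would make the entropy depend on float noise.
- **TTP** — t at the first sample attaining PPD. First occurrence is the
  conventional latency definition for ties.
- **PDS** — arctan of the OLS slope of PS against t over samples from
  onset through the peak (inclusive), time in seconds, diameter in mm. If
  the peak is the first stimulus sample there is no rise segment and PDS
  is defined as 0.

## Preprocessing

Per trial: samples flagged invalid by the tracker, or with neither eye
measured, are removed (blinks are taken from the device validity flag; no
blink detector is re-implemented). Binocular records are averaged; one-eyed
records pass through unchanged. A trial is rejected when more than 20% of
its records were invalid (inclusive bound: exactly 20% passes). The
stimulus-phase series is then smoothed with a Savitzky–Golay filter,
window 7 samples, polynomial order 2 (configurable) — mild smoothing that
preserves peak structure; series shorter than the window pass through
unsmoothed with a logged warning. The baseline is computed from the raw
(cleaned, unsmoothed) prestimulus samples: smoothing exists to stabilise
the peak-dependent features (PD, TTP, PDS), which the baseline mean does
not need. Trials whose cleaned prestimulus phase is empty cannot define a
baseline; in batch runs they are reported as rejections alongside the
20%-rule failures, so accepted and rejected trials always partition the
input.

## Synthetic study generator

The generator emulates the study design so the whole pipeline runs and is
testable without recordings. Defaults (all configurable):

- 24 subjects × 12 trials per level, 50 Hz sampling, 2 s prestimulus,
  one digit/s, 4 s retention tail (at ~1 Hz this yields 7/9/12 stimulus
  measurements for 3/5/8 digits, matching the coarse per-trial counts such
  tasks produce).
- Subject baseline ~ Normal(4.0, 0.5²) mm truncated positive — resting
  pupil diameters cluster around 3–5 mm; baseline parameters are identical
  across levels, so baseline features are null by construction.
- Dilation amplitude: mean trajectory ramps linearly from baseline during
  encoding, peaks at the end of digit presentation, then decays
  exponentially (τ = 2 s). Peak amplitude = sensitivity ×
  {low 0.12, medium 0.24, high 0.44} mm; subject sensitivity is lognormal
  with unit median and log-sd 0.3, giving each subject a proportional
  load response (the "random slope" the mixed model targets).
- Measurement noise 0.1 mm per sample on the common trajectory (typical
  video-oculography noise), independent 0.02 mm per-eye jitter, 2% chance
  per sample that one eye is untracked, and blink runs: with probability
  0.002 per sample a run of 2–10 consecutive invalid samples starts
  (~1–2% invalid records per trial, occasionally breaching the 20% rule).

Not emulated: luminance reflexes, gaze-angle foreshortening, habituation
across trials, serially correlated noise. Passing tests therefore show the
pipeline recovers the structure this model encodes — ordered dilation,
null baselines, subject heterogeneity, blink artifacts — not that it would
behave identically on any particular real dataset.

A corollary worth stating: difficulty sets trial *duration* as well as
amplitude, so duration-sensitive features (TTP especially) separate levels
strongly; classification scores on synthetic data are upper-end for the
same reason. A "null" configuration must equalise digit counts in addition
to amplitudes, otherwise duration still encodes the label — the type-I
simulations do exactly that (equal amplitudes, all levels 5 digits).

## Mixed-model analysis

Each feature is modelled with difficulty (3 levels) as a fixed effect and
per-subject random effects: a random intercept plus per-level difficulty
effects where identifiable. Estimation is REML. With only three levels the
random-slope covariance is frequently singular; the fit then silently
simplifies to intercept-only (logged). Singularity is judged on the
standardised scale: any random-effect variance below 0.5% of the response
variance marks a boundary fit. The threshold matters — retaining a
spurious slope covariance makes the ML likelihood-ratio test
anticonservative for null effects (measured on the generator's baseline
feature), while genuine subject-level load responses sit well above it. The difficulty effect is tested by
a likelihood-ratio test on ML refits of both models — REML log-likelihoods
are not comparable across fixed-effect structures — with chi-square df 2.

Numerical choices: all fits run on the variance-standardised response
(estimates and standard errors are rescaled back). Raw feature variances
span ~1e−3 (MPDC, mm²) to ~1e1 (TTP, s²), and at the small end the
optimiser can terminate at a degenerate point with an unbounded
log-likelihood, which standardisation prevents; the LRT statistic is
invariant to this affine rescaling. Optimisers are tried in the order
lbfgs → bfgs → powell → nm because a boundary optimum (zero variance
component) can leave the gradient-based fits with a singular Hessian.

Pairwise contrasts (medium−low, high−low, high−medium) come from the fixed
effects with standard errors from their covariance; the familywise
adjustment is single-step max-|z| under the joint normal distribution of
the three contrast statistics (the mixed-model analogue of Tukey's HSD;
studentised-range theory does not apply to LMMs). The three contrasts are
linearly dependent, so the joint correlation matrix is rank-2 — handled
exactly, with a Holm step-down fallback only if the joint distribution
degenerates further. Influence screening flags observations with
|standardised conditional residual| > 3 (≈0.3% of clean data under
normality) and refits; both pre- and post-screen contrasts are reported.
An optional log1p-after-shift response transform exists for
heteroscedastic features but is off by default.

## Classification

All 2⁷ − 1 = 127 non-empty feature subsets × 7 classifier families (SVM
with linear/RBF/sigmoid kernels, squared-hinge LinearSVC, LDA, decision
tree, 100-tree random forest) = 889 configurations, each under stratified
5-fold cross-validation with a fixed fold partition shared across the
search. Margin-based families see features standardised with
training-fold statistics; trees see raw features. The RBF kernel scale is
the median heuristic (1/median squared pairwise distance) computed on the
standardised training fold. Metrics derive from the confusion matrix
pooled over test folds: per-class precision/recall, unweighted macro
averages, and the headline F1 as the harmonic mean of macro precision and
macro recall; a per-class macro F1 and a fold-averaged F1 are emitted
alongside. Ranking ties prefer smaller subsets, then enumeration order,
making the ranking deterministic under a fixed seed.

Default CV is stratified by difficulty without subject grouping, mirroring
the plain k-fold scheme such studies typically report; because a subject's
trials then straddle train and test folds, subject identity leaks into the
scores. A `group_by_subject` mode (StratifiedGroupKFold) provides the
leakage-safe estimate, and the fourth analysis script reports both.

## Problem sizes and determinism

The default study is 24 subjects × 36 trials (~490k samples); a full
pipeline run — simulate, preprocess, extract, 7 mixed-model analyses,
889-configuration search — takes a few minutes on one core. Simulation
studies use scaled sizes chosen for stable Monte-Carlo estimates: 20
replicates of the default study for the significance-pattern check and
500 replicates of a 12-subject null study for type-I calibration. Every
random draw flows from an explicit seed; the same seed reproduces every
output file byte for byte.

## Known limitations

- The generator's trajectory (linear ramp, exponential decay) is a
  convenience shape; real TEPR morphology varies with task and subject.
- LRT p-values rely on chi-square asymptotics; with very few subjects they
  can drift from nominal (the calibration test pins the default regime).
- "Tukey HSD" on an LMM is necessarily an analogue, not the exact
  studentised-range procedure.
- Pooled-CV metrics are optimistic under subject leakage; use the grouped
  mode for subject-generalisation claims.
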