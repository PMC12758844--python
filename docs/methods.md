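# Methods

This note documents the models, parameters and numerical choices behind
`fovflow`: what the synthetic generators emulate, how each analysis
stage is defined, and where open design decisions were settled.

## Synthetic laminar fMRI data

One table per ROI per subject (foveal V1, peripheral V1, LOC, pIPS by
default; 500/500/400/400 voxels). The block design mirrors the study
layout: 12 runs × 2 tasks (peripheral object discrimination, foveal
fixation) × 2 categories × 2 orientations, one block per cell per run,
one beta sample per block.

* **Layer structure.** Each voxel's volume-fraction vector over
  (WM, CSF, deep, middle, superficial) is Dirichlet-distributed with one
  dominant compartment (α = 12 vs 0.5; dominant fraction ≈ 0.86),
  mimicking voxels sampled across a laminar ribbon without equi-volume
  geometry. Compartment probabilities are 8% WM, 8% CSF, 28% per
  cortical layer, so a realistic minority of voxels is excluded as
  WM/CSF-dominant.
* **Information.** For every (task, ROI, layer, feature) cell of the
  information profile with amplitude a, condition effects are added
  along a fixed unit pattern vector over voxels, weighted per voxel by
  a × (fraction of that layer); class 1 (cubie / vertical) adds
  +pattern, class 0 subtracts it. The default profile plants the
  qualitative laminar map of the study conditions (foveal-V1 category
  in deep+superficial, orientation deep-only; peripheral-V1 orientation
  in middle+superficial with no category; LOC/pIPS category in
  middle+superficial; the foveal task instead carries orientation in all
  foveal-V1 layers and no category there) with a = 3 × noise_sd.
* **Vasculature.** A fraction (default 10%) of voxels is vein-flagged:
  beta mean shifted by +3, beta noise doubled, mean-EPI intensity
  shifted by −250 against a base of 1000 ± 30 plus a linear spatial
  trend (50 intensity units per mm along a random direction).

Not emulated: hemodynamics, spatial autocorrelation, motion, subject
anatomy differences (patterns are shared across subjects). Passing tests
therefore certify the analysis logic, not robustness to those real-data
properties.

## Synthetic MEG data

Trial × source × time arrays at 100 Hz over (−0.3, 0.8) s, three regions
(early visual, occipitotemporal, posterior parietal; 60 sources each by
default), 104 trials per condition per location set.

* **Components.** Each region/feature contributes
  amplitude × class-sign × pattern × envelope(t − onset) × gain(trial, t)
  on top of unit Gaussian noise. The envelope is a raised cosine (50 ms
  rise, 300 ms plateau, 100 ms fall). Feedforward onsets default to
  70 ms (early visual), 110 ms (parietal), 130 ms (occipitotemporal);
  feedback onsets to 220 ms (category) and 250 ms (orientation).
* **Location structure.** Feedforward patterns in the retinotopic
  regions (early visual, parietal) are mutually orthogonal unit vectors
  per location set; occipitotemporal patterns are location-invariant.
  The early-visual feedback pattern is identical for both location sets
  and orthogonalized against that region's feedforward patterns, so
  cross-location transfer in early visual cortex carries feedback
  information only.
* **Gain coupling.** Per-trial, per-time gains are exponentials of
  Gaussian noise smoothed to 10 ms and rescaled to log-SD 0.8. The
  early-visual feedback gain is the occipitotemporal gain series delayed
  by fb_lag = 30 ms (3 samples) — the directed dependency that
  conditional Granger causality must recover; the exact lagged copy
  keeps the coupling detectable at the autoregressive model order
  regardless of the gain's own autocorrelation. The smoothing is kept
  near-white deliberately: a strongly autocorrelated gain shared between
  the two series makes their own-lag-predictable content interact with
  response-envelope edges inside the sliding regression window,
  producing spurious direction-free Granger influence (see the
  normalization note below). The study data do not constrain
  single-trial gain statistics; this coupling model is an explicit
  assumption, and its scale (log-SD 0.8, feedback amplitudes 1.0/0.8)
  was fixed at design time so the planted lag is detectable through a
  trailing 150 ms regression window at the stated onset tolerance.
* **Behavior.** RT = 0.55 − 0.15 × (mean feedback drive in the 200 ms
  after the feedback onset) + N(0, 0.05), floored at 0.2 s; correctness
  is Bernoulli with logistic probability 1/(1+e^-(1.2+z)) of the
  standardized strength (≈ 77% mean accuracy).

## Analysis stages

* **EPI detrending** — OLS residuals of intensity on (1, x, y, z);
  mean-centering fallback (logged) on a rank-deficient design.
* **Two-Gaussian mixture** — 1-D EM, median-split initialization,
  tolerance 1e-6 on mean log-likelihood, ≤ 500 iterations, components in
  ascending mean order. Separation = |μ₂−μ₁| / pooled SD. Exclusion uses
  hard maximum-responsibility assignment; each criterion (high-beta
  component, low-EPI component) only applies when its separation ≥ 2 —
  a two-component fit on unimodal data splits arbitrarily, and at small
  voxel counts (≲ 200) even the gate becomes unreliable, which is why
  default ROIs are several hundred voxels.
* **Layer assignment** — argmax over deep/middle/superficial unless WM
  or CSF dominates overall (→ excluded); ties break deep > middle >
  superficial.
* **fMRI decoding** — per fold: hold out one run, average same-condition
  blocks per run within training runs, apply the vasculature mask
  (computed once from condition-agnostic per-voxel means — no label
  leakage) and optional layer restriction, rank voxels by |two-sample t|
  on training samples (top 500 per ROI, top 300 per layer, all if
  fewer), mean-center with training statistics, train a linear SVC
  (C = 1, libsvm), score the held-out run's condition averages. Ties at
  the boundary count as errors. Whether ranking should use signed t or
  |t| is not determined by the study description; |t| is used.
* **MEG decoding** — per repeat (default 20): fresh pseudo-trial
  partition (8 near-equal splits per condition); per time point: one-way
  ANOVA F feature ranking on training samples (ties by feature index;
  zero within-group variance ⇒ F = ∞, ranked first, logged), top 100
  features, linear SVC on pseudo-trial averages. Same-location:
  leave-one-split-out over both location sets pooled. Cross-location:
  train on all pseudo-trials of one location set, test on the other's,
  both directions averaged. Re-drawing the partition on every repeat is
  a deliberate reading of "repeated 20 times".
* **Smoothing** — Gaussian kernel with half-width-at-half-maximum as the
  stated width (σ = hw/√(2 ln 2)), reflected boundaries; 100 ms for
  decoding and behavior curves, 50 ms for GC curves (display only, never
  before inference).
* **Latency** — normalize to (acc−chance)/(peak−chance) with the peak
  over t > 0; latency is the first t ≥ 0 crossing 75% of peak, linearly
  interpolated. Group latency is computed on the group-mean smoothed
  curve (per-subject latencies are available too but noisier).
* **Strength** — every raw trial scored per time point by the
  scheme-matched classifier: distance = true-sign × (w·x+b)/‖w‖;
  cross-location trials are scored by the opposite-set hyperplane. Raw
  trials (not pseudo-trials) are scored because the behavior analysis
  needs trial resolution. Before GC, the distances are normalized per
  time point: the per-condition-cell mean (category x orientation x
  location set — the evoked component, including static condition- or
  scoring-set-coded offsets that classifier cross-talk leaves in the
  distances) is subtracted, then the series is scaled to unit variance
  across trials. Removing the ensemble mean before autoregressive
  modelling is standard practice for event-related data: static
  trial-coded mean content violates the local-stationarity assumption
  of the sliding-window VAR, and globally fitted lag coefficients then
  misfit it at response edges, injecting predictable content into the
  residuals and creating spurious, direction-free Granger influence
  (verified in simulation; the time-reversed control detects exactly
  this failure mode).
* **Conditional GC** — for each evaluation time, regression rows are
  pooled over trials and the 15 window samples in (t−0.15, t]; the full
  model regresses the target on 5 lags of target, source and the
  conditioning region plus intercept (OLS; ridge 1e-8 fallback with a
  logged warning on singular designs); gc = ln(RSS_reduced/RSS_full) ≥ 0
  by nesting. Lags may reach before the window start (the epoch provides
  the history). Evaluation times ending at or before 0 form the
  per-subject baseline, summarized as a scalar mean — the stable
  statistic given the few pre-stimulus evaluation points. Group onset =
  start of the earliest significant cluster of gc − baseline (one-tailed
  sign-flip cluster test). Note the trailing window makes a detected
  onset a conservative (late-biased) estimate of the true coupling
  onset: at the true onset only a minority of window samples carry the
  coupling.
* **Behavior correlation** — per object condition (location sets
  pooled): correct trials only; RT outliers beyond mean ± 2 SD of that
  condition's correct trials excluded (per condition within subject,
  since conditions can differ in difficulty); per time point,
  misclassified trials (negative distance) with |distance| > 2 SD also
  excluded — the exclusion is read as applying to misclassified trials
  only. Reported r = −corr(distance, RT) so positive means better
  representation, faster response; the four condition coefficients are
  averaged, then smoothed (100 ms). Time points with < 5 usable trials
  are set to missing and smoothed with a renormalized kernel.
* **Inference** — one-sample t (one- or two-tailed); BH step-up with an
  explicit family size m ≥ number of tests (the laminar map is corrected
  as one 24-test family per task); sign-flip cluster permutation with
  cluster mass = summed t (scale-free across regions; "effects summed"
  is read as summed statistics), max-cluster-mass null, and the +1
  permutation correction so p ≥ 1/(n_perm+1). Defaults follow the study
  conventions: cluster-forming and corrected thresholds 0.01 for
  decoding and GC, 0.05 for behavior; 50,000 flips by default,
  reduced (≥ 2000) in tests for desk-scale runtime.

## Problem sizes

Structural constants always match the study design (12 runs, 8 blocks
per run, 100 Hz, 104 trials/condition, 8 splits, 20 repeats, top
500/300/100 selection). Tests and the acceptance script scale the free
sizes down as this package's own desk-scale choices: 12–18 sources per
region, 16–48 trials per condition, 1–5 decoding repeats, 150–500
voxels per ROI, n_perm = 2000. The laminar group analysis keeps the full
n = 18 subjects and default ROI sizes; the GC and behavior analyses use
15 subjects, matching the study's MEG cohort.

## Known limitations

* The gain-coupling and RT models are assumptions; only their recovery,
  not their realism, is tested.
* Sign-flip permutation assumes symmetric null distributions; gc −
  baseline is only asymptotically symmetric under the null.
* The mixture separation gate can fire on unimodal samples of a few
  hundred voxels (≈ 4% of seeds at n = 450); the method inherits this
  from its bimodality assumption.
* Group latencies use the group-mean curve; subject-level latency
  distributions are not modeled.
* No sensor-space modeling, source reconstruction, hemodynamic
  convolution, or stimulus rendering — those upstream steps produce this
  pipeline's inputs and are out of scope.
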