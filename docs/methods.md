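# Methods

## The analysis model

The pipeline treats recurrence risk assessment of atypical meningioma as a
two-stage problem: (i) quantify each segmented tumor with a compact set of
imaging descriptors, and (ii) screen those descriptors — together with
human-read binary semantic annotations — for association with relapse and
progression-free survival (PFS).

The statistical chain is deliberately the one a clinical imaging study
would run in standard software: univariate logistic regression per binary
predictor (odds ratio, Wald 95% CI), ROC analysis per continuous feature
with a Youden-index cutoff, a multivariate Cox proportional-hazards model
on the features that pass screening, and Kaplan–Meier / log-rank analysis
of the leading semantic feature. No multiple-testing correction is applied
by default; the procedure is a *screening* chain, and its false-positive
behavior is characterized by simulation instead (see Calibration below).

## Image processing

**Resampling.** Texture offsets are defined on the voxel lattice, so all
13 spatial directions must have equal physical length. Volumes are
resampled to isotropic spacing (default 1 mm; image linear, mask
nearest-neighbor) before feature extraction.

**Discretization.** Masked intensities are quantized to a fixed count of
`Ng = 32` gray levels with equal-width bins between the masked minimum and
maximum: `level(x) = min(Ng, ⌊(x−min)/(max−min)·Ng⌋ + 1)`. A constant ROI
maps to level 1. Fixed bin *count* makes texture features unit-free and
comparable across filter channels, at a price documented prominently: any
absolute feature threshold is tied to this choice and must be re-derived
per dataset rather than transferred. Levels are 1-based throughout so the
`1/i²` emphasis weights are always defined.

**Filter channels.** The Laplacian of Gaussian (default σ = 3 mm,
configurable list) uses mirror boundaries and a generous kernel truncation
(8σ): a short kernel has a nonzero DC gain that leaks the local mean into
what should be a pure second-derivative response. The wavelet channel set
is a single-level 3D Coiflet-1 transform with periodized boundaries (which
keeps the orthonormal Parseval identity exact); the eight subbands
(LLL…HHH) are linearly interpolated back to the input shape so the
unmodified mask applies to each.

**Texture matrices.** GLCM: distance 1, the 13 unique directions of the
26-neighborhood, both orderings accumulated (symmetric), pairs crossing
the mask boundary excluded, matrices *summed* over directions and then
normalized — summing reduces variance on small ROIs and makes the
direction set closed under axis-aligned rotations, so aggregated features
are rotation-robust. GLRLM: runs of equal level per direction, summed over
the 13 directions by default (per-direction matrices available). GLSZM:
26-connected components of equal level; direction-free. Each matrix
implementation is verified against an independent brute-force enumeration
(explicit pair loops, line scanning with `groupby`, BFS flood fill) on
hundreds of random small ROIs.

**Shape.** Spherical disproportion is the ratio of the mask's surface area
to that of the equal-volume sphere. The area comes from a marching-cubes
mesh of the mask after zero-padding and a light Gaussian smoothing
(σ = 0.5 voxel). Meshing the raw binary mask facets along voxel walls and
overestimates a sphere's area by ~9%, while heavier smoothing erodes
corners and biases a cube's area low; σ = 0.5 keeps a radius-20 digital
sphere within [1.00, 1.05] and a 30-voxel cube within 3% of its closed
form 6/(4π)·(4π/3)^{2/3} ≈ 1.2407.

**Small ROIs.** Texture statistics on fewer than 27 voxels are unstable; a
warning is emitted and features are still computed. A single-voxel ROI has
no co-occurring pairs and is an error.

## Statistics

- **Logistic screening.** ML fit with intercept; OR = exp(β̂), Wald 95% CI.
  For a binary predictor with a zero cell the ML estimate diverges; the
  result is reported as a degenerate 0 or ∞ with a separation flag rather
  than a misleading finite number, and degenerate features do not advance
  to the multivariate stage.
- **ROC / Youden.** AUC is the tie-corrected Mann–Whitney probability; its
  p-value is the two-sided Mann–Whitney test. The positive call is
  `feature > t`; candidate cutoffs are the observed values and ties in
  J = sensitivity + specificity − 1 break toward the lower threshold, so
  reports are deterministic. J and the AUC are invariant under strictly
  monotone transforms of the feature.
- **Cox models.** lifelines (Efron ties) behind the module surface, with
  two numerical adjustments: the stopping tolerance is tightened
  (`precision 1e-12`) because the stock rules leave ~1e-6 error against
  the true partial-likelihood maximum, and convergence failures are
  retried with damped Newton steps (step size 0.5, then 0.1) — at hazard
  ratios of ~20 an undamped Newton step can overshoot into overflow even
  though the maximizer is finite and interior. If all attempts fail, an
  error with the fitter's diagnostics is raised.
- **Kaplan–Meier.** Product-limit estimate per group. The reported "mean"
  PFS is the restricted mean survival time with the horizon at the largest
  observed time in the cohort — the convention of common clinical software
  when the largest observation is censored; an unrestricted mean is
  undefined there.
- **Screening rules.** Semantic features advance at univariate p < 0.05;
  radiomic features at Mann–Whitney p ≤ 0.10 (a deliberately permissive
  "trend" rule for a screening step, configurable). The PFS stage fits a
  univariate Cox model per clinical covariate (completeness of resection,
  location, sex, age > 65, postoperative radiation) plus the advanced
  features, then a multivariate Cox on the significant ones with
  completeness of resection always retained. The univariate PFS
  associations are hazard ratios (PFS is a time-to-event outcome), not
  odds ratios; the multivariate recurrence model is likewise Cox on
  time-to-recurrence, with multivariate logistic available as a config
  alternative.

## Synthetic data

**Phantoms** are ellipsoids (default semi-axes 14/12/10 mm on a 48³ 1 mm
grid) of base intensity 100 plus two noise terms: a correlated Gaussian
field (white noise convolved with a Gaussian of width
`texture_correlation_mm`, rescaled to `texture_sd = 20`; the field needs
an explicit amplitude parameter, and is off when the correlation length
is 0)
and independent voxel noise (`noise_sd = 5`). A cystic phantom replaces
the mean inside a central sphere (radius 0.5× the smallest semi-axis) with
0.3× the base intensity. A *smoother* field (correlation 3 mm vs 0.5 mm)
concentrates co-occurrence mass at jointly-high/jointly-low level pairs
and raises cluster prominence — measured medians ≈ 2.7×10⁴ vs ≈ 5.5×10³
at Ng = 32, with disjoint ranges over seeds — so the high-cluster-
prominence phenotype maps to the longer correlation length.

**Cohorts** draw a cystic flag (prevalence 9/55) and a high-cluster-
prominence flag (prevalence 0.25, independent — no correlation between
the two is modeled) per patient; event times are exponential with hazard
`0.0008 × 20.21^cystic × 5.89^highCP` per month and censoring is uniform
over 3–168 months. The baseline hazard was calibrated once, analytically,
to give ≈22% observed relapse — the reference cohort's rate — and then
frozen. Ten further semantic flags are drawn independent of outcome at
fixed prevalences, as screening decoys. Demographics (age ~ N(58.7, 13.8²)
clipped to 12–81, 59.2% women, localization and Simpson-grade frequencies)
follow the reference cohort's table; Simpson-grade probabilities are
renormalized to sum to 1 (the printed percentages total 98.8%).

A continuous cluster-prominence surrogate is attached per patient:
log-normal with phenotype means log 50 000 / log 110 000 and σ = 0.35,
mirroring the near-disjoint separation the phantom texture classes
produce. A consequence worth stating: because relapse is driven by the
*binary* phenotype plus the cystic component and baseline hazard, the
feature's population AUC against relapse is capped near 0.65 under this
model no matter how informative the feature is about the phenotype; the
simulated value (~0.62) is an honest property of the model, and published
single-feature AUC estimates of this magnitude carry sampling errors of
the same order at n ≈ 50.

**What the generator does not emulate:** MRI physics (bias fields, partial
volume, scanner effects), multi-sequence imaging, inter-rater variability
of the semantic reads, correlated semantic features, or non-proportional
hazards. Passing tests therefore demonstrate the correctness and
calibration of the *analysis machinery* under the stated model, not
clinical performance on real data.

## Calibration and recovery (what the suite verifies)

- Under null simulations (all HR = 1) log-rank and Cox Wald p-values over
  200 replicate cohorts are uniform (KS test at α = 0.01) and the 95% CI
  covers 1 in 90–99% of replicates.
- At the default effect sizes (HR 20.21 / 5.89, n = 500, 200 replicates)
  the mean Cox log-HR is within 0.15 of the truth for both covariates, and
  the screening chain advances the cystic component with a CI excluding 1
  in ≥ 90% of 200-patient replicates.
- Problem sizes in the test suite and acceptance script (ROIs ≤ 5³ for
  exact enumeration; 100–200 replicates; 500-patient cohorts; 20-phantom
  imaging runs at 40³) were chosen as the smallest at which these
  statistical statements are stable.

## Known limitations

- Wavelet subbands are interpolated back to input shape for masking; the
  per-subband features are therefore smoothed versions of the decimated
  coefficients, not IBSI-standard undecimated-transform features.
- The GLRLM/GLSZM feature set is the 13-feature panel only, not a full
  radiomics bank.
- Cox fits on near-separated data (very large effects in small cohorts)
  can still legitimately fail to converge; such failures surface as errors
  with diagnostics, and in screening reports they are collected per
  analysis rather than aborting the run.
- DICOM import, bias-field correction, registration and automatic
  segmentation are out of scope; inputs are NIfTI image/mask pairs.
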