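# Methods

This note documents the models, the synthetic data the package tests
itself against, the numerical conventions, and the design decisions
that were genuinely open. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Data model

All analyses operate on a `MaskedImageStack`: an observations ×
in-mask-voxels matrix tied to a 3-D grid (boolean mask + RAS+ affine)
with per-observation metadata (subject, condition, trial, 1–5 rating).
Voxel indices are 0-based internally; world coordinates go through the
NIfTI affine; masks are stored as uint8 NIfTI; tables are TSV with
BIDS-flavoured column names (onset, duration, trial_type).

## Synthetic cohort

The generator emulates the structure of a social-pain-empathy MVPA
study: a cohort of subjects, each with four control-subtracted
condition contrasts (exclusion, inclusion, separation, company) and
60 + 60 single-trial images for the two "pain" tasks with 1–5 ratings.

* **Patterns.** Each condition pattern is
  `rho·g + sqrt(1−rho²)·u_c` with `g` and the condition-specific `u_c`
  orthonormal Gaussian draws, so every pattern has unit L2 norm and
  any two condition patterns have cosine exactly `rho²`
  (default `rho = 0.5`). A mediator pattern with configured cosine
  overlap (default 0.5) to the exclusion pattern supports mediation
  tests.
* **Amplitudes and noise.** Pain conditions (exclusion, separation)
  express their pattern with subject amplitude ~ N(1, 0.25²) clipped
  at zero; inclusion/company images are noise only. Voxel noise is
  i.i.d. Gaussian, default SD 0.2 in beta units. At that default the
  paired pattern-response effect sizes fall in the range reported for
  well-powered signature studies (Cohen's d of several units), which
  is what the published near-ceiling forced-choice accuracies imply.
* **Grid.** Default 16³ with an ellipsoidal mask (~1400 voxels):
  large enough for FDR behaviour to be meaningful, small enough for
  seconds-scale tests. Semi-axes scale with the grid, so smaller test
  grids keep the same geometry.
* **Ratings.** A latent Gaussian link
  `latent = intercept + slope·expression + noise`, rounded and clipped
  to 1–5. With the default low intercept this reproduces the heavy
  rating-1 skew of naturalistic trial-count tables; centring the
  intercept populates all five levels (used by the rating-stratified
  analyses).
* **Trial coupling modes.** `coupling="amplitude"`: the condition
  pattern's expression scales with the per-trial amplitude and the
  rating tracks that amplitude — the exclusion-vs-separation
  difference signal grows with rated intensity. `coupling="pattern"`:
  the condition-specific component has constant expression while the
  rating tracks a shared-intensity component — the difference is
  rating-independent. These two modes operationalize "intensity
  coding" vs "context coding" for the rating-stratified analysis. A
  naive alternative (one shared pattern whose amplitude alone differs
  between conditions) cannot produce a rating gradient: with Gaussian
  amplitudes the conditional between-condition difference at a matched
  rating is level-independent, so the scaled-difference construction
  is the one that reproduces the rising-accuracy phenomenon.
* **Seeding.** One global integer seed fans out through named
  `SeedSequence` substreams (patterns / contrasts / trials /
  time series, then per subject), so subject subsets and repeated
  calls are reproducible.
* **Inter-subject pattern variability** is exposed as
  `subject_pattern_jitter` and defaults to 0 (no empirical value to
  anchor it).

What the generator does **not** emulate: spatial autocorrelation and
smoothness, physiological noise, anatomical structure, hemodynamic
nonlinearity, inter-regional covariance. Passing tests therefore
demonstrate correctness and calibration of the *procedures* under
clean assumptions, not expected performance on real fMRI data.

## First-level GLM

Boxcar regressors are convolved with the canonical double-gamma HRF
(shape-6 response gamma, peak ≈ 5 s, minus a shape-16 undershoot scaled
by 1/6) on a 16× oversampled grid and sampled at scan times. Nuisance
regressors are the 6 motion parameters, their squares, first
differences, and squared differences (24 columns, per run). A
discrete-cosine basis with a 128 s cutoff (order ⌊2·T/128⌋ per run)
plus per-run intercepts implements the high-pass; drifts lying in the
DCT span are removed exactly, and out-of-phase slow drifts are
attenuated to a small residual (quantified in the tests). Estimation is
OLS without prewhitening — a deliberate simplification: AR noise
modelling changes efficiency, not any downstream contract. Runs are
concatenated with run-specific nuisance/high-pass/intercept blocks;
task conditions share columns across runs. The single-trial model puts
all trial regressors in one simultaneous design (deterministic and
fast, rather than iterative one-vs-rest estimation). Parametric rating
modulators are mean-centred but **not** orthogonalized against the
condition boxcar — users who need SPM-style serial orthogonalization
should be aware of the difference.

## Signatures and evaluation

Training is a soft-margin linear SVM on raw (unstandardized) contrast
values with C = 1; any convergent solver for that hinge-loss objective
is conformant (scikit-learn's libsvm backend here). No feature scaling
is applied — scaling would change the solution the published protocol
specifies. Forced choice credits exact ties 0.5 and excludes them from
the two-sided exact binomial test (unbiased under the null; the exact
test replaces the normal approximation, an immaterial difference at
n ≈ 65). AUC pools the two conditions' responses; Cohen's d is
mean/SD of the paired response differences. Cross-validation partitions
subjects, not images, so a subject's images never straddle the
train/test boundary; whether the published protocol refolded images or
subjects is ambiguous, and subject folding is the conservative
reading. The intercept cancels within subject and is off by default
(`use_intercept` exposes it).

## Core systems

Bootstrap (Step 1): subjects are resampled with replacement — images
within a subject travel together because they are dependent — the SVM
is retrained per sample, and each voxel gets z = mean/SD of its weight
distribution with a normal-theory two-tailed p (as the source protocol
computes, rather than percentile p), then Benjamini–Hochberg FDR at
q = 0.05. Degenerate voxels (zero bootstrap SD) get z = 0, p = 1.
A calibration caveat the package's own acceptance checks quantify: for
non-smooth SVM weights in the overparameterized regime (voxels ≫
images) the subject bootstrap underestimates sampling variability, so
null-voxel z values are over-dispersed relative to N(0, 1) (SD ≈ 1.3
at 40 subjects and ~1400 voxels; the distribution is conservative in
the opposite, n > V, regime). Realized false-discovery fractions on
signal-free data nonetheless stay well below q in the package's null
simulations — the FDR gate, not the z scale, is what downstream steps
consume.

Haufe transform (Step 2): per subject, the structure coefficient of
voxel v is cov(x_v, w·x) across that subject's observations (the
forward model A ∝ Σₓw), followed by a group one-sample t-test with
BH-FDR. Pooling within subject and testing across subjects matches the
single-sample t-test protocol; a single group-level Σₓw map is
available behind `per_subject=False`. Which observations enter the
covariance is configurable: condition images (the library default, for
parity with the 4-images-per-subject protocol) or single-trial images
(the reference pipeline's default — 4 observations per subject cannot
support a stable covariance estimate at desk-scale noise, while 120
trials can).

Conjunction (Step 3): the core map is the intersection of the two
significance masks, with weights zeroed outside it. It exists for
interpretation and display only; classification always uses the full
weight vector.

## Atlas similarity

Maps are rectified to absolute values before comparison (positive
values for interpretability). For region r with m voxels the cosine is
`Σ|x|_r / (‖x_r‖·√m)` — the cosine between the map restricted to r and
r's all-ones indicator; since both vectors vanish outside r, restricting
to the region or computing over the whole grid is the same number. A
region where the map is identically zero scores 0; an empty region is
reported missing, not 0. Ribbons divide by the global maximum cosine
across regions and maps. "Relative contribution" is operationalized as
the voxelwise argmax share (the percent of region voxels on which each
map has the largest rectified value, ties split equally, shares summing
to 100 % per region), following the percentage-of-winning-voxels
definition; regions where all maps are zero are reported missing.

## Rating-stratified decoding

Per subject and rating level, same-rating trial images are averaged per
condition and the averaged pair enters the forced choice; subjects
lacking the level in either condition are excluded at that level, and
levels with fewer than 2 usable subjects are flagged rather than
silently dropped. Averaging per-level trials stands in for per-level
parametric-modulator betas — an approximation, stated as such. The
packaged study conditions for this analysis (30 subjects, 40 + 40
trials, voxel noise 0.3, centred rating link) were chosen so that every
level is populated and the constant-difference control saturates; at
that operating point the intensity-coupled generator produces a rising
accuracy-by-level profile and the constant-difference generator a flat
one, which is the logic the analysis exists to test.

## Mediation

Paths are estimated per subject by OLS — a from m ~ x; b and c′ from
y ~ x + m; c from y ~ x — so c = c′ + a·b holds exactly within every
subject. Group inference is a summary-statistics multilevel approach:
bootstrap resampling of subjects, mean of per-subject coefficients per
sample, percentile CIs (not BCa) and two-tailed bootstrap p with a
+1/(B+1) small-sample correction; full mixed-effects likelihood was
deliberately avoided to keep the contract simple and desk-testable.
The mediation verdict requires a, b, and a×b all significant; c′
decides partial vs complete. x and m are z-scored within subject by
default for conditioning (ratings stay raw 1–5); `standardize=False`
keeps raw units, in which the chain-recovery checks run. Subjects with
zero-variance x or m are dropped with a warning; more than 30 % dropped
is an error; exactly collinear x and m (e.g. the same signature twice)
raise rather than return an unidentifiable c′.

## Summary statistics

Pooled (equal-variance) two-sample t is the default for
summary-statistic comparisons, and Cohen's d for two condition means
uses average-variance pooling √((s₁²+s₂²)/2) — these are the
conventions under which the published behavioural values are
reproduced to print precision (the paired d_z form is computed by
`paired_t` separately). One published p-value (p = 0.16 alongside
t = 1.78, df = 36) is inconsistent with its own t statistic (the
correct two-tailed p is 0.083); the package reports the correctly
computed p.

## Problem sizes

Desk-scale defaults (chosen once, as the package's reference operating
points): 10–30 subjects on 10³–16³ grids for decoding tests; 200
bootstrap samples for desk runs (scalable to the 10 000-sample
reference protocol by configuration); 20–50 CV repetitions (reference:
1000); mediation with 2000 bootstrap draws (reference: 10 000). The
reference pipeline (`sps run`: 16³ grid, 20 subjects, 200 bootstraps,
20 CV repeats) completes in well under ten minutes on one CPU and is
byte-reproducible under a fixed seed.

## Known limitations

* No spatial structure in the noise; FDR behaviour on spatially smooth
  real data will differ.
* OLS without prewhitening; efficiency, not validity, is affected
  under serially correlated noise.
* The bootstrap z anticonservatism described above is a property of
  the mean/SD bootstrap summary for SVM weights, inherited from the
  protocol it implements.
* Rating-level analysis approximates parametric betas by per-level
  trial averages.
* The atlas similarity module consumes any integer parcellation but
  does not bundle a real brain atlas.
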