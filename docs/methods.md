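# Methods

This note documents the models and numerical choices behind `rehosim`: what
the synthetic cohorts emulate, how each pipeline stage is defined, which
parameters matter, and what passing tests do and do not establish.

## 1. Synthetic cohorts

### Time-series model (`make_cohort`)

Each subject's voxel time series on the common grid is

```
y_v(t) = drift_v(t) + Σ_k b_vk · z_k(t) + w · s(t) · 1[v ∈ effect region] + ε_v(t)
```

* `drift_v` — Legendre polynomial of order `drift_order` (default 2) with
  coefficients drawn per subject *and voxel* (scale = the study noise scale).
  Per-voxel coefficients are deliberate: a subject-shared drift would leak
  through the band edges and create spurious concordance everywhere.
* `z_k` — six motion-like nuisance regressors per subject: standardized
  AR(1) series with autocorrelation 0.3.  Mild autocorrelation is chosen over
  random walks so the regressors do not concentrate in the narrow passband at
  desk-scale run lengths (see "Temporal cleaning" below).
* `s(t)` — a unit-variance AR(1) latent (autocorrelation 0.85) shared by all
  voxels of the study's spherical effect region.  Its mixing weight is
  `w = (0.4 + effect_strength·1[male]) · noise_sd`: a higher shared-signal
  weight means higher local synchrony, hence higher expected Kendall's W.
  `effect_strength` is therefore a dimensionless synchrony difference between
  the sexes; 0 makes the sexes statistically identical.
  `region_jitter_sd > 0` adds a per-subject offset to `w` (both sexes),
  modeling population heterogeneity in regional synchrony.
* `ε_v` — white Gaussian noise with per-study scale `noise_sd`.

Subject masks are the innermost `coverage_fraction` of a canonical
ellipsoidal mask (semi-axes 0.45 × grid), selected by jittered distance from
center, so each subject mask is a subset of the canonical mask and mean
coverage tracks the parameter to well under 2%.

Defaults: 16×16×16 grid, 60 timepoints at 2 s (120 s window — the
0.01–0.08 Hz band holds 8 DFT bins at this length, so band edges are
coarse), one master seed with per-subject streams hash-derived (SHA-256)
from (seed, study, subject index).  Identical spec + seed reproduce the
cohort bit for bit across platforms.

Age is generated (per-study Gaussian, for schema fidelity with the packaged
demographics table) but unused by the pipeline.

### Fast path (`make_reho_maps`)

For simulation-harness experiments the generator can emit ReHo-like maps
directly: Gaussian fields clipped to [0, 1] with baseline 0.25, additive map
noise `0.05 · noise_sd`, and inside the effect region an elevation
`0.2 / (1 + noise_sd²)` — emulating that temporal noise depresses
concordance — plus `effect_strength` for males (here a *direct* map-mean
difference) plus the per-subject `region_jitter_sd` offset.
`region_baseline` overrides the noise-derived elevation where an experiment
needs sites without concordance-level differences.

### Packaged cohorts

* `null_cohort_spec` — one 80-subject study, `effect_strength 0`.
* `two_site_spec` — shared effect (0.05), noise 1.5 vs 2.5, coverage 1.0 vs
  0.85.  The noise difference shifts the effect-region concordance baseline
  between sites and the coverage difference misaligns group masks, so
  classifiers transfer imperfectly: within-site ≈ 0.93/0.73 vs cross-site
  ≈ 0.69/0.69 at size 20 (200 replicates).
* `subset_geometry_spec` — a homogeneous site with a strong narrow effect
  (0.3, radius 2) strictly inside a heterogeneous site's weak wide region
  (0.07, radius 4, jitter 0.05).  Training on the wide site classifies the
  narrow site well (~0.82) while the reverse direction drops toward chance
  (~0.53): the classifier trained on the homogeneous subsample is
  miscalibrated for, and destabilized by, variation it never saw.

These parameters were calibrated once, when the cohorts were frozen, to
place accuracies in the informative mid-range; they are study conditions,
not fitted estimates of any real site's properties.

### What the generator does *not* emulate

Hemodynamics, anatomical geometry, physiological noise, realistic motion
(only additive regressors), registration/resampling, age or diagnosis
effects.  Passing tests therefore demonstrate correctness of the *pipeline
machinery* and qualitative site-effect logic, not expected accuracy levels
on real multi-site data.

## 2. Temporal cleaning

The bandpass is a discrete-Fourier brick wall: coefficients strictly outside
[f_low, f_high] (defaults 0.01/0.08 Hz) and the zero-frequency term are
zeroed.  As an exact orthogonal projection it is idempotent, which is
tested.  Bands reaching Nyquist are rejected.

Detrending is voxelwise OLS on Legendre polynomials 0..poly_order plus the
nuisance columns, with a rank check that names collinear columns.

Order: **regression first, then bandpass** (default).  At 60 timepoints the
passband holds only 8 complex bins; raw low-frequency regressors nearly span
it, so filtering first and then regressing either leaves most of the
filtered nuisance in the data (raw regressors) or removes roughly half of
any in-band shared signal (filtered regressors).  Regressing first
annihilates baseline and nuisance exactly and costs the latent signal only
its small projection onto the design.  The alternative order remains
available (`detrend_first=False`); it bandpasses the nuisance columns before
regression so the surviving nuisance component is still removed exactly.

## 3. Regional homogeneity

Ranks use the average-rank tie convention (`scipy.stats.rankdata`).  The
neighborhood scan is vectorized: per-voxel ranks once, then 3×3×3 box sums
for column rank sums and in-mask counts; it agrees with per-voxel
brute-force evaluation to 1e−12.  Tie correction is implemented but **off**
by default — the data are continuous and the classical ReHo definition omits
it.  Boundary policy: all in-mask cube voxels participate (1 ≤ m ≤ 27);
voxels with m < 2 get exactly 0; a strict full-cube-only policy is available.
Values are clipped to [0, 1] against eps-level float accumulation overshoot.
Maps live on the common synthetic grid; no resampling occurs.

Note one intrinsic spillover: a voxel just outside the effect region has
in-region neighbors, so ReHo elevation extends one voxel beyond the region.
Tests of "no effect outside" exclude this dilated ring.

## 4. Group mask and features

A voxel enters the group mask iff present in ≥ `threshold` (default 0.95,
inclusive) of the *training* subjects' masks; the comparison is implemented
as `count ≥ threshold·n − 1e−9` because binary floating point otherwise
breaks the inclusive boundary (0.95 × 20 > 19 in float64).  A voxel absent
from every mask is never kept (threshold 0 yields the union).  Feature order
is lexicographic in the (x, y, z) voxel index (C-order flattening), fixed
and tested.  Test-subject masks are never read during training, so feature
dimensionality p varies across replicates — by design.

## 5. Classifier

Mean-centering only (no variance scaling by default), full-rank PCA
(min(n−1, p) components — the only meaningful "no dimensionality reduction"
with n ≪ p), then a linear-kernel soft-margin SVM with C = 1.0 (exposed) and
a fixed solver tolerance 1e−4, no random subsampling, so replicate variance
comes only from sampling.  Because PCA after centering is an orthonormal
change of basis and the kernel is linear, the decision function equals that
of a linear SVM on the centered raw features up to solver tolerance; the
suite asserts ≥99% test-label agreement over 100 random problems.  Labels
are coded female = −1, male = +1, so back-projected weights
(`pca_basis @ svm_weights`, scattered through the group mask) are positive
where males have higher ReHo.

## 6. Resampling framework

Five families: within_study, study_to_pooled, study_pair, pooled_to_study,
pooled_to_pooled.  Samples are balanced (size/2 per sex, uniform without
replacement); the test sample is drawn first, and for families whose train
and test pools overlap the training draw excludes the test subjects, so
train ∩ test = ∅ always (asserted per replicate).  Pooled sampling ignores
study strata beyond the exclusion list.  Replicate seeds are hash-derived
from (config seed, train size, replicate id), so any replicate is re-runnable
in isolation.  Failed replicates abort the configuration with context rather
than being resampled, keeping the accuracy distribution unbiased.  Summaries
report per-size mean and sample SD (SD = 0 by convention and flagged when
n_replicates = 1); `summary_matrix` assembles the train × test table of mean
accuracies at the largest size, with pooled sources as "All/Others".

Sample-size planning: a study's maximum balanced size is the largest
multiple of 10 not exceeding twice its smaller sex count, with a per-study
override table shipped alongside the packaged demographics for the one
published value the rule does not reproduce.  Within-study grids run from 20
in steps of 10 up to the largest grid point not exceeding half the maximum
(train and test halves must coexist without overlap); cross-study training
grids run to the maximum; pooled grids run 20–200; single-study test sets
use the test study's maximum, pooled test sets use 200.

### Null benchmark

`null_benchmark` measures chance-level recovery: balanced within-study
replicates at size 20 on 80-subject cohorts with `effect_strength 0`.  The
replicate mean *conditional on one cohort* is not a clean 0.5: a finite
pool's chance sex/image association is shared between its disjoint train and
test draws, giving a cohort-level SD of ~0.025 with a right-skewed
distribution (an association can only help within-pool generalization).
Marginally, over cohorts, the expected accuracy is exactly 0.5 (test
subjects are independent of the classifier, and labels are independent of
images).  The benchmark therefore blocks its 200 replicates over 40
independent cohorts (5 each), estimating the marginal null accuracy with
~0.01 SD.  Measured values: 0.515 (seed 0), 0.506 (seed 1), 0.493 (seed
derived in the acceptance script from `--seed 1`).

## 7. Problem sizes

Default experiments use 16×16×16 grids (canonical mask ≈ 1550 voxels), 60
timepoints, 60–100 subjects per cohort, and 200 replicates per cell; the
full acceptance computation completes in about two minutes on one CPU.
These sizes were chosen so the whole study design — including the 1000-
replicate default for production configurations — remains practical on a
laptop while keeping the passband and the W statistics meaningful.

## 8. Known limitations

* Band edges are coarse at 60 × 2 s; the brick wall passes exactly 8 bins.
* The fast path's noise-to-baseline link (elevation `0.2/(1+σ²)`) is a
  stylized stand-in for the physical noise–concordance relation of the
  time-series path, not derived from it.
* The planner's override table records one published maximum balanced size
  that the 2·min(F, M) rule does not reproduce; no attempt is made to guess
  the original rule.
* Cross-platform bit-identity relies on NumPy's seeded generators and
  deterministic BLAS reductions at these sizes; across BLAS implementations
  the SVM solution may differ at solver tolerance (1e−4) level.
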