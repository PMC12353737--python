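# Methods

## The junction-volume model

The gray-white junction is operationalized as the set of voxels whose
T1-weighted signal intensity lies strictly between "typical gray matter"
and "typical white matter", restricted to brain tissue. Typicality is
estimated per subject: the mean and sample SD (n−1 divisor) of the signal
intensity over voxels whose GM (resp. WM) partial volume strictly exceeds
0.5. The band is `[mean_GM + SD_GM, mean_WM − SD_WM]` — the stored "2SD"
dispersion fields enter the threshold equations with a factor of ½. The
">50%" rule is read literally as partial volume > 0.5, so a voxel can
qualify for at most one tissue.

The binary in-band map additionally requires GM+WM partial volume ≥ 0.5.
Without this location constraint, CSF or background voxels whose intensity
happens to fall in-band (always possible under noise) would enter the
junction; the constraint is configurable (`brain_mask_min`).

The binary map is a thin, subject-specific line carrying no distributional
information, so it is regularized by a normalized 5×5×5 box convolution
(every weight 1/125, zero padding). Total junction volume is the sum of
the blurred map times the voxel volume (mL); per-voxel maps are divided by
TIV. Smoothing for group statistics uses a separable Gaussian with
σ = FWHM/(2√(2 ln 2)) per axis, truncated at 4σ, zero padding; the default
FWHM is 8 mm isotropic.

Processing order is binarize → box blur → TIV normalization → Gaussian
smoothing. Since all three transforms are linear, the order of the last
two affects nothing but scaling metadata.

**TIV normalization modes.** Dividing a dimensionless junction density by
TIV yields values of order 10⁻⁴/mL, whereas published ROI summaries of
this kind sit at order 0.1–0.45. The default mode `scaled` therefore
multiplies the per-TIV map by a reference TIV (the cohort mean; the
subject's own TIV for single-subject runs), which removes head-size
variation while keeping the magnitude of the local junction density. Mode
`fraction` keeps the raw map/TIV values. The mode is recorded in every
output sidecar. GMV and WMV maps are the partial-volume maps themselves,
TIV-normalized and smoothed identically.

**Intensity invariance.** Thresholds are affine-equivariant in the signal
intensity, so the binary junction map — and everything downstream — is
exactly invariant under SI → a·SI + b, a > 0. This is the key robustness
property of the construction and is enforced by test.

## The phantom

Synthetic subjects are three concentric spheres — WM core (default radius
16 mm at 64³, 10 mm at the 48³ test scale), GM shell, CSF shell — in air.
Partial volume across each boundary is a logistic function of signed
distance to the boundary sphere; `transition_width_mm` (default 2 mm) is
the 5%→95% distance of the GM↔WM blend, i.e. the physical junction width.
Outer boundaries use a fixed 1 mm width, there only to avoid aliasing. T1
intensity is the partial-volume mix of tissue means (CSF 40, GM 100,
WM 160, arbitrary units, the T1w ordering) plus white Gaussian noise
(SD 2). Closed forms follow for everything downstream: the volume of a
logistic-blended sphere is (4/3)πR³(1 + π²s²/R²) with s the logistic
scale, and the junction shell where GM partial volume ∈ (0.05, 0.95) is
the spherical shell of half-width `width/2` around the GM/WM boundary.

Cohorts (defaults: 33 no-plaque + 36 plaque, ages uniform on 30–70 years)
vary between subjects in two ways:

* each subject's junction width in a target subregion (one octant) is
  drawn Normal(group mean, 0.25 mm); the plaque group's mean is reduced by
  `junction_effect` (default 0.15, i.e. 0.3 mm on the 2 mm base). The
  defaults give an analytic planted effect size d = 0.3/0.25 = 1.2 on
  regional gwJTV, the scale of a strongly significant published cluster;
* metabolic covariates are built by a fixed two-factor assembly
  `cov = mean + sd·(r_age·z_age + r_w·z_width + √(1−r_age²−r_w²)·ε)`,
  which hits the declared correlations with age and with regional junction
  width exactly in expectation and requires r_age² + r_w² < 1 (checked).

The table carries ground-truth columns (`gt_width_mm`,
`gt_region_gwjtv_mm3`) so statistical stages can be validated without
running the imaging chain. What the phantom does *not* emulate: cortical
folding, bias fields, registration error, spatially varying noise, and —
important for interpreting the calibration results — anatomy that varies
between subjects through many local factors rather than one regional
width. Passing tests therefore validate the estimators and their
calibration under idealized geometry, not segmentation or registration
robustness on real brains.

## Voxel-based analysis

Per voxel, ordinary least squares of the subject maps on
[intercept, group indicator, age] (group comparison) or
[intercept, parameter, age] (metabolic regression); the reported statistic
is the t of the middle column. Voxels with no between-subject variation
(exact equality across subjects) are undefined under OLS; they get t = 0
and a flag, and are excluded from the analysis mask. Thresholding is
one-sided per direction (positive/negative contrasts reported separately,
the SPM convention) at α = 0.0005 uncorrected, followed by an extent
threshold of 100 contiguous voxels under 18-neighbour connectivity
(configurable 6/26). Peak z is Φ⁻¹(T_df(t)), clamped at |z| = 8.2 where
the CDF saturates. No further multiple-comparison correction is applied;
output tables say "uncorrected".

A calibration caveat that the test suite quantifies: with 8 mm FWHM
smoothing the null t-field is correlated over roughly (8 mm)³ ≈ 500-voxel
resels, so although the voxelwise false-positive *rate* is nominal, null
excursions that do occur usually span ≥ 100 contiguous voxels. An
uncorrected-α + extent rule is not a familywise error control under
smoothing; results should be read as descriptive, which is why the
labelling is explicit.

## ROI statistics and power

ROI values are plain means over mask voxels. Group comparison is the
pooled-variance two-sample t-test; association is Pearson partial
correlation by the residual method (both variables residualized on the
controls plus intercept; df = n − 2 − k). If the controls explain a
variable completely (residual SD below 10⁻¹⁰ of the original), the partial
correlation is 0 by residual orthogonality rather than 0/0.

Observed power is computed under the noncentral t distribution at the
observed effect: noncentrality (m_a − m_b)/(s_p√(1/n_a + 1/n_b)) with
df = n_a + n_b − 2 for the t-test, |r|√(n−2−k)/√(1−r²) with df = n−2−k for
the partial correlation, two-sided critical values at α = 0.016 by default
(0.05 Bonferroni-divided by the three tissue measures). This default is
what reproduces published power annotations of this study design; it is
configurable. Summary-level entry points (mean, SD, n) exist so published
tables can be re-analysed without raw data. Power at zero effect equals α
by construction.

Stepwise regression starts from a forced core (default age + HbA1c, never
removed), enters the candidate with the smallest partial p if below
p_enter = 0.05, then removes any non-forced term whose p exceeds
p_remove = 0.1, iterating to a fixed point (entry/removal use the
partial-F ≡ squared-t convention, identical for single-term steps).
Exactly collinear candidates are skipped with a warning. Note the
well-known selection property: with m independent null candidates the
probability that none enters is (1 − p_enter)^m ≈ 0.77 at m = 5, so noise
variables appear in roughly a quarter of null fits — a property of the
procedure, not of the implementation.

Missing covariate values are handled by listwise deletion per analysis;
the heatmap uses pairwise-complete Pearson correlations (≥ 3 pairs,
constant columns marked undefined).

## Pipeline, determinism, problem sizes

All randomness descends from one root seed through SHA-256-derived
per-stage streams (each below 2³¹); per-subject noise seeds are spawned
from the cohort stream. The run manifest records SHA-256 hashes of every
artifact and of the in-memory volumes, and identical configs reproduce
identical hashes bit for bit.

Enrollment filtering applies exclusions sequentially (consent withdrawn,
MRI refused, MRI incomplete, then age 30–70, BMI < 40, HbA1c ≤ 10,
eGFR ≥ 30); a subject failing several criteria counts under the first, so
per-criterion counts sum exactly to the number removed. An MMSE ≥ 26
filter supports cognitive sensitivity analyses.

Test-suite problem sizes are chosen so the full suite runs in minutes on
one core: junction-core oracles at 32³–48³; GLM calibration on 200 null
cohorts of 10+10 subjects at 48³ (radii 10/16/20 mm); planted-effect
recovery on 100 cohorts of 33+36 subjects at 32³ (radii 7/11/14 mm);
stepwise simulations at n = 200 with 5 candidates. The statistical
engines are size-agnostic; nothing in the implementation depends on these
grid choices.

## Known limitations

* No segmentation, spatial normalization, skull stripping or bias
  correction: inputs must be co-registered partial-volume maps in a common
  space. Surface-based or EDGE-sequence junction measures are out of scope.
* The `scaled` TIV mode is one defensible reading of "divide by TIV" that
  preserves interpretable map magnitudes; analyses comparing across
  cohorts should fix `tiv_ref` explicitly.
* Cluster extent under heavy smoothing is descriptive, not corrected
  inference (see above); random-field or permutation corrections are
  deliberately not implemented.
* The apolipoprotein ratio is computed as ApoB/ApoA1, following the
  numeric convention of clinical tables rather than the frequently
  inverted label (see the covariates module docstring).
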