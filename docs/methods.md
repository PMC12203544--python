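# Methods

This note records the models, the synthetic-data design, the numerical
choices, and the limits of what the test suite can demonstrate.

## Phantom

The phantom is an ellipsoidal head (soft tissue) inside a bone shell, with
two curved ellipsoidal ventricular tubes and a choroid plexus (ChP) grown by
seeded, jittered 6-connected region growth along the medial ventricular
wall, so the ChP is always a single connected, irregular ("frond-like")
component of exactly the requested voxel count. Ventricle voxels 6-adjacent
to the ChP receive partial-volume intensities (`m·ChP + (1−m)·CSF`,
`m ~ U(0.3, 0.7)`): these boundary voxels are what makes the second,
3-component mixture stage meaningful — without them the final
"highest-mean component" rule would split a pure ChP cluster.

Intensities are class mean × bias field + additive Gaussian noise, clipped
at zero (a Rician option exists but Gaussian is the default: at the SNRs
used the difference is negligible and Gaussian keeps the class means exact
for oracle tests). The bias field is the exponential of a random degree-2
polynomial whose *log* is rescaled to `[log(1−a), log(1+a)]`; rescaling in
the log domain keeps the log-field exactly quadratic, so the polynomial
bias corrector can remove it to machine precision — a deliberate
oracle-design choice. Default class means (T1w: CSF 20, bone 40, ChP 60,
soft 80; T2w: bone 10, ChP 40, soft 50, CSF 100) give realistic contrast
ordering on both sequences; default noise SD 4.0 is 10% of the CSF–ChP T1w
contrast; default bias amplitude 0.05. All geometry is in voxel space with
a diagonal affine.

## Segmentation

Mixtures are fitted by EM (scikit-learn) with k-means initialization, 5
seeded restarts, and a covariance regularizer proportional to the data
variance (`1e-6 · var`) — a proportional rather than absolute floor is what
makes the whole pipeline exactly equivariant under affine intensity
rescaling. Components are reported sorted by ascending mean and hard
assignments break ties toward the lower-mean component (conservative
segmentation). A variational Bayesian mixture is available behind
`SegParams.bayesian`; the selection rule (keep the highest-mean component)
is unchanged, which is the only property downstream code relies on.

SUSAN smoothing uses weights
`exp(−d²_mm/2σ²) · exp(−((I−I₀)/t)²)` over in-mask neighbours within 3σ,
centre voxel excluded; voxels whose total weight underflows (< 1e-12) keep
their input value. The brightness threshold `t` defaults to 10% of the
robust (2nd–98th percentile) in-ventricle intensity range, mirroring common
practice for the reference implementation of the filter; expressing it as a
fraction of the robust range (not an absolute intensity) is the second half
of the affine-invariance property. If the smoothed stage-1 cluster is
numerically homogeneous (relative spread ≤ 1e-12), stage 2 is skipped and
the whole cluster is returned — the only sensible degenerate-input answer.

Left/right ChP are not separated (downstream statistics use their sum), and
manual mask editing is out of scope; a `mask_diff` utility summarizes
voxel-level disagreement instead.

## T1/T2 ratio

Bias correction fits a degree-2 polynomial to log-intensities by least
squares *on the homogeneous soft-tissue reference mask* and divides out its
exponential everywhere, rescaled to preserve the in-mask median. Fitting on
a single tissue class keeps anatomy out of the fitted field; fitting on the
whole head would make even a bias-free volume non-identity.

Calibration detects each reference region's intensity peak as the mode of a
Gaussian KDE on a 512-point grid (bandwidth = 0.25 × region SD; ties go to
the lowest intensity) and maps peaks to fixed anchors (0.2, 0.6, 1.0) by a
monotone piecewise-linear transform with linear extrapolation. The expected
class order is bone < soft < CSF on T2w and CSF < bone < soft on T1w;
non-monotone peaks raise "calibration anchors not separable". A
piecewise-linear map was chosen over smoother alternatives because it is
monotone, exactly invertible, and monotone peak alignment is the only
property the downstream ratio uses; the resulting ratio is invariant to
independent positive rescaling of either raw input, which is the contract
the tests pin down.

The ratio map divides calibrated T1 by calibrated T2 where the latter
exceeds 1e-6 × its in-mask median; the mean ChP ratio is taken over the
mask eroded once with the 6-connected structuring element (falling back,
with a logged warning, to the un-eroded mask if erosion empties it).
Erosion demonstrably reduces partial-volume bias on a boundary-corrupted
phantom (asserted in the tests). T1–T2 rigid registration is out of scope:
phantoms are generated co-registered and a grid mismatch is an input error.

## Synthetic cohort

Each variable is generated on a latent z-scale built to have unit variance
at baseline, then mapped to natural units by the cohort's published
location/scale (normalized volumes on the ×1000 scale). The generating
equation per outcome and visit is

    z = curve(d₀) + Σβ·z₀(predictor) + slope·t + Σγ·z₀(moderator)·t + b + e

with d₀ the baseline disease duration, t years since baseline, b a subject
random intercept and e within-subject noise. Design decisions that matter:

* **Durations** are Gamma(shape ≈ 0.3) moment-matched to mean 9.5 / SD 17.4
  years, *conditioned on duration ≤ 50 years* by exact inverse-CDF sampling.
  The untruncated tail reaches past 80 years, which is biologically
  impossible in a cohort of mean age 40.8 and would dominate the variance of
  the quadratic T1/T2 curve; the published duration moments are internally
  inconsistent with the age distribution, so the realized marginal
  (≈ 6.9 ± 10.3 y) is the closest biologically admissible match.
* **Long-term curves** (saturating-exponential rise with optional late
  hinge decline for ChP volume, plateau parameter 12 y; parabola with
  vertex at the 10-y nadir for T1/T2; linear for lateral ventricle) are
  empirically standardized over the sampled durations and scaled by the
  `amplitudes` parameter, which therefore *is* the SD of the long-term
  component: the default 0.7 places half of the between-subject variance on
  the trajectory, consistent with clearly resolved long-term curves.
  Curves are evaluated at baseline duration and frozen within subject:
  short-term within-subject change is carried entirely by the time slopes
  and interactions, so the generating coefficients are exactly the
  estimands of the recovery models (letting the curve also evolve within
  subject would add ≈ 0.26 z/y of drift to the ChP slope and make the
  printed coefficients unrecoverable by construction).
* **Effects** are partial standardized coefficients; structural terms use
  the subject's *observed* baseline predictor z (including its noise), so
  regression recovery is unattenuated. Residual intercept variance is set
  as 1 − var(deterministic part) − var(within noise), with an explicit
  error naming the offending equation when a requested effect combination
  is infeasible. Within-noise SD defaults: 0.25 for MRI-derived measures
  (high scan–rescan reliability), 0.45 for cognitive/EDSS scores.
* **EDSS** maps its latent z through a monotone two-piece lognormal
  calibrated to median 2.0, IQR 1.5–3.5, rounded to the 0–10 half-point
  scale. The nonlinearity slightly attenuates linear associations on the
  observed scale; EDSS recovery is therefore not oracle-gated.
* **Visits**: 65% of subjects have a first follow-up (log-normal around
  7.2 months, IQR-matched), 80/276 of those a second (19.2 months);
  dropout is independent of outcomes (no mechanism is published). Missing
  visits are absent rows, not NAs. Learning effects on cognition are
  encoded as positive time slopes.
* The lateral-ventricle marginal (15 ± 8, ×1000) is an assumption — no
  published value exists. Linear location/scale mapping can produce rare
  negative lesion volumes; statistics operate on the z-scale, so these are
  kept rather than truncated (documented limitation).

What the generator does *not* emulate: relapse events, treatment
switching, pseudo-atrophy, outcome-dependent dropout, measurement floor and
ceiling effects (other than EDSS), and any spatial correspondence between
the imaging phantom and the cohort table. Passing recovery tests therefore
show that the statistical machinery is correct and well-calibrated under
the stated generating model — not that the pipeline is robust to the
messiness of real cohorts.

## Trajectory estimation

The alternating fit interleaves (i) a local-linear tricube smooth of
`(duration, y − α)` and (ii) ridge-shrunk subject offsets
`αᵢ = nᵢ/(nᵢ+λ)·mean(residual)`, recentred to mean zero (λ = 1 mimics a
random-intercept BLUP with unit variance ratio), until the curve changes by
less than `tol = 1e-4` in sup-norm (max 50 iterations; non-convergence is
flagged, not fatal). The smoother bandwidth is a *nearest-neighbour span*:
at each evaluation point the tricube half-width is the distance to the
`ceil(0.3·n)`-th nearest observation. With disease durations heavily
right-skewed, a fixed-width window of comparable coverage is ~15 y wide and
demonstrably cannot resolve the 4-y rise scale of the ChP curve even on
noise-free data; the adaptive span keeps windows narrow where the data are
dense (early durations, where the curve's headline behaviour lives) and
wide in the sparse tail. Local-linear (rather than spline) smoothing is
kept for its boundary-bias control. Windows with fewer than 5 observations
raise an error advising a larger span; windows whose durations coincide
fall back to the weighted mean.

Because the local-linear smoother is not a symmetric shrinking operator,
the alternation is a fixed-point iteration, not coordinate descent, and the
mean-squared-residual path is not exactly monotone: after the large initial
drop it exhibits geometrically decaying micro-increases (≲ 3e-5). The path
is recorded and monitored — tests require no per-iteration rise above 0.1%
of the initial objective and a net decrease — as a divergence guard rather
than a strict descent certificate.

Confidence bands are percentile intervals from 200 subject-level bootstrap
resamples (respecting within-subject correlation), each refitted with a
reduced iteration cap (10); bands are widened minimally where needed so
they always envelop the point estimate. Turning points: slopes by central
differences on the 100-point grid; plateau onset is the first grid point
after the global-|slope| maximum whose |slope| falls below 10% of that
maximum and stays below for 5 further grid points; the extremum is the
interior global minimum ("nadir") or maximum ("peak") at least 2 grid
points from each boundary. Note an intrinsic property of the plateau rule:
for a saturating exponential `A(1−e^{−3d/P})` the 10% crossing sits at
`P·ln10/3 ≈ 0.77·P`, i.e. the rule's estimand is systematically *earlier*
than the curve's nominal plateau parameter; the tests pin the analytic
crossing, not P itself. Offsets-only self-modelling (no latent time shifts)
suffices because the time axis is anchored to observed disease duration; a
shift extension is intentionally out of scope.

## Association layer

Continuous variables are z-scored against the baseline-visit mean/SD, so
longitudinal coefficients are in baseline-SD units and are not shrunk by
follow-up variance inflation; categorical covariates (gender, DMT class)
enter dummy-coded and unstandardized; time stays in raw years. In
longitudinal models all covariates are taken at their baseline value:
disease duration at assessment equals baseline duration plus time and is
exactly collinear with the time effect within subject — entered
time-varying it absorbs ~11% of the generating slope. Mixed models use ML
(not REML) so nested fixed-effect comparisons remain valid, with Wald CIs;
a singular random-intercept variance is logged and the fit retained. The
degenerate limit (no noise, no random effects) reproduces OLS to 1e-6.

Stepwise selection is bidirectional on p-values (enter < 0.05,
remove > 0.10, covariates forced, candidates scanned deterministically by
ascending p), the common clinical-stats default; it is excluded from FDR
correction because its p-values are selection-conditioned. BH-FDR is the
exact step-up formula (cross-checked in tests against both a brute-force
rejection-set oracle and statsmodels), applied within one family per
results table, which the output labels explicitly.

## Problem sizes and tolerances

Defaults used by the tests and the acceptance script: 64³ phantoms
(~2400 ventricle voxels, 500-voxel ChP), cohorts of n = 422 with the study
visit structure, one 20 000-subject baseline-only cohort for large-sample
recovery, 200 bootstrap resamples for trajectory bands, and 100-replicate
simulations (n = 120–422) for type-I error, coverage and stepwise
calibration checks. Closed-form oracles are asserted at 1e-6–1e-9;
parameter-recovery checks use 2-SE bands or the generator's ±0.02
large-sample tolerance.
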