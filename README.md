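# plexdyn

Tools for studying the **choroid plexus (ChP)** — the CSF-producing,
immunologically active structure inside the brain ventricles — in
relapsing-remitting multiple sclerosis. The ChP enlarges early in MS, and
its tissue microstructure (probed by the conventional-MRI **T1w/T2w ratio**)
changes on a different clock than its volume. `plexdyn` packages the whole
computational chain needed to study those dynamics, exercised end-to-end on
synthetic data with exact ground truth:

* **Phantom generator** — co-registered 3D T1w/T2w volumes with ventricles,
  an embedded frond-like ChP, partial-volume boundary voxels, reference
  tissue regions, smooth multiplicative bias fields and additive noise.
* **ChP segmentation** — a two-stage intensity-clustering pipeline: a
  2-component Gaussian mixture over in-ventricle T1w voxels keeps the bright
  cluster, SUSAN structure-preserving smoothing (spatial Gaussian ×
  intensity-similarity weights) denoises it, and a 3-component mixture on
  the smoothed intensities selects the highest-mean component as the final
  ChP. Volumes are reported in ml and normalized by intracranial volume
  (NChPV = ChP volume / ICV).
* **T1/T2 ratio mapping** — log-domain polynomial bias correction, then a
  monotone piecewise-linear calibration that pins the detected intensity
  peaks of CSF / bone / soft-tissue reference regions to fixed dimensionless
  anchors, making the voxelwise ratio T1w/T2w invariant to scanner gain;
  the mean ChP ratio is read from a one-voxel-eroded mask to limit
  partial-volume contamination.
* **Cohort generator** — longitudinal subject-visit tables calibrated to a
  422-patient RRMS cohort (baseline / ~6-month / ~18-month visits with
  dropout), with latent non-linear long-term curves over disease duration
  and configurable standardized cross-sectional and longitudinal effects.
* **Trajectory estimation (GRACE/ACE)** — each subject contributes a few
  observations spanning under two years, but baseline disease durations are
  staggered over decades. After ECDF-rescaling the outcome to (0,1), an
  alternating self-modelling fit estimates a shared long-term curve
  *g*(duration) plus ridge-shrunk subject offsets α*ᵢ*:

      y_ij = g(d_ij) + α_i + ε_ij,   Σ α_i = 0

  with *g* a local-linear tricube smoother (nearest-neighbour span),
  subject-level bootstrap confidence bands, and turning-point detection
  (plateau onset, interior nadir/peak).
* **Association layer** — annualized changes, standardized (z-scored)
  adjusted OLS at baseline, linear mixed models with random subject
  intercepts for change over follow-up time (including baseline-measure ×
  time interactions), bidirectional p-value stepwise selection, and
  Benjamini–Hochberg FDR.

## Worked example

```python
from plexdyn import (PhantomSpec, make_phantom, SegParams, segment_chp, dice,
                     t1t2_ratio_workflow, CohortSpec, sample_cohort,
                     fit_longitudinal, GraceModel, GraceParams)

pair = make_phantom(PhantomSpec(seed=7))
seg = segment_chp(pair.t1w, pair.ventricle_mask, pair.voxel_dims,
                  pair.icv_ml, SegParams(seed=0))
print(f"ChP volume: {seg.volume_ml:.3f} ml "
      f"(truth {pair.chp_volume_ml:.3f} ml, "
      f"Dice {dice(seg.mask, pair.chp_truth_mask):.3f})")

ratio = t1t2_ratio_workflow(pair.t1w, pair.t2w, seg.mask, pair.ref_masks)
print(f"mean ChP T1/T2 ratio: {ratio.mean_ratio:.3f}")

cohort = sample_cohort(CohortSpec(seed=1))
res = fit_longitudinal(cohort.data, "nchpv")[0]
print(f"NChPV ~ time: beta = {res.beta_std:.2f} (SE {res.se:.2f})")

fit = GraceModel.from_dataframe(cohort.data, "t1t2",
                                params=GraceParams(seed=8)).fit()
print(fit.summary())
```

prints

```
ChP volume: 0.509 ml (truth 0.500 ml, Dice 0.991)
mean ChP T1/T2 ratio: 1.576
NChPV ~ time: beta = 0.45 (SE 0.02)
GRACE long-term trajectory fit
==============================
observations:        794
subjects:            422
duration range (y):  0.00 .. 48.75
span (data fraction):0.30
iterations:          12 (converged)
final mean sq resid: 0.01295
offset SD:           0.1553
nadir (y):           8.37
```

The segmentation recovers the ground-truth ChP almost voxel-perfectly at
the default noise level (Dice 0.99); the mixed model recovers the
generating standardized time slope of normalized ChP volume (0.45 per
year); and the trajectory stage finds the interior minimum of the latent
T1/T2 curve — volume rises early in the disease course while the T1/T2
ratio dips and later recovers.

A `plexdyn` CLI mirrors the library (`simulate-phantom`, `segment`,
`ratio`, `simulate-cohort`, `trajectory`, `associations`, `run-full`), e.g.

```bash
plexdyn run-full --out run1 --seed 5
```

writes NIfTI/CSV/JSON artifacts for every stage plus an aggregated
`report.json` that is byte-identical across reruns with the same
configuration and seed.

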