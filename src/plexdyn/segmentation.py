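"""Two-stage GMM choroid plexus segmentation with SUSAN smoothing.

Stage 1 clusters the in-ventricle T1w intensities into two Gaussian
components and keeps the brighter one (ChP plus partial-volume voxels).
Those voxels are smoothed with a 3D SUSAN-style structure-preserving filter
(spatial Gaussian x intensity-similarity weights), and a second, 3-component
GMM on the smoothed intensities selects the highest-mean component as the
final ChP.  Volumes are reported absolute (ml) and normalized by the
intracranial volume (ICV).

The mixtures are fitted by EM with k-means initialization and multiple
seeded restarts (an optional variational Bayesian treatment is available via
``SegParams.bayesian``); components are always reported sorted by ascending
mean, and hard assignments break responsibility ties toward the lower-mean
component.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.mixture import BayesianGaussianMixture, GaussianMixture

__all__ = [
    "GMMFit",
    "SegParams",
    "ChPSegmentation",
    "fit_gmm",
    "susan_smooth",
    "segment_chp",
    "normalized_volume",
    "dice",
    "mask_diff",
]


class DegenerateIntensityError(ValueError):
    """Raised when the intensity distribution has no spread."""


@dataclass
class GMMFit:
    k: int
    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    responsibilities: np.ndarray
    log_likelihood: float
    converged: bool

    @property
    def labels(self) -> np.ndarray:
        """Hard assignment: argmax responsibility, ties to the lower index
        (= lower mean, since components are sorted)."""
        return np.argmax(self.responsibilities, axis=1)


@dataclass(frozen=True)
class SegParams:
    susan_sigma_mm: float = 1.0
    susan_brightness_frac: float = 0.1
    gmm_restarts: int = 5
    gmm_tol: float = 1e-5
    gmm_max_iter: int = 300
    seed: int = 0
    bayesian: bool = False

    def __post_init__(self) -> None:
        if self.susan_sigma_mm <= 0:
            raise ValueError("susan_sigma_mm must be > 0")
        if not 0 < self.susan_brightness_frac <= 1:
            raise ValueError("susan_brightness_frac must be in (0, 1]")
        if self.gmm_restarts < 1 or self.gmm_max_iter < 1:
            raise ValueError("gmm_restarts and gmm_max_iter must be >= 1")


@dataclass
class ChPSegmentation:
    mask: np.ndarray
    volume_ml: float
    normalized_volume: float
    stage1_fit: GMMFit
    stage2_fit: GMMFit | None
    brightness_thresh: float


def fit_gmm(values, k: int, params: SegParams | None = None) -> GMMFit:
    """Fit a k-component univariate Gaussian mixture by EM.

    Best of ``params.gmm_restarts`` seeded k-means-initialized restarts by
    log-likelihood.  The covariance regularizer is scaled to the data
    variance so results are equivariant under affine intensity rescaling.
    """
    params = params or SegParams()
    values = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(values)):
        raise ValueError("intensities must be finite")
    if len(values) < 10 * k:
        raise ValueError(f"need at least {10 * k} values for k={k}, got {len(values)}")
    spread = np.ptp(values)
    if spread == 0:
        raise DegenerateIntensityError("degenerate intensities (zero spread)")

    X = values.reshape(-1, 1)
    reg = max(float(np.var(values)) * 1e-6, np.finfo(float).tiny)
    common = dict(
        n_components=k,
        covariance_type="full",
        tol=params.gmm_tol,
        max_iter=params.gmm_max_iter,
        n_init=params.gmm_restarts,
        init_params="kmeans",
        reg_covar=reg,
        random_state=params.seed,
    )
    if params.bayesian:
        model = BayesianGaussianMixture(
            weight_concentration_prior_type="dirichlet_process", **common)
    else:
        model = GaussianMixture(**common)
    model.fit(X)

    means = model.means_.ravel()
    order = np.argsort(means, kind="stable")
    resp = model.predict_proba(X)[:, order]
    return GMMFit(
        k=k,
        means=means[order],
        variances=model.covariances_.reshape(k, -1)[:, 0][order],
        weights=model.weights_[order],
        responsibilities=resp,
        log_likelihood=float(model.score(X) * len(values)),
        converged=bool(model.converged_),
    )


def _susan_offsets(sigma_mm: float, voxel_dims) -> tuple[np.ndarray, np.ndarray]:
    radius = 3.0 * sigma_mm
    ranges = [int(np.floor(radius / d)) for d in voxel_dims]
    offs, w = [], []
    for o in itertools.product(*(range(-r, r + 1) for r in ranges)):
        if o == (0, 0, 0):
            continue
        d2 = sum((oi * di) ** 2 for oi, di in zip(o, voxel_dims))
        if d2 <= radius * radius:
            offs.append(o)
            w.append(np.exp(-d2 / (2.0 * sigma_mm**2)))
    return np.asarray(offs, dtype=int), np.asarray(w, dtype=float)


def susan_smooth(volume, mask, sigma_mm: float, brightness_thresh: float,
                 voxel_dims=(1.0, 1.0, 1.0)) -> np.ndarray:
    """SUSAN-style smoothing restricted to a mask.

    For each in-mask voxel the output is the weighted mean over in-mask
    neighbours within 3 sigma (the centre voxel excluded), with weight
    ``exp(-d_mm^2 / 2 sigma^2) * exp(-((I - I0)/t)^2)``.  If the total
    weight underflows the voxel keeps its input value; out-of-mask voxels
    are returned unchanged.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    if sigma_mm <= 0 or brightness_thresh <= 0:
        raise ValueError("sigma_mm and brightness_thresh must be > 0")

    offs, w_spatial = _susan_offsets(sigma_mm, voxel_dims)
    coords = np.argwhere(mask)
    if len(coords) == 0:
        return volume.copy()
    center_vals = volume[mask]

    num = np.zeros(len(coords))
    den = np.zeros(len(coords))
    shape = np.asarray(volume.shape)
    for o, ws in zip(offs, w_spatial):
        nb = coords + o
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        idx = tuple(nb[ok].T)
        ok[ok] = mask[idx]
        idx = tuple((coords[ok] + o).T)
        nv = volume[idx]
        wi = ws * np.exp(-(((nv - center_vals[ok]) / brightness_thresh) ** 2))
        num[ok] += wi * nv
        den[ok] += wi

    out = volume.copy()
    good = den >= 1e-12
    smoothed = center_vals.copy()
    smoothed[good] = num[good] / den[good]
    out[mask] = smoothed
    return out


def segment_chp(t1w, ventricle_mask, voxel_dims, icv_ml: float,
                params: SegParams | None = None) -> ChPSegmentation:
    """Run the full two-stage segmentation on one T1w volume."""
    params = params or SegParams()
    t1w = np.asarray(t1w, dtype=float)
    ventricle_mask = np.asarray(ventricle_mask, dtype=bool)
    if t1w.shape != ventricle_mask.shape:
        raise ValueError("t1w and ventricle_mask shapes differ")
    if not ventricle_mask.any():
        raise ValueError("ventricle_mask is empty")
    if icv_ml <= 0:
        raise ValueError("icv_ml must be > 0")

    vals = t1w[ventricle_mask]
    stage1 = fit_gmm(vals, 2, params)
    keep = stage1.labels == 1  # higher-mean component (sorted ascending)
    if not keep.any():
        raise ValueError("stage-1 high-intensity cluster is empty")
    kept_mask = np.zeros_like(ventricle_mask)
    kept_mask[ventricle_mask] = keep

    p2, p98 = np.percentile(vals, [2, 98])
    brightness = params.susan_brightness_frac * (p98 - p2)
    if brightness <= 0:
        brightness = max(abs(float(vals.mean())), 1.0) * 1e-6

    smoothed = susan_smooth(t1w, kept_mask, params.susan_sigma_mm,
                            brightness, voxel_dims)
    svals = smoothed[kept_mask]
    scale = max(float(np.max(np.abs(svals))), 1.0)
    if np.ptp(svals) <= 1e-12 * scale:
        # homogeneous after smoothing: nothing left for stage 2 to split
        final_in_kept = np.ones(len(svals), dtype=bool)
        stage2 = None
    else:
        stage2 = fit_gmm(svals, 3, params)
        final_in_kept = stage2.labels == 2  # highest-mean component
    final = np.zeros_like(ventricle_mask)
    final[kept_mask] = final_in_kept

    vox_ml = float(np.prod(voxel_dims)) / 1000.0
    volume_ml = float(final.sum()) * vox_ml
    return ChPSegmentation(
        mask=final,
        volume_ml=volume_ml,
        normalized_volume=normalized_volume(volume_ml, icv_ml),
        stage1_fit=stage1,
        stage2_fit=stage2,
        brightness_thresh=float(brightness),
    )


def normalized_volume(volume_ml: float, icv_ml: float) -> float:
    """Tissue volume divided by total intracranial volume (both ml)."""
    if icv_ml <= 0:
        raise ValueError("icv_ml must be > 0")
    return float(volume_ml) / float(icv_ml)


def dice(a, b) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)


def mask_diff(a, b) -> dict[str, int]:
    """Voxel-count summary of how two masks differ (stand-in for manual QC
    editing, which is out of scope)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    return {
        "only_a": int((a & ~b).sum()),
        "only_b": int((b & ~a).sum()),
        "both": int((a & b).sum()),
    }
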