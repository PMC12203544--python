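"""Calibrated T1w/T2w ratio maps and mean ChP ratio extraction.

Raw T1w and T2w intensities are in arbitrary, scanner-dependent units, so a
voxelwise quotient is meaningless without calibration.  Both volumes are
bias-corrected (log-domain polynomial fit on a homogeneous reference
tissue), then mapped through a monotone piecewise-linear transform that
sends the detected intensity peaks of three reference regions (CSF, bone,
soft tissue) to fixed dimensionless anchor targets.  The ratio of the two
calibrated volumes is then invariant to independent positive rescaling of
the raw inputs.  The mean ChP ratio is extracted from the ChP mask eroded by
one voxel (6-connectivity) to reduce partial-volume contamination.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "CalibrationParams",
    "RatioResult",
    "correct_bias",
    "histogram_peak",
    "calibration_peaks",
    "calibrate_intensities",
    "erode_one_voxel",
    "compute_ratio",
    "t1t2_ratio_workflow",
]

logger = logging.getLogger(__name__)

#: default anchors, ascending intensity per contrast
T1W_CLASS_ORDER = ("csf", "bone", "soft_tissue")
T2W_CLASS_ORDER = ("bone", "soft_tissue", "csf")
DEFAULT_TARGETS = (0.2, 0.6, 1.0)


@dataclass(frozen=True)
class CalibrationParams:
    """Anchor targets and peak-detection controls for one contrast.

    ``class_order`` lists the reference classes in the intensity order the
    contrast is expected to produce; ``anchor_targets`` maps each class to
    its dimensionless target value (must increase along ``class_order``).
    """

    class_order: tuple[str, str, str] = T2W_CLASS_ORDER
    anchor_targets: dict[str, float] = field(
        default_factory=lambda: dict(zip(T2W_CLASS_ORDER, DEFAULT_TARGETS)))
    kde_bandwidth_frac: float = 0.25
    bias_poly_order: int = 2

    def __post_init__(self) -> None:
        if self.kde_bandwidth_frac <= 0:
            raise ValueError("kde_bandwidth_frac must be > 0")
        if self.bias_poly_order < 0:
            raise ValueError("bias_poly_order must be >= 0")
        targets = [self.anchor_targets[c] for c in self.class_order]
        if not all(a < b for a, b in zip(targets, targets[1:])):
            raise ValueError("anchor_targets must increase along class_order")

    @classmethod
    def for_t1w(cls) -> "CalibrationParams":
        return cls(class_order=T1W_CLASS_ORDER,
                   anchor_targets=dict(zip(T1W_CLASS_ORDER, DEFAULT_TARGETS)))

    @classmethod
    def for_t2w(cls) -> "CalibrationParams":
        return cls()


@dataclass
class RatioResult:
    ratio_map: np.ndarray
    eroded_mask: np.ndarray
    mean_ratio: float
    peaks_t1: dict[str, float] | None = None
    peaks_t2: dict[str, float] | None = None


def _poly_design(coords_norm: np.ndarray, order: int) -> np.ndarray:
    cols = []
    for powers in itertools.product(range(order + 1), repeat=3):
        if sum(powers) <= order:
            cols.append(np.prod([coords_norm[:, i] ** p
                                 for i, p in enumerate(powers)], axis=0))
    return np.column_stack(cols)


def correct_bias(volume, head_mask, order: int = 2) -> np.ndarray:
    """Divide out a smooth multiplicative bias field.

    A degree-``order`` polynomial is least-squares fitted to the
    log-intensities of the in-mask voxels; its exponential is divided out
    everywhere and the result rescaled so the in-mask median is unchanged.
    The mask should cover (approximately) homogeneous tissue, otherwise
    anatomy leaks into the fitted field.
    """
    volume = np.asarray(volume, dtype=float)
    head_mask = np.asarray(head_mask, dtype=bool)
    if volume.shape != head_mask.shape:
        raise ValueError("volume and head_mask shapes differ")
    if not head_mask.any():
        raise ValueError("head_mask is empty")
    vals = volume[head_mask]
    if np.any(vals <= 0):
        raise ValueError("in-mask intensities must be strictly positive")

    shape = volume.shape
    coords = np.argwhere(head_mask).astype(float)
    norm = 2.0 * coords / (np.asarray(shape) - 1.0) - 1.0
    X = _poly_design(norm, order)
    coef, *_ = np.linalg.lstsq(X, np.log(vals), rcond=None)

    all_coords = np.indices(shape).reshape(3, -1).T.astype(float)
    all_norm = 2.0 * all_coords / (np.asarray(shape) - 1.0) - 1.0
    field_log = _poly_design(all_norm, order) @ coef
    bias = np.exp(field_log).reshape(shape)

    out = volume / bias
    med_in, med_out = np.median(vals), np.median(out[head_mask])
    if med_out > 0:
        out *= med_in / med_out
    return out


def histogram_peak(values, bandwidth: float) -> float:
    """Mode of a Gaussian KDE on a 512-point grid over the value range.

    Ties resolve to the lowest-intensity mode.
    """
    values = np.asarray(values, dtype=float).ravel()
    if len(values) < 50:
        raise ValueError(f"need at least 50 values, got {len(values)}")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    lo, hi = values.min(), values.max()
    if lo == hi:
        return float(lo)
    grid = np.linspace(lo, hi, 512)
    dens = np.zeros(512)
    for chunk in np.array_split(values, max(1, len(values) // 4096)):
        dens += np.exp(-0.5 * ((grid[:, None] - chunk[None, :]) / bandwidth) ** 2
                       ).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def calibration_peaks(volume, ref_masks: dict[str, np.ndarray],
                      params: CalibrationParams) -> dict[str, float]:
    """Detect the KDE intensity peak of each reference region."""
    volume = np.asarray(volume, dtype=float)
    peaks: dict[str, float] = {}
    for cls in params.class_order:
        mask = np.asarray(ref_masks[cls], dtype=bool)
        if not mask.any():
            raise ValueError(f"reference mask {cls!r} is empty")
        vals = volume[mask]
        sd = float(vals.std())
        if sd == 0:
            peaks[cls] = float(vals[0])
        else:
            peaks[cls] = histogram_peak(vals, params.kde_bandwidth_frac * sd)
    return peaks


def _piecewise_linear(x: np.ndarray, xs, ys) -> np.ndarray:
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    out = np.interp(x, xs, ys)
    lo_slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
    hi_slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
    below = x < xs[0]
    above = x > xs[-1]
    out[below] = ys[0] + (x[below] - xs[0]) * lo_slope
    out[above] = ys[-1] + (x[above] - xs[-1]) * hi_slope
    return out


def calibrate_intensities(volume, ref_masks: dict[str, np.ndarray],
                          params: CalibrationParams) -> np.ndarray:
    """Monotone piecewise-linear map through (detected peak -> anchor).

    Linear extrapolation beyond the outer anchors; raises if the detected
    peaks are not strictly increasing along the expected class order.
    """
    volume = np.asarray(volume, dtype=float)
    peaks = calibration_peaks(volume, ref_masks, params)
    pk = [peaks[c] for c in params.class_order]
    if not all(a < b for a, b in zip(pk, pk[1:])):
        raise ValueError(
            f"calibration anchors not separable: peaks {peaks} not strictly "
            f"increasing along {params.class_order}")
    tg = [params.anchor_targets[c] for c in params.class_order]
    return _piecewise_linear(volume.ravel(), pk, tg).reshape(volume.shape)


def erode_one_voxel(mask) -> np.ndarray:
    """One iteration of binary erosion with the 6-connected structuring
    element."""
    mask = np.asarray(mask, dtype=bool)
    return ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1))


def compute_ratio(t1_cal, t2_cal, chp_mask,
                  peaks_t1: dict[str, float] | None = None,
                  peaks_t2: dict[str, float] | None = None) -> RatioResult:
    """Voxelwise calibrated T1/T2 ratio and its mean over the eroded mask.

    Voxels with near-zero calibrated T2 (below 1e-6 x the in-mask median)
    are excluded.  If erosion empties the mask the mean falls back to the
    un-eroded mask with a logged warning.
    """
    t1_cal = np.asarray(t1_cal, dtype=float)
    t2_cal = np.asarray(t2_cal, dtype=float)
    chp_mask = np.asarray(chp_mask, dtype=bool)
    if not (t1_cal.shape == t2_cal.shape == chp_mask.shape):
        raise ValueError("calibrated volumes and mask must share one grid")
    if not chp_mask.any():
        raise ValueError("chp_mask is empty")

    eps = 1e-6 * float(np.median(t2_cal[chp_mask]))
    valid = t2_cal > eps
    ratio = np.full(t1_cal.shape, np.nan)
    ratio[valid] = t1_cal[valid] / t2_cal[valid]

    eroded = erode_one_voxel(chp_mask)
    sel = eroded & valid
    if not sel.any():
        logger.warning("eroded ChP mask is empty; falling back to the "
                       "un-eroded mask for the mean ratio")
        sel = chp_mask & valid
    if not sel.any():
        raise ValueError("no valid ratio voxels inside the ChP mask")
    return RatioResult(
        ratio_map=ratio,
        eroded_mask=eroded,
        mean_ratio=float(ratio[sel].mean()),
        peaks_t1=peaks_t1,
        peaks_t2=peaks_t2,
    )


def t1t2_ratio_workflow(t1w, t2w, chp_mask, ref_masks: dict[str, np.ndarray],
                        params_t1: CalibrationParams | None = None,
                        params_t2: CalibrationParams | None = None,
                        bias_correct: bool = True) -> RatioResult:
    """Full ratio pipeline: bias correction, calibration, ratio extraction.

    The bias field is fitted on the homogeneous soft-tissue reference region
    and applied globally.
    """
    params_t1 = params_t1 or CalibrationParams.for_t1w()
    params_t2 = params_t2 or CalibrationParams.for_t2w()
    if bias_correct:
        t1w = correct_bias(t1w, ref_masks["soft_tissue"], params_t1.bias_poly_order)
        t2w = correct_bias(t2w, ref_masks["soft_tissue"], params_t2.bias_poly_order)
    peaks_t1 = calibration_peaks(t1w, ref_masks, params_t1)
    peaks_t2 = calibration_peaks(t2w, ref_masks, params_t2)
    t1_cal = calibrate_intensities(t1w, ref_masks, params_t1)
    t2_cal = calibrate_intensities(t2w, ref_masks, params_t2)
    return compute_ratio(t1_cal, t2_cal, chp_mask, peaks_t1, peaks_t2)
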