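"""Synthetic co-registered T1w/T2w brain phantoms with ground truth.

The phantom stands in for the scanner acquisitions so the imaging stages
(intensity clustering, structure-preserving smoothing, ratio calibration)
can be exercised against exact ground truth.  Geometry is deliberately
simple -- an ellipsoidal head with a bone shell, two curved ellipsoidal
ventricular tubes and a frond-like choroid plexus (ChP) grown on the medial
ventricular wall -- but it reproduces the intensity structure the pipeline
has to cope with: bright ChP inside CSF-dark ventricles on T1w (reversed on
T2w), partial-volume boundary voxels, a smooth multiplicative bias field and
additive noise.

All geometry lives in voxel space with a diagonal affine; world coordinates
are not modelled.
"""

from __future__ import annotations

import heapq
import json
import os
from dataclasses import dataclass, field, asdict, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomSpec",
    "PhantomPair",
    "make_phantom",
    "write_phantom",
    "read_phantom",
]

TISSUE_CLASSES = ("csf", "chp", "soft_tissue", "bone", "background")

#: default class-mean intensities (arbitrary scanner units)
DEFAULT_MEANS_T1 = {
    "csf": 20.0,
    "chp": 60.0,
    "soft_tissue": 80.0,
    "bone": 40.0,
    "background": 2.0,
}
DEFAULT_MEANS_T2 = {
    "csf": 100.0,
    "chp": 40.0,
    "soft_tissue": 50.0,
    "bone": 10.0,
    "background": 2.0,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic T1w/T2w phantom pair.

    ``noise_sd`` is additive Gaussian noise SD (Rician optional via
    ``rician=True``); ``bias_amplitude`` *a* gives a smooth multiplicative
    field in ``[1-a, 1+a]``.  The default noise SD (4.0) is 10% of the
    CSF-ChP T1w contrast (20 vs 60).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    chp_voxel_count: int = 500
    tissue_means_t1: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEANS_T1))
    tissue_means_t2: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEANS_T2))
    noise_sd: float = 4.0
    bias_amplitude: float = 0.05
    rician: bool = False
    pv_mix_range: tuple[float, float] = (0.3, 0.7)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) < 16 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 axes, each >= 16")
        if len(self.voxel_dims) != 3 or any(d <= 0 for d in self.voxel_dims):
            raise ValueError("voxel_dims must be positive")
        for name in TISSUE_CLASSES:
            if name not in self.tissue_means_t1 or name not in self.tissue_means_t2:
                raise ValueError(f"missing tissue mean for class {name!r}")
        if not self.tissue_means_t1["chp"] > self.tissue_means_t1["csf"]:
            raise ValueError("on T1w, mean(ChP) must exceed mean(CSF)")
        if not self.tissue_means_t2["csf"] > self.tissue_means_t2["chp"]:
            raise ValueError("on T2w, mean(CSF) must exceed mean(ChP)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.bias_amplitude < 1:
            raise ValueError("bias_amplitude must be in [0, 1)")
        if self.chp_voxel_count < 1:
            raise ValueError("chp_voxel_count must be >= 1")


@dataclass
class PhantomPair:
    """Co-registered synthetic volumes plus full ground truth."""

    t1w: np.ndarray
    t2w: np.ndarray
    ventricle_mask: np.ndarray
    chp_truth_mask: np.ndarray
    ref_masks: dict[str, np.ndarray]
    bias_t1: np.ndarray
    bias_t2: np.ndarray
    icv_ml: float
    voxel_dims: tuple[float, float, float]
    spec: PhantomSpec | None = None
    pv_mask: np.ndarray | None = None

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_dims)) / 1000.0

    @property
    def chp_volume_ml(self) -> float:
        return float(self.chp_truth_mask.sum()) * self.voxel_volume_ml


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def _ventricle_tube(shape, center, side, n_samples=240):
    """One curved ellipsoidal tube (union of balls along a centreline)."""
    cx, cy, cz = center
    sy = min(shape[1] - 18, 36)  # anterior-posterior extent
    mask = np.zeros(shape, dtype=bool)
    taus = np.linspace(0.0, 1.0, n_samples)
    xs = cx + side * (5.0 + 3.0 * np.sin(np.pi * taus))
    ys = cy + (taus - 0.5) * sy
    zs = cz + 3.0 * np.cos(np.pi * taus)
    rads = 2.5 + 1.0 * np.sin(np.pi * taus)
    for x, y, z, r in zip(xs, ys, zs, rads):
        ri = int(np.ceil(r))
        sl = tuple(
            slice(max(0, int(np.floor(c - ri))), min(s, int(np.ceil(c + ri)) + 1))
            for c, s in zip((x, y, z), shape)
        )
        sub = np.ogrid[sl]
        d2 = sum((g - c) ** 2 for g, c in zip(sub, (x, y, z)))
        mask[sl] |= d2 <= r * r
    return mask


def _grow_chp(tube: np.ndarray, count: int, cx: float, rng) -> np.ndarray:
    """Seeded 6-connected region growth along the medial wall of one tube.

    Priority favours voxels close to the mid-sagittal plane with seeded
    jitter, producing an irregular frond-like single component.
    """
    coords = np.argwhere(tube)
    if count > len(coords):
        raise ValueError(
            f"chp_voxel_count={count} exceeds ventricle capacity {len(coords)}")
    jitter = rng.uniform(0.0, 0.75, size=tube.shape)
    medial = np.abs(np.indices(tube.shape)[0] - cx)
    pri = medial + jitter
    # seed: medial-most tube voxel (deterministic tie-break on flat index)
    order = np.lexsort((np.arange(len(coords)), medial[tuple(coords.T)]))
    seed = tuple(coords[order[0]])

    grown = np.zeros(tube.shape, dtype=bool)
    heap = [(pri[seed], seed)]
    seen = {seed}
    offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    n = 0
    while heap and n < count:
        _, v = heapq.heappop(heap)
        if grown[v]:
            continue
        grown[v] = True
        n += 1
        for o in offs:
            w = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
            if (0 <= w[0] < tube.shape[0] and 0 <= w[1] < tube.shape[1]
                    and 0 <= w[2] < tube.shape[2] and tube[w] and w not in seen):
                seen.add(w)
                heapq.heappush(heap, (pri[w], w))
    if n < count:  # pragma: no cover - guarded by capacity check
        raise ValueError("region growth exhausted ventricle before reaching count")
    return grown


def _bias_field(shape, amplitude: float, rng) -> np.ndarray:
    """exp of a random degree-2 polynomial, rescaled (in the log domain) so
    the field spans exactly [1-a, 1+a].  Rescaling the polynomial keeps the
    log-field exactly quadratic, which the bias corrector exploits."""
    if amplitude == 0:
        return np.ones(shape)
    axes = [np.linspace(-1.0, 1.0, s) for s in shape]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    terms = [np.ones(shape), X, Y, Z, X * Y, X * Z, Y * Z, X**2, Y**2, Z**2]
    coef = rng.normal(size=len(terms))
    q = sum(c * t for c, t in zip(coef, terms))
    qmin, qmax = q.min(), q.max()
    lo, hi = np.log(1.0 - amplitude), np.log(1.0 + amplitude)
    if qmax - qmin < 1e-12:
        return np.full(shape, np.exp(0.5 * (lo + hi)))
    q = lo + (q - qmin) * (hi - lo) / (qmax - qmin)
    return np.exp(q)


def make_phantom(spec: PhantomSpec) -> PhantomPair:
    """Build a seeded, fully deterministic phantom pair from ``spec``."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    center = tuple((s - 1) / 2.0 for s in shape)
    cx = center[0]

    head_radii = tuple(0.40 * s for s in shape)
    skull_radii = tuple(r + 3.0 for r in head_radii)
    head = _ellipsoid(shape, center, head_radii)
    skull = _ellipsoid(shape, center, skull_radii)
    bone = skull & ~head

    left = _ventricle_tube(shape, center, side=+1)
    right = _ventricle_tube(shape, center, side=-1)
    left &= head
    right &= head
    ventricle = left | right

    tube = left if left.sum() >= right.sum() else right
    chp = _grow_chp(tube, spec.chp_voxel_count, cx, rng)

    # partial-volume shell: ventricle voxels 6-adjacent to the ChP
    struct = ndimage.generate_binary_structure(3, 1)
    pv = ndimage.binary_dilation(chp, structure=struct) & ventricle & ~chp
    csf = ventricle & ~chp & ~pv

    # reference-tissue regions (pairwise disjoint, pure tissue)
    vent_dil = ndimage.binary_dilation(ventricle, structure=struct, iterations=2)
    ref_csf = ventricle & ~ndimage.binary_dilation(chp, structure=struct,
                                                   iterations=2)
    ref_bone = bone
    ref_soft = ndimage.binary_erosion(head, structure=struct, iterations=3) & ~vent_dil

    def _compose(means: dict[str, float], bias: np.ndarray, pv_mix: np.ndarray):
        vol = np.full(shape, means["background"], dtype=float)
        vol[head] = means["soft_tissue"]
        vol[bone] = means["bone"]
        vol[csf] = means["csf"]
        vol[pv] = pv_mix * means["chp"] + (1.0 - pv_mix) * means["csf"]
        vol[chp] = means["chp"]
        vol = vol * bias
        if spec.noise_sd > 0:
            if spec.rician:
                re = vol + rng.normal(scale=spec.noise_sd, size=shape)
                im = rng.normal(scale=spec.noise_sd, size=shape)
                vol = np.hypot(re, im)
            else:
                vol = vol + rng.normal(scale=spec.noise_sd, size=shape)
        return np.clip(vol, 0.0, None)

    bias_t1 = _bias_field(shape, spec.bias_amplitude, rng)
    bias_t2 = _bias_field(shape, spec.bias_amplitude, rng)
    mix = rng.uniform(*spec.pv_mix_range, size=int(pv.sum()))
    pv_mix = np.zeros(shape)
    pv_mix[pv] = mix
    t1w = _compose(spec.tissue_means_t1, bias_t1, pv_mix[pv])
    t2w = _compose(spec.tissue_means_t2, bias_t2, pv_mix[pv])

    vox_ml = float(np.prod(spec.voxel_dims)) / 1000.0
    icv_ml = float(skull.sum() - bone.sum()) * vox_ml

    return PhantomPair(
        t1w=t1w, t2w=t2w,
        ventricle_mask=ventricle, chp_truth_mask=chp,
        ref_masks={"csf": ref_csf, "bone": ref_bone, "soft_tissue": ref_soft},
        bias_t1=bias_t1, bias_t2=bias_t2,
        icv_ml=icv_ml, voxel_dims=tuple(spec.voxel_dims),
        spec=spec, pv_mask=pv,
    )


def _affine(voxel_dims) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_dims
    return aff


_VOLUMES = ("t1w", "t2w", "bias_t1", "bias_t2")
_MASKS = ("ventricle_mask", "chp_truth_mask")


def write_phantom(pair: PhantomPair, directory: str | os.PathLike) -> dict[str, str]:
    """Write NIfTI-1 volumes/masks plus a JSON ground-truth sidecar.

    Returns a name -> path mapping of everything written.
    """
    directory = os.fspath(directory)
    try:
        os.makedirs(directory, exist_ok=True)
        aff = _affine(pair.voxel_dims)
        written: dict[str, str] = {}

        def _save(name, arr, dtype):
            path = os.path.join(directory, f"{name}.nii.gz")
            nib.save(nib.Nifti1Image(arr.astype(dtype), aff), path)
            written[name] = path

        for name in _VOLUMES:
            _save(name, getattr(pair, name), np.float32)
        for name in _MASKS:
            _save(name, getattr(pair, name), np.uint8)
        for cls, m in pair.ref_masks.items():
            _save(f"ref_{cls}", m, np.uint8)

        sidecar = {
            "icv_ml": pair.icv_ml,
            "voxel_dims": list(pair.voxel_dims),
            "chp_voxel_count": int(pair.chp_truth_mask.sum()),
            "chp_volume_ml": pair.chp_volume_ml,
            "spec": _spec_dict(pair.spec) if pair.spec is not None else None,
        }
        path = os.path.join(directory, "ground_truth.json")
        with open(path, "w") as fh:
            json.dump(sidecar, fh, indent=2)
        written["ground_truth"] = path
        return written
    except OSError as exc:
        raise OSError(f"failed writing phantom to {directory!r}: {exc}") from exc


def _spec_dict(spec: PhantomSpec) -> dict:
    d = asdict(spec)
    d["grid_shape"] = list(spec.grid_shape)
    d["voxel_dims"] = list(spec.voxel_dims)
    d["pv_mix_range"] = list(spec.pv_mix_range)
    return d


def read_phantom(directory: str | os.PathLike) -> PhantomPair:
    """Read back a phantom written by :func:`write_phantom`."""
    directory = os.fspath(directory)

    def _load(name):
        return np.asarray(
            nib.load(os.path.join(directory, f"{name}.nii.gz")).dataobj)

    with open(os.path.join(directory, "ground_truth.json")) as fh:
        sidecar = json.load(fh)
    spec = None
    if sidecar.get("spec"):
        s = dict(sidecar["spec"])
        s["grid_shape"] = tuple(s["grid_shape"])
        s["voxel_dims"] = tuple(s["voxel_dims"])
        s["pv_mix_range"] = tuple(s["pv_mix_range"])
        spec = PhantomSpec(**s)
    return PhantomPair(
        t1w=_load("t1w").astype(float),
        t2w=_load("t2w").astype(float),
        ventricle_mask=_load("ventricle_mask").astype(bool),
        chp_truth_mask=_load("chp_truth_mask").astype(bool),
        ref_masks={cls: _load(f"ref_{cls}").astype(bool)
                   for cls in ("csf", "bone", "soft_tissue")},
        bias_t1=_load("bias_t1").astype(float),
        bias_t2=_load("bias_t2").astype(float),
        icv_ml=float(sidecar["icv_ml"]),
        voxel_dims=tuple(sidecar["voxel_dims"]),
        spec=spec,
    )
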