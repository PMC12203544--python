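"""End-to-end reproducible pipeline: phantom -> segmentation -> ratio ->
cohort -> trajectories -> associations.

A :class:`PipelineConfig` (optionally loaded from YAML) carries the seed,
per-stage toggles and per-module parameter overrides.  Each stage writes
its own JSON/data artifacts into the output directory; the final report
aggregates numbers *by re-reading the stage artifacts* (the reporter never
recomputes anything) and echoes a hash of the resolved configuration, so
two runs with the same config and seed produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import cohort as cohort_mod
from . import phantom as phantom_mod
from . import ratio as ratio_mod
from . import segmentation as seg_mod
from . import stats as stats_mod
from .trajectory import GraceModel, GraceParams

__all__ = ["PipelineConfig", "StageError", "run_full"]

logger = logging.getLogger(__name__)

STAGES = ("simulate_phantom", "segment", "ratio", "simulate_cohort",
          "trajectory", "associations")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "plexdyn_run"
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES})
    phantom: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    grace: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    trajectory_outcomes: tuple[str, ...] = ("nchpv", "t1t2", "nlvv")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.stages = {**{s: True for s in STAGES}, **cfg.stages}
        cfg.trajectory_outcomes = tuple(cfg.trajectory_outcomes)
        return cfg

    def resolved(self) -> dict:
        """Full parameter dump minus the output path (so reports from runs
        that differ only in destination stay byte-identical)."""
        d = dataclasses.asdict(self)
        d["trajectory_outcomes"] = list(self.trajectory_outcomes)
        d.pop("out_dir")
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(path: str, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default, sort_keys=True)


def run_full(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the aggregated report.

    Any stage error halts the run with a :class:`StageError`; artifacts of
    completed stages (and the partial report) are retained on disk.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.resolved(),
        "stages": {},
    }
    report_path = os.path.join(config.out_dir, "report.json")

    def _finish_stage(name: str, summary) -> None:
        report["stages"][name] = summary
        _write_json(report_path, report)

    state: dict = {}
    for stage in STAGES:
        if not config.stages.get(stage, True):
            _finish_stage(stage, "skipped")
            continue
        t0 = time.monotonic()
        try:
            summary = _STAGE_FUNCS[stage](config, state)
        except Exception as exc:  # halt, keep partial outputs
            _finish_stage(stage, {"error": str(exc)})
            raise StageError(stage, exc) from exc
        logger.info("stage %s finished in %.2fs", stage,
                    time.monotonic() - t0)
        _finish_stage(stage, summary)
    return report


# --- stage implementations ----------------------------------------------

def _stage_simulate_phantom(config: PipelineConfig, state: dict) -> dict:
    spec = phantom_mod.PhantomSpec(**{"seed": config.seed, **config.phantom})
    pair = phantom_mod.make_phantom(spec)
    out = os.path.join(config.out_dir, "phantom")
    files = phantom_mod.write_phantom(pair, out)
    state["phantom_dir"] = out
    with open(files["ground_truth"]) as fh:
        sidecar = json.load(fh)
    return {"directory": "phantom", "icv_ml": sidecar["icv_ml"],
            "chp_volume_ml": sidecar["chp_volume_ml"]}


def _load_phantom(config: PipelineConfig, state: dict):
    if "phantom_pair" in state:
        return state["phantom_pair"]
    pdir = state.get("phantom_dir",
                     os.path.join(config.out_dir, "phantom"))
    try:
        pair = phantom_mod.read_phantom(pdir)
    except Exception as exc:
        raise RuntimeError(f"cannot read phantom inputs from {pdir!r}: {exc}")
    state["phantom_pair"] = pair
    return pair


def _stage_segment(config: PipelineConfig, state: dict) -> dict:
    pair = _load_phantom(config, state)
    params = seg_mod.SegParams(**{"seed": config.seed, **config.segmentation})
    seg = seg_mod.segment_chp(pair.t1w, pair.ventricle_mask, pair.voxel_dims,
                              pair.icv_ml, params)
    state["segmentation"] = seg
    seg_path = os.path.join(config.out_dir, "chp_segmentation.nii.gz")
    import nibabel as nib
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = pair.voxel_dims
    nib.save(nib.Nifti1Image(seg.mask.astype(np.uint8), aff), seg_path)
    summary = {
        "mask_file": "chp_segmentation.nii.gz",
        "volume_ml": seg.volume_ml,
        "normalized_volume": seg.normalized_volume,
        "stage1_means": seg.stage1_fit.means.tolist(),
        "stage2_means": (None if seg.stage2_fit is None
                         else seg.stage2_fit.means.tolist()),
        "brightness_thresh": seg.brightness_thresh,
        "params": dataclasses.asdict(params),
    }
    if pair.chp_truth_mask is not None:
        summary["dice_vs_truth"] = seg_mod.dice(seg.mask, pair.chp_truth_mask)
    _write_json(os.path.join(config.out_dir, "segmentation.json"), summary)
    return summary


def _stage_ratio(config: PipelineConfig, state: dict) -> dict:
    pair = _load_phantom(config, state)
    seg = state.get("segmentation")
    chp_mask = seg.mask if seg is not None else pair.chp_truth_mask
    res = ratio_mod.t1t2_ratio_workflow(pair.t1w, pair.t2w, chp_mask,
                                        pair.ref_masks)
    summary = {
        "mean_ratio": res.mean_ratio,
        "eroded_voxels": int(res.eroded_mask.sum()),
        "peaks_t1": res.peaks_t1,
        "peaks_t2": res.peaks_t2,
    }
    _write_json(os.path.join(config.out_dir, "ratio.json"), summary)
    return summary


def _stage_simulate_cohort(config: PipelineConfig, state: dict) -> dict:
    overrides = dict(config.cohort)
    for key in ("curve_params", "effects"):
        if key in overrides and isinstance(overrides[key], dict):
            cls = (cohort_mod.CurveParams if key == "curve_params"
                   else cohort_mod.EffectSpec)
            overrides[key] = cls(**overrides[key])
    spec = cohort_mod.CohortSpec(**{"seed": config.seed, **overrides})
    table = cohort_mod.sample_cohort(spec)
    out = os.path.join(config.out_dir, "cohort")
    cohort_mod.export_cohort(table, out)
    state["cohort"] = table
    base = table.baseline()
    return {
        "directory": "cohort",
        "n_subjects": table.n_subjects,
        "n_observations": int(len(table.data)),
        "mean_age": float(base["age"].mean()),
        "median_edss": float(base["edss"].median()),
    }


def _load_cohort(config: PipelineConfig, state: dict):
    if "cohort" in state:
        return state["cohort"]
    cdir = os.path.join(config.out_dir, "cohort")
    try:
        table = cohort_mod.read_cohort(cdir)
    except Exception as exc:
        raise RuntimeError(f"cannot read cohort from {cdir!r}: {exc}")
    state["cohort"] = table
    return table


def _stage_trajectory(config: PipelineConfig, state: dict) -> dict:
    table = _load_cohort(config, state)
    params = GraceParams(**{"seed": config.seed, **config.grace})
    summary = {}
    for outcome in config.trajectory_outcomes:
        res = GraceModel.from_dataframe(table.data, outcome,
                                        params=params).fit()
        payload = res.to_dict()
        _write_json(os.path.join(config.out_dir,
                                 f"trajectory_{outcome}.json"), payload)
        summary[outcome] = {
            "file": f"trajectory_{outcome}.json",
            "converged": payload["converged"],
            "turning_points": payload["turning_points"],
        }
    return summary


def _stage_associations(config: PipelineConfig, state: dict) -> dict:
    table = _load_cohort(config, state)
    cfg = stats_mod.AnalysisConfig(**config.analysis)
    results = stats_mod.run_associations(table.data, cfg)
    _write_json(os.path.join(config.out_dir, "associations.json"), results)
    nchpv_time = results.get("chp_time", {}).get("nchpv", [{}])[0]
    return {
        "file": "associations.json",
        "nchpv_time_beta": nchpv_time.get("beta_std"),
        "tables": [k for k in results if k != "config"],
    }


_STAGE_FUNCS = {
    "simulate_phantom": _stage_simulate_phantom,
    "segment": _stage_segment,
    "ratio": _stage_ratio,
    "simulate_cohort": _stage_simulate_cohort,
    "trajectory": _stage_trajectory,
    "associations": _stage_associations,
}
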