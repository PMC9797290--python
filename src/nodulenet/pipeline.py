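"""End-to-end orchestration: phantom cohort -> preprocessing -> anchor
clustering -> detector training -> candidate detection -> 3D false-positive
filtering -> FROC/CPM evaluation, with a JSON manifest per run.

Runs are seeded end to end: every stage's randomness derives from the single
config seed, so a rerun with the same config reproduces the manifest metrics
exactly for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, anchors as anchors_mod, detector as det_mod, evaluate as eval_mod
from . import fpfilter as fp_mod, phantom, preprocess as pre_mod
from .core import CTVolume, Detection, NoduleAnnotation
from .io import write_annotations, write_candidates, write_volume

__all__ = ["PipelineConfig", "run_pipeline", "report", "detections_to_candidates"]


@dataclass
class PhantomConfig:
    n_scans: int = 6
    shape: tuple[int, int, int] = (64, 128, 128)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_nodules: int = 2
    n_distractors: int = 3
    difficulty: float = 0.0


@dataclass
class PreprocessConfig:
    window: tuple[float, float] = pre_mod.HU_WINDOW
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    out_size: int = 128  # in-plane size of slice triplets (512 at full scale)


@dataclass
class FPFilterConfig:
    arch: str = "msm"  # msm | cnn1 | cnn2 | cnn3
    spec: str = "tiny"  # tiny | full
    n_folds: int = 2
    epochs: int = 6
    batch_size: int = 8
    n_train_pos: int = 12
    n_train_neg: int = 12


@dataclass
class PipelineConfig:
    """Schema-validated configuration for a full run."""

    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    anchor_k: int = 9
    detector: det_mod.DetectorConfig = field(default_factory=det_mod.DetectorConfig)
    fpfilter: FPFilterConfig = field(default_factory=FPFilterConfig)
    hit_radius_mm: Optional[float] = None  # None = nodule-radius criterion

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        kwargs: dict = {}
        sub = {
            "phantom": PhantomConfig,
            "preprocess": PreprocessConfig,
            "detector": det_mod.DetectorConfig,
            "fpfilter": FPFilterConfig,
        }
        for key, value in raw.items():
            if key in sub:
                fields = {f.name for f in dataclasses.fields(sub[key])}
                bad = set(value) - fields
                if bad:
                    raise ValueError(f"unknown config key(s) under {key}: {', '.join(sorted(bad))}")
                value = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
                }
                kwargs[key] = sub[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def detections_to_candidates(
    detections: list[Detection],
    volumes: dict[str, CTVolume],
    out_size: int,
) -> pd.DataFrame:
    """Map 2D slice detections back to world-coordinate candidates.

    Box centres are rescaled from triplet pixels to voxels, the slice index
    supplies z, and the volume metadata supplies the world transform.
    """
    rows = []
    for d in detections:
        vol = volumes[d.scan_id]
        nz, ny, nx = vol.voxels.shape
        cx_px = (d.box[0] + d.box[2]) / 2
        cy_px = (d.box[1] + d.box[3]) / 2
        vx = cx_px * nx / out_size
        vy = cy_px * ny / out_size
        wx, wy, wz = pre_mod.voxel_to_world((vx, vy, d.slice_index), vol)
        rows.append(
            {
                "seriesuid": d.scan_id,
                "coordX": wx,
                "coordY": wy,
                "coordZ": wz,
                "probability": d.score,
            }
        )
    return pd.DataFrame(
        rows, columns=["seriesuid", "coordX", "coordY", "coordZ", "probability"]
    )


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages in order; returns the manifest (also written).

    The run directory is append-only: each stage writes its own artifacts
    and never rewrites another stage's outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = asdict(config)
    manifest: dict = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "seed": config.seed,
        "versions": {"nodulenet": __version__, "numpy": np.__version__},
        "stages": {},
    }

    def _stage(name):
        manifest["stages"][name] = {"started": time.time()}
        return manifest["stages"][name]

    try:
        # ---- phantom cohort
        st = _stage("phantom")
        vols: dict[str, CTVolume] = {}
        all_ann: list[NoduleAnnotation] = []
        pc = config.phantom
        scan_dir = out / "scans"
        scan_dir.mkdir(exist_ok=True)
        for i in range(pc.n_scans):
            vol, ann = phantom.generate_volume(
                seed=config.seed * 1000 + i,
                shape=pc.shape,
                spacing=pc.spacing,
                n_nodules=pc.n_nodules,
                n_distractors=pc.n_distractors,
                difficulty=pc.difficulty,
            )
            vols[vol.scan_id] = vol
            all_ann.extend(ann)
            write_volume(vol, scan_dir / f"{vol.scan_id}.mhd")
        write_annotations(all_ann, out / "annotations.csv")
        st.update(n_scans=pc.n_scans, n_annotations=len(all_ann))

        # ---- preprocessing
        st = _stage("preprocess")
        prepped = {
            sid: pre_mod.preprocess_volume(
                v, config.preprocess.window, config.preprocess.target_spacing
            )
            for sid, v in vols.items()
        }
        st.update(n_volumes=len(prepped))

        # ---- anchors
        st = _stage("anchors")
        boxes = anchors_mod.boxes_from_annotations(all_ann)
        # the detector wants equal anchor counts per pyramid level, so k is
        # trimmed to a multiple of 3; tiny cohorts fall back to the preset
        k = min(config.anchor_k, len(boxes))
        k -= k % 3
        anchor_set = (
            anchors_mod.cluster_anchors(boxes, k=k, seed=config.seed) if k >= 3 else None
        )
        if anchor_set is not None:
            (out / "anchors.json").write_text(
                json.dumps(
                    {
                        "boxes": anchor_set.boxes,
                        "per_level": {str(k_): v for k_, v in anchor_set.per_level.items()},
                    },
                    indent=2,
                )
            )
        st.update(k=len(anchor_set.boxes) if anchor_set else 0)

        # ---- detector training + candidate detection
        st = _stage("detector")
        triplets = []
        ann_by_scan = {}
        for ann in all_ann:
            ann_by_scan.setdefault(ann.scan_id, []).append(ann)
        for sid, vol in prepped.items():
            triplets.extend(
                pre_mod.augment_2d(vol, ann_by_scan.get(sid, []), config.preprocess.out_size)
            )
        model, train_log = det_mod.train_detector(triplets, config.detector, anchor_set)
        det_mod.save_model(model, out / "detector.npz")
        detections = det_mod.detect(triplets, model)
        candidates = detections_to_candidates(detections, prepped, config.preprocess.out_size)
        write_candidates(candidates, out / "candidates.csv")
        st.update(
            n_triplets=len(triplets),
            n_detections=len(detections),
            final_loss=train_log[-1]["total"] if train_log else None,
        )

        # ---- false-positive filter
        st = _stage("fpfilter")
        fc = config.fpfilter
        spec = fp_mod.MSMSpec.tiny() if fc.spec == "tiny" else fp_mod.MSMSpec.full_scale()
        train_set = pre_mod.balance_samples(
            phantom.generate_multiscale_dataset(
                config.seed + 17, fc.n_train_pos, fc.n_train_neg,
                difficulty=pc.difficulty,
            ),
            seed=config.seed,
        )
        tcfg = fp_mod.TrainConfig(
            epochs=fc.epochs, batch_size=fc.batch_size, seed=config.seed
        )
        if fc.arch == "msm":
            clf = fp_mod.build_msm(spec, seed=config.seed)
        else:
            clf = fp_mod.SingleScaleCNN(int(fc.arch[-1]) - 1, spec, seed=config.seed)
        clf_log = fp_mod.train_classifier(clf, train_set, tcfg)
        scored = rescore_candidates(candidates, prepped, clf)
        write_candidates(scored, out / "candidates_scored.csv")
        st.update(train_accuracy=clf_log[-1]["accuracy"])

        # ---- evaluation
        st = _stage("evaluate")
        froc_res = eval_mod.froc(
            scored, all_ann, n_scans=pc.n_scans, hit_radius_mm=config.hit_radius_mm
        )
        match = eval_mod.match_detections(scored, all_ann, config.hit_radius_mm)
        breakdown = eval_mod.diameter_breakdown(match, all_ann)
        breakdown.to_csv(out / "diameter_breakdown.csv", index=False)
        eval_mod.plot_froc(froc_res, str(out / "froc.png"))
        metrics = {
            "cpm": froc_res.cpm,
            "rate_sensitivities": {str(k_): v for k_, v in froc_res.rate_sensitivities.items()},
            "n_candidates": int(len(scored)),
            "train_classifier_accuracy": clf_log[-1]["accuracy"],
        }
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
        st.update(**{"cpm": froc_res.cpm})
        manifest["metrics"] = metrics
    except Exception as exc:  # annotate which stage failed, then re-raise
        failed = [k for k, v in manifest["stages"].items() if "started" in v][-1:]
        raise RuntimeError(f"pipeline stage {failed[0] if failed else '?'} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def rescore_candidates(
    candidates: pd.DataFrame,
    volumes: dict[str, CTVolume],
    classifier,
) -> pd.DataFrame:
    """Replace candidate probabilities with the 3D classifier's scores."""
    from .core import MultiscaleCrop

    scored = candidates.copy()
    crops = []
    keep = []
    for i, row in candidates.iterrows():
        vol = volumes[str(row.seriesuid)]
        try:
            cubes = pre_mod.extract_multiscale_patches(
                vol, (row.coordX, row.coordY, row.coordZ)
            )
        except ValueError:
            continue
        crop64 = cubes[0][3:67, 3:67, 3:67]
        crop32 = cubes[1][2:34, 2:34, 2:34]
        crop16 = cubes[2][2:18, 2:18, 2:18]
        crops.append(MultiscaleCrop(cubes=(crop64, crop32, crop16), label=0))
        keep.append(i)
    if not crops:
        return scored
    probs = fp_mod.predict_proba(classifier, crops)[:, 1]
    scored.loc[keep, "probability"] = probs
    return scored


def report(run_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Regenerate the report tables of a completed run from its artifacts."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError("incomplete run: manifest.json missing")
    metrics = json.loads((run_dir / "metrics.json").read_text())
    froc_rows = [
        {"fp_per_scan": k, "sensitivity": v}
        for k, v in metrics["rate_sensitivities"].items()
    ]
    froc_rows.append({"fp_per_scan": "CPM", "sensitivity": metrics["cpm"]})
    tables = {
        "froc": pd.DataFrame(froc_rows),
        "diameter_breakdown": pd.read_csv(run_dir / "diameter_breakdown.csv"),
    }
    for name, df in tables.items():
        df.to_csv(run_dir / f"report_{name}.csv", index=False)
    return tables
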