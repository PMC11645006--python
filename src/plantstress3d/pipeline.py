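"""End-to-end orchestration: recognition -> leaf detection -> depth ->
3D reconstruction -> stress classification."""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import (
    StressModel,
    build_feature_vector,
    classify_stress,
    train_stress_dnn,
)
from .depth import DepthModel, infer_depth, train_depth_net, build_depth_pairs
from .evaluation import ConfusionCounts, basic_metrics
from .geometry import CameraModel, reconstruct_leaf
from .leaves import classify_superpixels, compute_superpixels
from .segmentation import (
    SegmenterModel,
    extract_training_patches,
    segment_image,
    train_segmenter,
)

__all__ = [
    "PipelineConfig",
    "PipelineModels",
    "PipelineResult",
    "run_pipeline",
    "sweep_superpixel_count",
    "train_models_from_scenes",
]


@dataclass
class PipelineConfig:
    patch_size: int = 32
    seg_stride: int = 1
    depth_stride: int = 1
    n_superpixels: int = 999
    slic_iterations: int = 9
    slic_smoothing: float = 5.0
    camera: CameraModel = field(default_factory=CameraModel)
    feature_mode: str = "heights"
    pad_value: float = 0.0
    segmenter_path: str | None = None
    depth_model_path: str | None = None
    stress_model_path: str | None = None
    seeds: dict = field(default_factory=lambda: {"seg": 0, "depth": 1, "stress": 2})

    @classmethod
    def from_dict(cls, data):
        data = dict(data)
        if "camera" in data and not isinstance(data["camera"], CameraModel):
            cam = dict(data["camera"])
            for key in ("principal_point", "image_size"):
                if key in cam:
                    cam[key] = tuple(cam[key])
            data["camera"] = CameraModel(**cam)
        return cls(**data)


@dataclass
class PipelineModels:
    segmenter: SegmenterModel
    depth: DepthModel
    stress: StressModel

    @classmethod
    def load(cls, config: PipelineConfig):
        stages = [
            ("segmentation", config.segmenter_path, SegmenterModel),
            ("depth", config.depth_model_path, DepthModel),
            ("stress", config.stress_model_path, StressModel),
        ]
        loaded = []
        for stage, path, model_cls in stages:
            if path is None or not Path(path).exists():
                raise FileNotFoundError(
                    f"missing checkpoint for the {stage} stage: {path!r}"
                )
            loaded.append(model_cls.load(path))
        return cls(*loaded)


@dataclass
class PipelineResult:
    mask: object
    regions: object
    depth_map: object
    leaves: list
    label: int
    score: float
    report: dict


def run_pipeline(image, models: PipelineModels, config: PipelineConfig = None):
    """Run all stages on one RGB image and return every intermediate."""
    config = config or PipelineConfig()
    image = np.asarray(image)
    report = {"stages": {}, "config": {k: v for k, v in asdict(config).items() if k != "camera"}}

    t0 = time.perf_counter()
    mask = segment_image(models.segmenter, image, stride=config.seg_stride)
    report["stages"]["recognition"] = {
        "plant_pixels": int(mask.labels.sum()),
        "stride": config.seg_stride,
        "seconds": round(time.perf_counter() - t0, 4),
    }

    t0 = time.perf_counter()
    spmap = compute_superpixels(
        image,
        n_desired=config.n_superpixels,
        iterations=config.slic_iterations,
        smoothing=config.slic_smoothing,
    )
    regions = classify_superpixels(spmap, mask)
    report["stages"]["leaf_detection"] = {
        "superpixels": int(spmap.n_actual),
        "kept": int(len(regions.kept_ids)),
        "seconds": round(time.perf_counter() - t0, 4),
    }

    t0 = time.perf_counter()
    depth_map = infer_depth(models.depth, image, stride=config.depth_stride)
    report["stages"]["depth"] = {
        "stride": config.depth_stride,
        "seconds": round(time.perf_counter() - t0, 4),
    }

    t0 = time.perf_counter()
    leaves = []
    for sp_id in regions.kept_ids:
        leaves.append(
            reconstruct_leaf(
                regions.region_pixels(sp_id),
                depth_map.codes,
                config.camera,
                superpixel_id=int(sp_id),
            )
        )
    report["stages"]["reconstruction"] = {
        "leaves": len(leaves),
        "points": int(sum(leaf.w for leaf in leaves)),
        "seconds": round(time.perf_counter() - t0, 4),
    }

    feature = build_feature_vector(
        leaves, mode=config.feature_mode, pad_value=config.pad_value
    )
    label, score = classify_stress(models.stress, feature)
    report["stages"]["classification"] = {
        "label": label,
        "score": round(score, 6),
        "n_leaves_used": feature.n_leaves,
    }
    if not leaves:
        report["flags"] = ["no foliage: prediction made on a fully padded vector"]
    return PipelineResult(
        mask=mask,
        regions=regions,
        depth_map=depth_map,
        leaves=leaves,
        label=label,
        score=score,
        report=report,
    )


def train_models_from_scenes(
    scenes,
    *,
    seg_seed=0,
    depth_seed=1,
    stress_seed=2,
    patch_stride=16,
    seg_epochs=5,
    depth_epochs=10,
    stress_epochs=60,
    camera: CameraModel = None,
    variant="reduced",
    feature_source="ground_truth",
    pipeline_config: PipelineConfig = None,
):
    """Train all three models from a list of synthetic scenes.

    Segmentation and depth patches are tiled from the scenes. The stress
    DNN is trained on height vectors built either from each scene's
    ground-truth leaf geometry (instance map + depth codes,
    ``feature_source="ground_truth"``) or from the same
    segmentation/superpixel/depth stages the pipeline applies at inference
    time (``feature_source="pipeline"``), which keeps the training and
    inference feature distributions consistent.
    """
    if feature_source not in ("ground_truth", "pipeline"):
        raise ValueError(f"unknown feature source {feature_source!r}")
    camera = camera or CameraModel()
    seg_x, seg_y = extract_training_patches(
        [(s.rgb, s.plant_mask) for s in scenes], stride=patch_stride
    )
    segmenter = train_segmenter(seg_x, seg_y, seg_seed, variant=variant, epochs=seg_epochs)

    dx, dy = [], []
    for s in scenes:
        px, py = build_depth_pairs(s.rgb, s.depth, stride=patch_stride)
        dx.append(px)
        dy.append(py)
    depth_model = train_depth_net(
        np.concatenate(dx), np.concatenate(dy), depth_seed,
        variant=variant, epochs=depth_epochs,
    )

    feats, labels = [], []
    if feature_source == "pipeline":
        cfg = pipeline_config or PipelineConfig(camera=camera)
        for s in scenes:
            mask = segment_image(segmenter, s.rgb, stride=cfg.seg_stride)
            spmap = compute_superpixels(
                s.rgb, cfg.n_superpixels, cfg.slic_iterations, cfg.slic_smoothing
            )
            regions = classify_superpixels(spmap, mask)
            dmap = infer_depth(depth_model, s.rgb, stride=cfg.depth_stride)
            leaves = [
                reconstruct_leaf(
                    regions.region_pixels(sp_id), dmap.codes, cfg.camera,
                    superpixel_id=int(sp_id),
                )
                for sp_id in regions.kept_ids
            ]
            feats.append(
                build_feature_vector(
                    leaves, mode=cfg.feature_mode, pad_value=cfg.pad_value
                ).values
            )
            labels.append(s.stress_label)
    else:
        for s in scenes:
            leaves = []
            for leaf_id in np.unique(s.leaf_instances):
                if leaf_id == 0:
                    continue
                leaves.append(
                    reconstruct_leaf(
                        s.leaf_instances == leaf_id, s.depth, camera,
                        superpixel_id=int(leaf_id),
                    )
                )
            feats.append(build_feature_vector(leaves).values)
            labels.append(s.stress_label)
    stress = train_stress_dnn(
        np.array(feats), np.array(labels), stress_seed, epochs=stress_epochs
    )
    return PipelineModels(segmenter=segmenter, depth=depth_model, stress=stress)


def sweep_superpixel_count(
    scenes, models: PipelineModels, config: PipelineConfig = None,
    counts=(800, 900, 999, 1100, 1200),
):
    """End-to-end stress-classification metrics per desired superpixel count.

    Returns a DataFrame with one row per count (precision, recall, F1,
    accuracy over the scenes' stress labels).
    """
    if not counts:
        raise ValueError("counts must be non-empty")
    config = config or PipelineConfig()
    rows = []
    for count in counts:
        cfg = PipelineConfig(**{**asdict_config(config), "n_superpixels": int(count)})
        preds, truths = [], []
        for scene in scenes:
            result = run_pipeline(scene.rgb, models, cfg)
            preds.append(result.label)
            truths.append(scene.stress_label)
        bundle = basic_metrics(ConfusionCounts.from_labels(preds, truths))
        rows.append(
            {
                "n_superpixels": int(count),
                "precision": bundle.precision,
                "recall": bundle.recall,
                "f_score": bundle.f_score,
                "accuracy": bundle.accuracy,
            }
        )
    return pd.DataFrame(rows)


def asdict_config(config: PipelineConfig):
    d = asdict(config)
    d["camera"] = config.camera  # keep the dataclass, not a dict
    return d
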