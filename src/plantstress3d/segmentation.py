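"""Patch-based semantic segmentation of plant vs. no-plant pixels.

A CNN classifies a 32x32 RGB section into one of two labels (plant = 1,
no-plant = 0) and is swept over the image as a sliding window; each
window's prediction is painted onto its central pixel. Training patches
are tiled from labelled images and take the ground-truth class of their
central pixel (or a majority vote, selectable).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .nn import Sequential, build_patch_cnn, fit, softmax_ce_loss
from .windows import (
    PATCH_SIZE,
    fill_from_grid,
    iter_window_batches,
    window_centers,
)

__all__ = [
    "PLANT",
    "NO_PLANT",
    "SegmentationMask",
    "SegmenterModel",
    "extract_training_patches",
    "mask_to_rgb",
    "save_training_log",
    "segment_image",
    "train_segmenter",
]

PLANT = 1  # label v1
NO_PLANT = 0  # label v2


@dataclass
class SegmentationMask:
    labels: np.ndarray  # H x W uint8, 1 = plant
    scores: np.ndarray  # H x W plant probability in [0, 1]
    patch_size: int = PATCH_SIZE
    stride: int = 1

    def __post_init__(self):
        if self.labels.shape != self.scores.shape:
            raise ValueError("labels and scores must share H x W")


def mask_to_rgb(mask: SegmentationMask):
    """Visualisation: plant pixels green, no-plant pixels black."""
    out = np.zeros(mask.labels.shape + (3,), dtype=np.uint8)
    out[mask.labels == PLANT] = (0, 255, 0)
    return out


def extract_training_patches(
    scene_images, patch_size=PATCH_SIZE, stride=PATCH_SIZE, label_rule="center"
):
    """Tile (image, plant_mask) pairs into labelled 32x32 patches.

    Yields ``floor((H - p) / stride) + 1  x  floor((W - p) / stride) + 1``
    patches per image. Returns (patches, labels) with patches scaled to
    [0, 1] float and labels in {0, 1}.
    """
    if label_rule not in ("center", "majority"):
        raise ValueError(f"unknown label rule {label_rule!r}")
    patches, labels = [], []
    for image, mask in scene_images:
        image = np.asarray(image)
        mask = np.asarray(mask)
        h, w = mask.shape
        if image.shape[:2] != (h, w):
            raise ValueError("image and mask must share H x W")
        if h < patch_size or w < patch_size:
            raise ValueError(f"image {h}x{w} smaller than the patch size")
        half = patch_size // 2
        for r in range(0, h - patch_size + 1, stride):
            for c in range(0, w - patch_size + 1, stride):
                win = image[r : r + patch_size, c : c + patch_size]
                sub = mask[r : r + patch_size, c : c + patch_size]
                if label_rule == "center":
                    lab = int(sub[half, half] > 0)
                else:
                    lab = int((sub > 0).mean() > 0.5)
                patches.append(win.astype(float) / 255.0)
                labels.append(lab)
    return np.array(patches), np.array(labels, dtype=int)


@dataclass
class SegmenterModel:
    net: Sequential
    meta: dict = field(default_factory=dict)
    history: list = field(default_factory=list)

    def predict_scores(self, patches):
        """Plant probability for a batch of (n, 32, 32, 3) patches."""
        logits = self.net.forward(np.asarray(patches, dtype=float))
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez[:, PLANT] / ez.sum(axis=1)

    def predict_labels(self, patches):
        return (self.predict_scores(patches) > 0.5).astype(np.uint8)

    def save(self, path):
        self.net.save(path, metadata=self.meta)

    @classmethod
    def load(cls, path):
        net, meta = Sequential.load(path)
        return cls(net=net, meta=meta)


def train_segmenter(
    patches,
    labels,
    seed,
    *,
    variant="reduced",
    epochs=6,
    batch_size=64,
    lr=1e-3,
    betas=(0.9, 0.999),
):
    """Train the patch classifier with Adam on softmax cross-entropy."""
    patches = np.asarray(patches, dtype=float)
    labels = np.asarray(labels, dtype=int)
    present = set(np.unique(labels))
    for cls_id, name in ((PLANT, "plant"), (NO_PLANT, "no-plant")):
        if cls_id not in present:
            raise ValueError(f"training set has no {name!r} (label {cls_id}) patches")
    rng = np.random.default_rng(seed)
    net = build_patch_cnn(variant=variant, n_out=2, rng=rng)
    history = fit(
        net,
        patches,
        labels,
        softmax_ce_loss,
        epochs=epochs,
        batch_size=batch_size,
        lr=lr,
        betas=betas,
        rng=rng,
        accuracy_fn=lambda logits, y: (logits.argmax(axis=1) == y).mean(),
    )
    meta = {
        "task": "segmentation",
        "variant": variant,
        "seed": int(seed),
        "epochs": epochs,
        "lr": lr,
        "batch_size": batch_size,
    }
    return SegmenterModel(net=net, meta=meta, history=history)


def segment_image(model: SegmenterModel, image, stride=1, batch_windows=4096):
    """Dense sliding-window segmentation of an RGB image.

    The window grid is evaluated in batches (mathematically identical to
    per-window evaluation); off-grid pixels take the label of the nearest
    evaluated window center.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    rows, cols = window_centers(image.shape, PATCH_SIZE, stride)
    scaled = image.astype(float) / 255.0
    grid = np.empty((len(rows), len(cols)))
    for rsl, batch in iter_window_batches(scaled, PATCH_SIZE, stride, batch_windows):
        scores = model.predict_scores(batch)
        grid[rsl] = scores.reshape(-1, len(cols))
    score_map = fill_from_grid(grid, image.shape, PATCH_SIZE, stride)
    return SegmentationMask(
        labels=(score_map > 0.5).astype(np.uint8),
        scores=score_map,
        stride=stride,
    )


def save_training_log(history, path):
    """Write the per-epoch training history as CSV."""
    fields = sorted({k for row in history for k in row})
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        writer.writerows(history)
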