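"""Monocular depth-code inference from 32x32 RGB patches.

Each training pair maps an RGB section to the arithmetic mean of the 8-bit
depth codes under it; the regressor (same backbone template as the
segmenter, scalar head) is trained on targets scaled to [0, 1] with squared
error, then swept over an image to produce a dense depth-code map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from PIL import Image

from .nn import Sequential, build_patch_cnn, fit, mse_loss
from .windows import (
    PATCH_SIZE,
    fill_from_grid,
    iter_window_batches,
    window_centers,
)

__all__ = [
    "DepthMap",
    "DepthModel",
    "build_depth_pairs",
    "fraction_in_band",
    "infer_depth",
    "train_depth_net",
    "write_depth_map",
]


@dataclass
class DepthMap:
    codes: np.ndarray  # H x W, values in [0, 255]
    code_convention: str = "distance-bright"  # z grows with distance

    def __post_init__(self):
        codes = np.asarray(self.codes, dtype=float)
        if np.any(codes < 0) or np.any(codes > 255):
            raise ValueError("depth codes must lie in [0, 255]")
        self.codes = codes


def build_depth_pairs(rgb, depth, patch_size=PATCH_SIZE, stride=PATCH_SIZE):
    """Tile an RGB/depth pair into (patch, mean window depth code) pairs."""
    rgb = np.asarray(rgb)
    depth = np.asarray(depth, dtype=float)
    if rgb.shape[:2] != depth.shape:
        raise ValueError("RGB image and depth map must share H x W")
    h, w = depth.shape
    if h < patch_size or w < patch_size:
        raise ValueError(f"image {h}x{w} smaller than the patch size")
    view = sliding_window_view(rgb, (patch_size, patch_size), axis=(0, 1))
    dview = sliding_window_view(depth, (patch_size, patch_size), axis=(0, 1))
    sub = view[::stride, ::stride]
    targets = dview[::stride, ::stride].mean(axis=(-2, -1)).reshape(-1)
    patches = (
        np.ascontiguousarray(sub.transpose(0, 1, 3, 4, 2)).reshape(
            -1, patch_size, patch_size, rgb.shape[2]
        )
        .astype(float)
        / 255.0
    )
    return patches, targets


@dataclass
class DepthModel:
    net: Sequential
    meta: dict = field(default_factory=dict)
    history: list = field(default_factory=list)

    def predict_codes(self, patches):
        """Predicted depth codes, clipped to [0, 255]."""
        out = self.net.forward(np.asarray(patches, dtype=float))[:, 0]
        scale = self.meta.get("target_scale", 255.0)
        offset = self.meta.get("target_offset", 0.0)
        return np.clip(out * scale + offset, 0.0, 255.0)

    def save(self, path):
        self.net.save(path, metadata=self.meta)

    @classmethod
    def load(cls, path):
        net, meta = Sequential.load(path)
        return cls(net=net, meta=meta)


def train_depth_net(
    patches,
    targets,
    seed,
    *,
    variant="reduced",
    epochs=8,
    batch_size=64,
    lr=1e-3,
    betas=(0.9, 0.999),
):
    """Seeded regression training on mean-window depth codes.

    Targets are standardised (zero mean, unit variance) for training —
    depth codes often occupy a narrow slice of the 0-255 range, and the
    squared-error problem is far better conditioned on the standardised
    scale. Predictions are mapped back to codes and clipped to [0, 255].
    """
    patches = np.asarray(patches, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if len(patches) == 0:
        raise ValueError("empty training set")
    if len(np.unique(targets)) < 2:
        raise ValueError("need at least two distinct depth targets")
    offset = float(targets.mean())
    scale = float(targets.std())
    rng = np.random.default_rng(seed)
    net = build_patch_cnn(variant=variant, n_out=1, rng=rng)
    history = fit(
        net,
        patches,
        ((targets - offset) / scale).reshape(-1, 1),
        mse_loss,
        epochs=epochs,
        batch_size=batch_size,
        lr=lr,
        betas=betas,
        rng=rng,
    )
    meta = {
        "task": "depth",
        "variant": variant,
        "seed": int(seed),
        "epochs": epochs,
        "lr": lr,
        "batch_size": batch_size,
        "target_offset": offset,
        "target_scale": scale,
    }
    return DepthModel(net=net, meta=meta, history=history)


def infer_depth(model: DepthModel, image, stride=1, batch_windows=4096):
    """Dense depth-code map from a single RGB image.

    Per-pixel code is the model output at the window centered there;
    borders and stride-skipped pixels follow the nearest-center fill rule.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    rows, cols = window_centers(image.shape, PATCH_SIZE, stride)
    scaled = image.astype(float) / 255.0
    grid = np.empty((len(rows), len(cols)))
    for rsl, batch in iter_window_batches(scaled, PATCH_SIZE, stride, batch_windows):
        grid[rsl] = model.predict_codes(batch).reshape(-1, len(cols))
    codes = fill_from_grid(grid, image.shape, PATCH_SIZE, stride)
    return DepthMap(codes=codes)


def fraction_in_band(depth_map: DepthMap, max_depth, band=(0.75, 0.80)):
    """Fraction of pixels whose decoded depth falls in a metric band.

    Intended as a sanity check (e.g. stressed foliage sitting 75-80 cm from
    the camera), not a hard constraint.
    """
    Z = max_depth * np.asarray(depth_map.codes, dtype=float) / 255.0
    lo, hi = band
    return float(((Z >= lo) & (Z <= hi)).mean())


def write_depth_map(depth_map: DepthMap, png_path, sidecar_path=None):
    """Rounded 8-bit PNG plus an optional lossless float sidecar (NPZ)."""
    arr = np.clip(np.rint(depth_map.codes), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(png_path)
    if sidecar_path is not None:
        np.savez_compressed(
            Path(sidecar_path),
            codes=depth_map.codes,
            code_convention=depth_map.code_convention,
        )
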