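"""Leaf detection: SLIC superpixels gated by segmentation purity.

The image is partitioned into superpixels (defaults: 999 desired
superpixels, 9 pixel-level iterations, shape smoothing 5) and a superpixel
is kept as a leaf region exactly when *all* of its pixels carry the plant
label — one impure pixel discards it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from skimage.segmentation import slic

__all__ = [
    "LeafRegionSet",
    "SuperpixelMap",
    "classify_superpixels",
    "compute_superpixels",
    "kept_regions_to_json",
    "write_superpixel_png",
]


@dataclass
class SuperpixelMap:
    assignment: np.ndarray  # H x W integer ids, 0-based
    n_desired: int
    iterations: int
    smoothing: float
    ids: np.ndarray = field(init=False)
    pixel_counts: np.ndarray = field(init=False)  # phi_i, indexed by id

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment)
        self.ids = np.unique(self.assignment)
        self.pixel_counts = np.bincount(
            self.assignment.ravel(), minlength=self.ids.max() + 1
        )

    @property
    def n_actual(self) -> int:
        return len(self.ids)


def compute_superpixels(image, n_desired=999, iterations=9, smoothing=5.0):
    """SLIC partition (CIELAB space); parameters are recorded on the map.

    The actual superpixel count may differ from ``n_desired``; SLIC only
    treats it as a target.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if n_desired < 1:
        raise ValueError("n_desired must be >= 1")
    assignment = slic(
        image,
        n_segments=n_desired,
        compactness=smoothing,
        max_num_iter=iterations,
        start_label=0,
    )
    return SuperpixelMap(
        assignment=assignment,
        n_desired=n_desired,
        iterations=iterations,
        smoothing=smoothing,
    )


@dataclass
class LeafRegionSet:
    spmap: SuperpixelMap
    plant_counts: np.ndarray  # gamma_i, indexed by id
    keep: np.ndarray  # theta_i in {0, 1}, indexed by id

    @property
    def kept_ids(self):
        return np.nonzero(self.keep)[0]

    def kept_mask(self):
        """Boolean H x W union of all kept superpixels."""
        return self.keep[self.spmap.assignment].astype(bool)

    def region_pixels(self, superpixel_id):
        """(n, 2) array of (row, col) indices of one superpixel."""
        rows, cols = np.nonzero(self.spmap.assignment == superpixel_id)
        return np.column_stack([rows, cols])


def classify_superpixels(spmap: SuperpixelMap, mask) -> LeafRegionSet:
    """Keep superpixels made entirely of plant pixels (phi_i == gamma_i)."""
    labels = getattr(mask, "labels", mask)
    labels = np.asarray(labels)
    if labels.shape != spmap.assignment.shape:
        raise ValueError("superpixel map and mask must share H x W")
    minlength = len(spmap.pixel_counts)
    gamma = np.bincount(
        spmap.assignment.ravel(),
        weights=(labels.ravel() > 0).astype(float),
        minlength=minlength,
    ).astype(int)
    keep = (spmap.pixel_counts > 0) & (gamma == spmap.pixel_counts)
    return LeafRegionSet(spmap=spmap, plant_counts=gamma, keep=keep.astype(np.uint8))


def write_superpixel_png(spmap: SuperpixelMap, path):
    """Superpixel ids as a 16-bit single-channel PNG."""
    arr = spmap.assignment.astype(np.uint16)
    Image.fromarray(arr).save(path)


def kept_regions_to_json(regions: LeafRegionSet, path=None):
    """Run-length encode kept regions (per row: col start/length pairs)."""
    payload = {}
    assignment = regions.spmap.assignment
    for sp_id in regions.kept_ids:
        runs = []
        mask = assignment == sp_id
        for row in np.nonzero(mask.any(axis=1))[0]:
            cols = np.nonzero(mask[row])[0]
            breaks = np.nonzero(np.diff(cols) > 1)[0]
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks, [len(cols) - 1]])
            for s, e in zip(starts, ends):
                runs.append([int(row), int(cols[s]), int(e - s + 1)])
        payload[str(int(sp_id))] = runs
    text = json.dumps(payload)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return payload
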