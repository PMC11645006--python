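"""Sliding-window bookkeeping shared by the patch segmenter and the depth
regressor.

A window of ``patch_size`` is evaluated at every grid position whose full
window fits in the image; the prediction is assigned to the window's
*center* pixel. Pixels without their own evaluated window (the border band
of ``patch_size // 2`` pixels, plus interior pixels skipped by a stride
greater than one) receive the value of the nearest evaluated center.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

PATCH_SIZE = 32


def window_centers(image_shape, patch_size=PATCH_SIZE, stride=1):
    """Center coordinates (rows, cols arrays) of all evaluable windows."""
    h, w = image_shape[:2]
    if h < patch_size or w < patch_size:
        raise ValueError(
            f"image {h}x{w} is smaller than the {patch_size}-pixel window"
        )
    if stride < 1:
        raise ValueError("stride must be >= 1")
    half = patch_size // 2
    rows = np.arange(half, h - patch_size + half + 1, stride)
    cols = np.arange(half, w - patch_size + half + 1, stride)
    return rows, cols


def n_windows(image_shape, patch_size=PATCH_SIZE, stride=1):
    rows, cols = window_centers(image_shape, patch_size, stride)
    return len(rows) * len(cols)


def iter_window_batches(image, patch_size=PATCH_SIZE, stride=1, batch_windows=4096):
    """Yield (row_slice, batch) pairs of contiguous window batches.

    ``image`` is H x W x C with values already scaled for the model; each
    batch is (n, patch, patch, C) covering whole grid rows.
    """
    rows, cols = window_centers(image.shape, patch_size, stride)
    view = sliding_window_view(image, (patch_size, patch_size), axis=(0, 1))
    sub = view[::stride, ::stride]  # (nr, nc, C, p, p)
    nr, nc = len(rows), len(cols)
    rows_per_batch = max(1, batch_windows // max(nc, 1))
    for r0 in range(0, nr, rows_per_batch):
        block = sub[r0 : r0 + rows_per_batch]
        x = np.ascontiguousarray(block.transpose(0, 1, 3, 4, 2)).reshape(
            -1, patch_size, patch_size, image.shape[2]
        )
        yield slice(r0, r0 + block.shape[0]), x


def fill_from_grid(grid, image_shape, patch_size=PATCH_SIZE, stride=1):
    """Expand per-center grid values to a full H x W map.

    Every pixel takes the value of the nearest evaluated window center
    (its own center when one exists, i.e. interior pixels at stride 1).
    """
    h, w = image_shape[:2]
    rows, cols = window_centers(image_shape, patch_size, stride)
    half = patch_size // 2
    ri = np.clip(np.rint((np.arange(h) - half) / stride).astype(int), 0, len(rows) - 1)
    ci = np.clip(np.rint((np.arange(w) - half) / stride).astype(int), 0, len(cols) - 1)
    return grid[np.ix_(ri, ci)]
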