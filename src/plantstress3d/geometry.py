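"""Metric 3D reconstruction of leaf regions from depth codes.

Depth codes are 8-bit gray values z in [0, 255] encoding camera-to-surface
distance; ``Z = k * z / 255`` with sensor range ``k`` converts them to
meters. Pixels are back-projected through a pinhole camera
(``X = x * Z / f``, ``Y = y * Z / f`` with image-plane coordinates taken
relative to the principal point), and each leaf region becomes a point
cloud summarised by its order-0/1 moments and centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CameraModel",
    "Leaf3D",
    "RMSResult",
    "back_project",
    "code_to_depth",
    "depth_to_code",
    "forward_project",
    "leaf_centroid",
    "leaf_moments",
    "pixel_to_image_plane",
    "reconstruct_leaf",
    "rms_error",
    "write_centroids_csv",
    "write_ply",
]


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera: focal length in pixels, principal point in (row, col)
    pixel coordinates, and the sensor's maximum depth ``k`` in meters."""

    focal_length: float = 525.0
    principal_point: tuple[float, float] = (239.5, 319.5)
    max_depth: float = 4.0
    image_size: tuple[int, int] = (480, 640)

    def __post_init__(self):
        if self.focal_length <= 0:
            raise ValueError("focal_length must be > 0")
        if self.max_depth <= 0:
            raise ValueError("max_depth must be > 0")
        h, w = self.image_size
        r, c = self.principal_point
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError("principal point must lie inside the image")


def code_to_depth(z, k):
    """Convert gray code(s) z in [0, 255] to metric depth Z = k * z / 255."""
    z = np.asarray(z, dtype=float)
    if k <= 0:
        raise ValueError("max depth k must be > 0")
    if np.any(z < 0) or np.any(z > 255):
        raise ValueError("depth codes must lie in [0, 255]")
    out = k * z / 255.0
    return float(out) if out.ndim == 0 else out

def depth_to_code(Z, k):
    """Inverse of :func:`code_to_depth`: nearest 8-bit code for depth Z."""
    Z = np.asarray(Z, dtype=float)
    if k <= 0:
        raise ValueError("max depth k must be > 0")
    code = np.clip(np.rint(255.0 * Z / k), 0, 255).astype(np.uint8)
    return int(code) if code.ndim == 0 else code


def back_project(x, y, Z, cam: CameraModel):
    """Image-plane (x, y) at metric depth Z -> 3D point (X, Y, Z)."""
    f = cam.focal_length
    if f <= 0:
        raise ValueError("focal length must be > 0")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    return x * Z / f, y * Z / f, Z + 0.0


def forward_project(X, Y, Z, cam: CameraModel):
    """Pinhole projection of a 3D point to image-plane coordinates."""
    if np.any(np.asarray(Z) <= 0):
        raise ValueError("cannot project points at Z <= 0")
    f = cam.focal_length
    return f * np.asarray(X, dtype=float) / Z, f * np.asarray(Y, dtype=float) / Z


def pixel_to_image_plane(rows, cols, cam: CameraModel):
    """0-based pixel indices -> image-plane (x, y) relative to the principal
    point; x grows rightward (columns), y downward (rows)."""
    r0, c0 = cam.principal_point
    return np.asarray(cols, dtype=float) - c0, np.asarray(rows, dtype=float) - r0


@dataclass
class Leaf3D:
    """Point cloud of one reconstructed leaf region."""

    points: np.ndarray  # (w, 3) meters
    superpixel_id: int = -1
    centroid: np.ndarray = field(init=False)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) == 0:
            raise ValueError("a leaf needs at least one point")
        self.centroid = leaf_centroid(self.points)

    @property
    def w(self) -> int:
        """Number of pixel projections in the leaf."""
        return len(self.points)

    def moment(self, p, q, g):
        return leaf_moments(self.points, p, q, g)


def leaf_moments(points, p, q, g):
    """Order-(p, q, g) moment: sum over points of X^p * Y^q * Z^g.

    Only orders 0 and 1 are supported; the zeroth moment equals the point
    count and first/zeroth ratios give the centroid.
    """
    for name, order in (("p", p), ("q", q), ("g", g)):
        if order not in (0, 1):
            raise ValueError(f"moment order {name}={order} not in {{0, 1}}")
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("moments of an empty point set are undefined")
    X, Y, Z = pts[:, 0], pts[:, 1], pts[:, 2]
    return float(np.sum(X**p * Y**q * Z**g))


def leaf_centroid(points):
    """Centroid = first-order moments over the zeroth moment (per axis)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    m000 = leaf_moments(pts, 0, 0, 0)
    return np.array(
        [
            leaf_moments(pts, 1, 0, 0) / m000,
            leaf_moments(pts, 0, 1, 0) / m000,
            leaf_moments(pts, 0, 0, 1) / m000,
        ]
    )


def reconstruct_leaf(region, depth_codes, cam: CameraModel, superpixel_id=-1):
    """Back-project every pixel of a leaf region into a metric point cloud.

    ``region`` is either a boolean mask over the depth map or an (n, 2)
    array of (row, col) indices. ``depth_codes`` is an H x W array of gray
    codes in [0, 255].
    """
    depth_codes = np.asarray(depth_codes)
    region = np.asarray(region)
    if region.dtype == bool:
        if region.shape != depth_codes.shape:
            raise ValueError("mask and depth map shapes differ")
        rows, cols = np.nonzero(region)
    else:
        idx = region.reshape(-1, 2)
        rows, cols = idx[:, 0], idx[:, 1]
    if len(rows) == 0:
        raise ValueError("empty leaf region")
    h, w = depth_codes.shape
    if rows.min() < 0 or rows.max() >= h or cols.min() < 0 or cols.max() >= w:
        raise ValueError("region indices fall outside the depth map")
    Z = code_to_depth(depth_codes[rows, cols], cam.max_depth)
    x, y = pixel_to_image_plane(rows, cols, cam)
    X, Y, Z = back_project(x, y, Z, cam)
    return Leaf3D(np.column_stack([X, Y, Z]), superpixel_id=superpixel_id)


@dataclass
class RMSResult:
    per_axis: np.ndarray  # RMS over matched pairs, one value per (X, Y, Z)
    average: float  # arithmetic mean of the three per-axis values
    n_matched: int
    n_unmatched: int = 0


def rms_error(pred_centroids, gt_centroids, matching="index", gate=None):
    """Per-axis root-mean-square centroid error plus their average.

    ``matching='index'`` pairs centroids positionally (arrays must have the
    same length); ``matching='nearest'`` greedily pairs each prediction to
    the closest unused ground-truth centroid in the (X, Y) plane, skipping
    pairs farther apart than ``gate`` (meters) when a gate is given.
    """
    pred = np.asarray(pred_centroids, dtype=float).reshape(-1, 3)
    gt = np.asarray(gt_centroids, dtype=float).reshape(-1, 3)
    if matching == "index":
        if len(pred) != len(gt):
            raise ValueError("index matching needs equal-length centroid lists")
        pairs = list(zip(range(len(pred)), range(len(gt))))
        unmatched = 0
    elif matching == "nearest":
        pairs, used = [], set()
        # visit predictions in a deterministic order
        for i in range(len(pred)):
            d = np.linalg.norm(gt[:, :2] - pred[i, :2], axis=1)
            for j in np.argsort(d, kind="stable"):
                if j in used:
                    continue
                if gate is not None and d[j] > gate:
                    break
                pairs.append((i, int(j)))
                used.add(int(j))
                break
        unmatched = len(pred) - len(pairs) + len(gt) - len(pairs)
    else:
        raise ValueError(f"unknown matching rule {matching!r}")
    if not pairs:
        raise ValueError("no matched centroid pairs")
    pi = np.array([a for a, _ in pairs])
    gi = np.array([b for _, b in pairs])
    diff = gt[gi] - pred[pi]
    per_axis = np.sqrt((diff**2).mean(axis=0))
    return RMSResult(per_axis, float(per_axis.mean()), len(pairs), unmatched)


def write_ply(path, leaves):
    """ASCII PLY export; vertices carry their leaf id as a property."""
    leaves = list(leaves)
    total = sum(leaf.w for leaf in leaves)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {total}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property int leaf_id\nend_header\n")
        for leaf in leaves:
            for X, Y, Z in leaf.points:
                fh.write(f"{X:.6f} {Y:.6f} {Z:.6f} {leaf.superpixel_id}\n")


def write_centroids_csv(path, leaves):
    with open(path, "w") as fh:
        fh.write("leaf_id,X,Y,Z\n")
        for leaf in leaves:
            cx, cy, cz = leaf.centroid
            fh.write(f"{leaf.superpixel_id},{cx:.6f},{cy:.6f},{cz:.6f}\n")
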