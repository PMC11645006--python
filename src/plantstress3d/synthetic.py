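"""Seeded synthetic top-view plant scenes (RGB + depth + masks + labels).

The generator emulates the structure of a top-view phenotyping dataset:
eight irrigation groups (A-H), paired RGB and 8-bit depth images, per-pixel
plant masks and leaf instance labels, and a binary stress label. Leaves are
filled ellipses arranged in a rosette; each leaf sits at a camera distance
drawn from its group's range (unstressed 65-74 cm, stressed 75-80 cm by
default) and its depth code follows the linear 0-255 encoding
``z = round(255 * Z / k)``.

Leaf brightness optionally encodes distance (``depth_shading``) so that a
monocular depth regressor has a learnable visual cue, mirroring how real
stressed foliage both sinks and changes appearance.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.draw import ellipse as draw_ellipse

from .geometry import CameraModel, code_to_depth, depth_to_code

__all__ = [
    "DEFAULT_GROUPS",
    "GroupSpec",
    "Scene",
    "SceneConfig",
    "decode_scene_depth",
    "generate_dataset",
    "generate_scene",
    "load_scene",
    "read_manifest",
]

UNSTRESSED_RANGE_CM = (65.0, 74.0)
STRESSED_RANGE_CM = (75.0, 80.0)


@dataclass(frozen=True)
class GroupSpec:
    """One irrigation group of the eight-group design."""

    name: str
    dose_ml: float
    watering_interval: int  # days between irrigations
    category: str  # excess | deficit | without stress | moderate stress
    nutrients: bool = False
    leaf_distance_range: tuple[float, float] | None = None  # cm, camera-to-leaf

    def __post_init__(self):
        if self.category not in (
            "excess",
            "deficit",
            "without stress",
            "moderate stress",
        ):
            raise ValueError(f"unknown stress category {self.category!r}")
        if self.leaf_distance_range is None:
            rng_cm = (
                UNSTRESSED_RANGE_CM if not self.stressed else STRESSED_RANGE_CM
            )
            object.__setattr__(self, "leaf_distance_range", rng_cm)
        lo, hi = self.leaf_distance_range
        if not (0 <= lo < hi):
            raise ValueError("leaf_distance_range must be a non-empty range >= 0")

    @property
    def stressed(self) -> bool:
        return self.category != "without stress"


DEFAULT_GROUPS = (
    GroupSpec("A", 250, 1, "excess"),
    GroupSpec("B", 250, 5, "deficit"),
    GroupSpec("C", 250, 2, "without stress"),
    GroupSpec("D", 250, 3, "moderate stress"),
    GroupSpec("E", 250, 1, "excess", nutrients=True),
    GroupSpec("F", 250, 5, "deficit", nutrients=True),
    GroupSpec("G", 250, 2, "moderate stress", nutrients=True),
    GroupSpec("H", 250, 3, "without stress", nutrients=True),
)


@dataclass(frozen=True)
class SceneConfig:
    image_width: int = 640
    image_height: int = 480
    groups: tuple[GroupSpec, ...] = DEFAULT_GROUPS
    leaves_per_plant: tuple[int, int] = (5, 9)
    # (major, minor) semi-axis ranges in pixels
    leaf_axis_lengths: tuple[tuple[float, float], tuple[float, float]] = (
        (22.0, 34.0),
        (12.0, 20.0),
    )
    leaf_hue_jitter: float = 6.0  # gray levels of per-leaf colour jitter
    camera: CameraModel = field(default_factory=CameraModel)
    noise_sd: float = 2.0  # additive RGB noise, gray levels
    soil_distance_m: float = 0.85
    depth_shading: bool = True  # leaf brightness encodes distance
    invert_depth_code: bool = False  # write near-bright (Kinect-style) PNGs

    def __post_init__(self):
        if self.image_width <= 32 or self.image_height <= 32:
            raise ValueError("image dimensions must exceed 32 pixels")
        lo, hi = self.leaves_per_plant
        if lo < 1 or hi < lo:
            raise ValueError("leaves_per_plant must be a range with minimum >= 1")
        for rng in self.leaf_axis_lengths:
            if rng[0] <= 0 or rng[1] < rng[0]:
                raise ValueError("leaf axis ranges must be positive and non-empty")
        if not self.groups:
            raise ValueError("at least one group is required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.soil_distance_m <= self.camera.max_depth:
            raise ValueError("soil distance must lie in (0, camera.max_depth]")


@dataclass
class Scene:
    """One synthetic dataset record."""

    rgb: np.ndarray  # H x W x 3 uint8
    depth: np.ndarray  # H x W uint8 gray codes (z grows with distance)
    plant_mask: np.ndarray  # H x W uint8, 1 = plant
    leaf_instances: np.ndarray  # H x W int32, 0 = background
    stress_label: int
    group: str
    leaf_distances_m: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        shapes = {
            self.rgb.shape[:2],
            self.depth.shape,
            self.plant_mask.shape,
            self.leaf_instances.shape,
        }
        if len(shapes) != 1:
            raise ValueError("scene arrays must share H x W")
        if np.any((self.leaf_instances > 0) != (self.plant_mask > 0)):
            raise ValueError("leaf instances and plant mask disagree")


def _leaf_color(Z, shading, jitter, rng):
    if shading:
        g = 600.0 * (1.05 - Z)  # steeper-than-physical cue; see module docstring
    else:
        g = 175.0
    base = np.array([38.0, g, 42.0])
    base += rng.normal(0.0, jitter, 3)
    return np.clip(np.rint(base), 0, 255).astype(np.uint8)


def generate_scene(config: SceneConfig, group: GroupSpec, seed: int) -> Scene:
    """Render one scene; deterministic for fixed (config, group, seed)."""
    k = config.camera.max_depth
    lo_cm, hi_cm = group.leaf_distance_range
    if hi_cm / 100.0 > k:
        raise ValueError(
            f"group {group.name}: leaf distances up to {hi_cm} cm exceed the "
            f"camera's maximum depth of {k} m"
        )
    rng = np.random.default_rng([seed, ord(group.name[0])])
    h, w = config.image_height, config.image_width

    rgb = np.empty((h, w, 3), dtype=float)
    rgb[..., 0] = 118.0
    rgb[..., 1] = 86.0
    rgb[..., 2] = 60.0
    rgb += rng.normal(0.0, 6.0, (h, w, 1))  # soil texture
    depth = np.full((h, w), depth_to_code(config.soil_distance_m, k), np.uint8)
    mask = np.zeros((h, w), np.uint8)
    instances = np.zeros((h, w), np.int32)

    n_leaves = int(rng.integers(config.leaves_per_plant[0], config.leaves_per_plant[1] + 1))
    cy = h / 2 + rng.uniform(-0.05, 0.05) * h
    cx = w / 2 + rng.uniform(-0.05, 0.05) * w
    (maj_lo, maj_hi), (min_lo, min_hi) = config.leaf_axis_lengths
    spread = 0.16 * min(h, w)
    distances = []
    for j in range(1, n_leaves + 1):
        angle = 2 * np.pi * j / n_leaves + rng.uniform(-0.3, 0.3)
        radius = spread * rng.uniform(0.55, 1.15)
        er = cy + radius * np.sin(angle)
        ec = cx + radius * np.cos(angle)
        a = rng.uniform(maj_lo, maj_hi)
        b = rng.uniform(min_lo, min_hi)
        Z_cm = rng.uniform(lo_cm, hi_cm)
        Z = Z_cm / 100.0
        distances.append(Z)
        rr, cc = draw_ellipse(er, ec, a, b, shape=(h, w), rotation=angle)
        if len(rr) == 0:
            continue
        rgb[rr, cc] = _leaf_color(Z, config.depth_shading, config.leaf_hue_jitter, rng)
        depth[rr, cc] = depth_to_code(Z, k)
        mask[rr, cc] = 1
        instances[rr, cc] = j

    if config.noise_sd > 0:
        rgb += rng.normal(0.0, config.noise_sd, rgb.shape)
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    return Scene(
        rgb=rgb,
        depth=depth,
        plant_mask=mask,
        leaf_instances=instances,
        stress_label=int(group.stressed),
        group=group.name,
        leaf_distances_m=np.array(distances),
    )


def decode_scene_depth(scene: Scene, camera: CameraModel):
    """Metric depth map (meters) recovered from the scene's gray codes."""
    return code_to_depth(scene.depth, camera.max_depth)


def _write_gray_png(path, arr, invert=False):
    a = np.asarray(arr, dtype=np.uint8)
    if invert:
        a = 255 - a
    Image.fromarray(a, mode="L").save(path)


def generate_dataset(config: SceneConfig, n_per_group: int, seed: int, out_dir):
    """Write ``n_per_group`` scenes per group as paired PNGs plus a manifest.

    Produces ``8 * n_per_group`` records with the default groups. The
    manifest is a CSV with header ``file_rgb,file_depth,group,stress,seed``;
    plant masks and leaf instance maps are written alongside as
    ``mask_*.png`` (0/255) and ``leaves_*.png`` (16-bit ids).
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(seed).generate_state(
        len(config.groups) * n_per_group
    )
    rows = []
    idx = 0
    for group in config.groups:
        for i in range(n_per_group):
            scene_seed = int(seeds[idx])
            idx += 1
            scene = generate_scene(config, group, scene_seed)
            stem = f"{group.name}_{i:04d}"
            rgb_name, depth_name = f"rgb_{stem}.png", f"depth_{stem}.png"
            Image.fromarray(scene.rgb, mode="RGB").save(out / rgb_name)
            _write_gray_png(
                out / depth_name, scene.depth, invert=config.invert_depth_code
            )
            _write_gray_png(out / f"mask_{stem}.png", scene.plant_mask * 255)
            Image.fromarray(
                scene.leaf_instances.astype(np.uint16)
            ).save(out / f"leaves_{stem}.png")
            rows.append(
                {
                    "file_rgb": rgb_name,
                    "file_depth": depth_name,
                    "group": group.name,
                    "stress": scene.stress_label,
                    "seed": scene_seed,
                }
            )
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["file_rgb", "file_depth", "group", "stress", "seed"]
        )
        writer.writeheader()
        writer.writerows(rows)
    return manifest


def read_manifest(manifest_path):
    with open(manifest_path, newline="") as fh:
        return list(csv.DictReader(fh))


def load_scene(out_dir, row, invert_depth_code=False):
    """Reload one dataset record from a manifest row."""
    out = Path(out_dir)
    rgb = np.asarray(Image.open(out / row["file_rgb"]).convert("RGB"))
    depth = np.asarray(Image.open(out / row["file_depth"]).convert("L"))
    if invert_depth_code:
        depth = 255 - depth
    stem = row["file_rgb"][len("rgb_") : -len(".png")]
    mask = (np.asarray(Image.open(out / f"mask_{stem}.png")) > 0).astype(np.uint8)
    instances = np.asarray(Image.open(out / f"leaves_{stem}.png")).astype(np.int32)
    return Scene(
        rgb=rgb,
        depth=depth,
        plant_mask=mask,
        leaf_instances=instances,
        stress_label=int(row["stress"]),
        group=row["group"],
    )
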