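"""Labeled synthetic backpack-LiDAR forest scenes.

Field clouds of ground-based scanners have a characteristic anatomy that the
generator reproduces with known ground truth:

* a gently sloping, noisy ground surface sampled everywhere in the plot;
* vertical trunks whose cross-section point density is a Gaussian ring
  around the stem outline (the scanner hits the bark from many directions,
  with ranging noise straddling the surface);
* ellipsoidal crowns atop each trunk;
* low shrub blobs that contaminate no trunk slab but are ground-connected;
* sparse far-range outliers beyond the survey polygon;
* a serpentine walking trajectory among the stems, and a mild per-point
  dropout growing with distance from it (a cheap stand-in for occlusion).

The defaults describe the stand every built-in experiment runs on: a
30 m x 30 m plot of 20 stems at >= 4 m spacing, roughly 6000 returns per
tree. Identical specs (including seed) produce bit-identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial import cKDTree

from .errors import InfeasibleSpecError
from .io_formats import PointCloud, Trajectory
from .merge_filter import SegmentationResult

__all__ = [
    "ForestSpec",
    "SyntheticScene",
    "generate",
    "truth_to_reference",
    "TRUTH_GROUND",
    "TRUTH_SHRUB",
    "TRUTH_OUTLIER",
]

TRUTH_GROUND = -1
TRUTH_SHRUB = -2
TRUTH_OUTLIER = -3


@dataclass
class ForestSpec:
    """Scene recipe; all lengths in meters, densities in points per m^2."""

    n_trees: int = 20
    plot_size: tuple[float, float] = (30.0, 30.0)
    min_spacing: float = 4.0
    trunk_radius_range: tuple[float, float] = (0.08, 0.15)
    trunk_height_range: tuple[float, float] = (4.0, 6.0)  # crown-base height
    trunk_ring_sigma: float = 0.02
    crown_radius_range: tuple[float, float] = (1.0, 1.6)
    crown_depth_range: tuple[float, float] = (2.0, 3.5)
    ground_slope: tuple[float, float] = (0.05, 0.03)
    ground_noise_sigma: float = 0.02
    points_per_tree: int = 6000
    trunk_point_fraction: float = 0.6
    ground_point_density: float = 15.0
    n_shrubs: int = 8
    shrub_points: int = 120
    n_outliers: int = 200
    dropout_per_meter: float = 0.01  # keep prob = 1 - rate * dist(trajectory)
    edge_margin: float = 2.5  # stems keep this far from the plot boundary
    stem_positions: tuple | None = None  # fixed (x, y) stems; overrides placement
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 0:
            raise ValueError("n_trees must be >= 0")
        if self.n_trees and self.min_spacing <= 2 * self.trunk_radius_range[1]:
            raise ValueError("min_spacing must exceed twice the max trunk radius")
        for name in ("trunk_radius_range", "trunk_height_range",
                     "crown_radius_range", "crown_depth_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (lo, hi) range")


@dataclass
class SyntheticScene:
    """A generated scene: cloud, per-point truth, trajectory, true stem map."""

    cloud: PointCloud
    truth: np.ndarray  # >=1 tree id, -1 ground, -2 shrub, -3 outlier
    trajectory: Trajectory
    stem_map: dict[int, tuple[float, float]]
    spec: ForestSpec

    def ground_elevation(self, xy: np.ndarray) -> np.ndarray:
        """Noise-free terrain height under arbitrary XY (the true plane)."""
        sx, sy = self.spec.ground_slope
        xy = np.atleast_2d(xy)
        return sx * xy[:, 0] + sy * xy[:, 1]


def _place_stems(spec: ForestSpec, rng: np.random.Generator) -> np.ndarray:
    w, h = spec.plot_size
    m = spec.edge_margin
    if spec.stem_positions is not None:
        return np.asarray(spec.stem_positions, dtype=float).reshape(-1, 2)
    if spec.n_trees == 0:
        return np.empty((0, 2))
    if w - 2 * m <= 0 or h - 2 * m <= 0:
        raise InfeasibleSpecError("plot too small for the edge margin")
    stems: list[np.ndarray] = []
    attempts = 0
    max_attempts = 400 * spec.n_trees
    while len(stems) < spec.n_trees:
        if attempts >= max_attempts:
            raise InfeasibleSpecError(
                f"could not place {spec.n_trees} stems at spacing "
                f"{spec.min_spacing} m in a {w} x {h} m plot"
            )
        attempts += 1
        cand = np.array([rng.uniform(m, w - m), rng.uniform(m, h - m)])
        if all(np.linalg.norm(cand - s) >= spec.min_spacing for s in stems):
            stems.append(cand)
    return np.array(stems)


def _serpentine_trajectory(spec: ForestSpec) -> np.ndarray:
    """Walking path: parallel lanes across the plot, 1.5 m above the terrain."""
    w, h = spec.plot_size
    lane_ys = np.linspace(1.0, h - 1.0, max(3, int(np.ceil(h / 4.5))))
    xs_fwd = np.arange(1.0, w - 1.0 + 1e-9, 1.0)
    rows = []
    for i, y in enumerate(lane_ys):
        xs = xs_fwd if i % 2 == 0 else xs_fwd[::-1]
        rows.append(np.column_stack([xs, np.full_like(xs, y)]))
    xy = np.vstack(rows)
    sx, sy = spec.ground_slope
    z = sx * xy[:, 0] + sy * xy[:, 1] + 1.5
    return np.column_stack([xy, z])


def _sample_ellipsoid(
    n: int, semi: tuple[float, float, float], rng: np.random.Generator
) -> np.ndarray:
    """Uniform samples inside an ellipsoid with the given semi-axes."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = rng.uniform(size=n) ** (1.0 / 3.0)
    return v * r[:, None] * np.asarray(semi)


def generate(spec: ForestSpec) -> SyntheticScene:
    """Generate a scene; identical specs yield bit-identical results."""
    rng = np.random.default_rng(spec.seed)
    w, h = spec.plot_size
    sx, sy = spec.ground_slope
    stems = _place_stems(spec, rng)

    chunks: list[np.ndarray] = []
    truth_chunks: list[np.ndarray] = []

    def terrain(xy: np.ndarray) -> np.ndarray:
        return sx * xy[:, 0] + sy * xy[:, 1]

    # ground
    n_ground = rng.poisson(spec.ground_point_density * w * h)
    gxy = rng.uniform([0, 0], [w, h], size=(n_ground, 2))
    gz = terrain(gxy) + rng.normal(0, spec.ground_noise_sigma, n_ground)
    chunks.append(np.column_stack([gxy, gz]))
    truth_chunks.append(np.full(n_ground, TRUTH_GROUND))

    # trees: Gaussian-ring trunks plus uniform ellipsoidal crowns
    stem_map: dict[int, tuple[float, float]] = {}
    for tid, stem in enumerate(stems, start=1):
        stem_map[tid] = (float(stem[0]), float(stem[1]))
        r_tree = rng.uniform(*spec.trunk_radius_range)
        crown_base = rng.uniform(*spec.trunk_height_range)
        crown_r = rng.uniform(*spec.crown_radius_range)
        crown_d = rng.uniform(*spec.crown_depth_range)
        n_total = rng.poisson(spec.points_per_tree)
        n_trunk = int(round(n_total * spec.trunk_point_fraction))
        n_crown = n_total - n_trunk
        z0 = terrain(stem[None, :])[0]

        theta = rng.uniform(0, 2 * np.pi, n_trunk)
        radial = rng.normal(r_tree, spec.trunk_ring_sigma, n_trunk)
        heights = rng.uniform(0, crown_base, n_trunk)
        trunk = np.column_stack(
            [
                stem[0] + radial * np.cos(theta),
                stem[1] + radial * np.sin(theta),
                z0 + heights,
            ]
        )
        crown = _sample_ellipsoid(n_crown, (crown_r, crown_r, crown_d / 2), rng)
        crown += np.array([stem[0], stem[1], z0 + crown_base + crown_d / 2])
        chunks.append(np.vstack([trunk, crown]))
        truth_chunks.append(np.full(n_trunk + n_crown, tid))

    # shrubs: low half-ellipsoid blobs away from every stem
    for _ in range(spec.n_shrubs):
        for _attempt in range(200):
            cxy = rng.uniform([0.5, 0.5], [w - 0.5, h - 0.5])
            if len(stems) == 0 or np.min(
                np.linalg.norm(stems - cxy, axis=1)
            ) >= 1.5:
                break
        sr = rng.uniform(0.4, 0.9)
        sh = rng.uniform(0.3, 0.8)
        pts = _sample_ellipsoid(spec.shrub_points, (sr, sr, sh), rng)
        pts[:, 2] = np.abs(pts[:, 2])
        pts += np.array([cxy[0], cxy[1], terrain(cxy[None, :])[0]])
        chunks.append(pts)
        truth_chunks.append(np.full(spec.shrub_points, TRUTH_SHRUB))

    # far-range outliers beyond the survey polygon
    if spec.n_outliers:
        ang = rng.uniform(0, 2 * np.pi, spec.n_outliers)
        ext = rng.uniform(3.0, 12.0, spec.n_outliers)
        half = np.array([w / 2, h / 2])
        edge = np.linalg.norm(half) + ext  # radially beyond the plot corner
        oxy = half + np.column_stack([np.cos(ang), np.sin(ang)]) * edge[:, None]
        oz = rng.uniform(0.0, 10.0, spec.n_outliers)
        chunks.append(np.column_stack([oxy, oz]))
        truth_chunks.append(np.full(spec.n_outliers, TRUTH_OUTLIER))

    coords = np.vstack(chunks)
    truth = np.concatenate(truth_chunks).astype(np.int64)

    traj_positions = _serpentine_trajectory(spec)
    trajectory = Trajectory(traj_positions)

    # occlusion stand-in: per-point dropout growing with trajectory distance
    if spec.dropout_per_meter > 0:
        kd = cKDTree(traj_positions[:, :2])
        d = kd.query(coords[:, :2])[0]
        keep_prob = np.clip(1.0 - spec.dropout_per_meter * d, 0.3, 1.0)
        keep = rng.uniform(size=len(coords)) < keep_prob
        keep |= truth == TRUTH_OUTLIER  # outliers are range artifacts, keep all
        coords, truth = coords[keep], truth[keep]

    cloud = PointCloud(coords, source_id=f"synthetic(seed={spec.seed})")
    return SyntheticScene(cloud, truth, trajectory, stem_map, spec)


def truth_to_reference(scene: SyntheticScene) -> SegmentationResult:
    """Reference labeling for validation: trees keep their true ids, all
    ground/shrub/outlier points are 0; stems are the true stem map."""
    labels = np.where(scene.truth >= 1, scene.truth, 0)
    return SegmentationResult(
        labels=labels.astype(np.int64),
        tree_locations=dict(scene.stem_map),
        params_used=None,
        stage_counts={"source": "synthetic truth"},
    )


def spec_to_dict(spec: ForestSpec) -> dict:
    return asdict(spec)


def spec_from_dict(data: dict) -> ForestSpec:
    fields = {k: v for k, v in data.items() if k in ForestSpec.__dataclass_fields__}
    for key in ("plot_size", "trunk_radius_range", "trunk_height_range",
                "crown_radius_range", "crown_depth_range", "ground_slope"):
        if key in fields and isinstance(fields[key], list):
            fields[key] = tuple(fields[key])
    return ForestSpec(**fields)
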