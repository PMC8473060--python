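"""Iterative cylinder voxelization of the vegetation cloud.

Each detected trunk defines an infinite vertical cylinder centered on its
centroid whose radius (the *candidate radius*) is the distance to the
nearest other trunk. Cylinders are processed in ascending radius order;
each claims every still-unclaimed point inside it and subclusters the claim
with a 3D DBSCAN at a small radius, so crown fragments of neighboring trees
stay separable. Points claimed by no cylinder, together with per-cylinder
DBSCAN noise, form the discarded set handled by the merge/filter stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateRadiusError
from .io_formats import PointCloud
from .trunk_detect import SegmentationParams, TrunkCluster, dbscan

__all__ = [
    "CylinderCell",
    "candidate_radii",
    "extract_cylinder",
    "subcluster_cylinder",
    "run_voxelization",
]


@dataclass
class CylinderCell:
    """One trunk's cylinder: its claimed points and their 3D subclusters."""

    trunk_id: int
    center_xy: tuple[float, float]
    radius: float
    member_indices: np.ndarray
    subclusters: list[np.ndarray] = field(default_factory=list)
    dbscan_noise: np.ndarray = field(default_factory=lambda: np.empty(0, int))


def candidate_radii(
    trunks: list[TrunkCluster],
    cloud: PointCloud | None = None,
    max_radius: float | None = None,
) -> dict[int, float]:
    """Nearest-neighbor distance between trunk centroids, per trunk.

    With a single trunk the nearest neighbor is undefined and the whole plot
    is treated as one tree: the radius becomes the cloud's XY bounding-circle
    radius about the trunk (``cloud`` required). ``max_radius`` optionally
    caps every radius.
    """
    if not trunks:
        raise ValueError("candidate_radii requires at least one trunk")
    if len(trunks) == 1:
        t = trunks[0]
        if cloud is None:
            raise ValueError("single-trunk radius needs the cloud extent")
        d = np.hypot(
            cloud.xy[:, 0] - t.centroid_xy[0], cloud.xy[:, 1] - t.centroid_xy[1]
        )
        radius = float(d.max()) if len(d) else 1.0
        return {t.trunk_id: min(radius, max_radius) if max_radius else radius}

    centers = np.array([t.centroid_xy for t in trunks])
    tree = cKDTree(centers)
    dist, idx = tree.query(centers, k=2)
    radii: dict[int, float] = {}
    for i, (t, (d, j)) in enumerate(zip(trunks, zip(dist[:, 1], idx[:, 1]))):
        if d <= 1e-12:
            # k-NN may return the point itself among distance-0 ties
            other = next(
                o.trunk_id
                for k, o in enumerate(trunks)
                if k != i and np.allclose(centers[k], centers[i])
            )
            raise DegenerateRadiusError(
                f"trunks {t.trunk_id} and {other} have coincident "
                f"centroids {t.centroid_xy}"
            )
        radii[t.trunk_id] = min(d, max_radius) if max_radius else float(d)
    return radii


def extract_cylinder(
    cloud: PointCloud,
    center_xy: tuple[float, float],
    radius: float,
    available: np.ndarray,
) -> np.ndarray:
    """Indices of available points whose XY distance to the center is <= radius.

    z is unconstrained (the cylinder is infinite). ``available`` is either a
    boolean mask over the cloud or an integer index set.
    """
    if radius <= 0:
        raise ValueError("cylinder radius must be > 0")
    available = np.asarray(available)
    idx = np.flatnonzero(available) if available.dtype == bool else available
    d = np.hypot(
        cloud.xy[idx, 0] - center_xy[0], cloud.xy[idx, 1] - center_xy[1]
    )
    return idx[d <= radius]


def subcluster_cylinder(
    cloud: PointCloud, members: np.ndarray, params: SegmentationParams
) -> tuple[list[np.ndarray], np.ndarray]:
    """3D DBSCAN of a cylinder's points at eps_cylinder.

    Returns (subclusters, noise), both as index arrays into ``cloud``.
    """
    members = np.asarray(members)
    if len(members) == 0:
        raise ValueError("subcluster_cylinder requires a non-empty member set")
    clusters, noise = dbscan(
        cloud.coords[members], params.eps_cylinder, params.min_points_cyl
    )
    return [members[c] for c in clusters], members[noise]


def run_voxelization(
    cloud: PointCloud, trunks: list[TrunkCluster], params: SegmentationParams
) -> tuple[list[CylinderCell], np.ndarray]:
    """Iterate cylinders smallest-radius-first over a shrinking point pool.

    Each cylinder removes its claim from the pool, so no point belongs to two
    cylinders. Returns the cylinder cells and the discarded set: points never
    claimed by any cylinder plus per-cylinder DBSCAN noise.
    """
    radii = candidate_radii(
        trunks, cloud=cloud, max_radius=params.max_candidate_radius
    )
    order = sorted(trunks, key=lambda t: (radii[t.trunk_id], t.trunk_id))
    available = np.ones(len(cloud), dtype=bool)
    cells: list[CylinderCell] = []
    noise_parts: list[np.ndarray] = []
    for trunk in order:
        members = extract_cylinder(
            cloud, trunk.centroid_xy, radii[trunk.trunk_id], available
        )
        available[members] = False
        if len(members):
            subclusters, cyl_noise = subcluster_cylinder(cloud, members, params)
        else:
            subclusters, cyl_noise = [], np.empty(0, dtype=int)
        noise_parts.append(cyl_noise)
        cells.append(
            CylinderCell(
                trunk_id=trunk.trunk_id,
                center_xy=trunk.centroid_xy,
                radius=radii[trunk.trunk_id],
                member_indices=members,
                subclusters=subclusters,
                dbscan_noise=cyl_noise,
            )
        )
    never_claimed = np.flatnonzero(available)
    discarded = np.concatenate([never_claimed, *noise_parts]) if cells else never_claimed
    return cells, np.sort(discarded.astype(int))
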