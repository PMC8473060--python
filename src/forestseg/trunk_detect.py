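"""Trunk-layer extraction, density clustering, and stem locations.

Stems of a height-normalized terrestrial cloud appear as dense, compact
rings in a thin horizontal slab near breast height. DBSCAN on the XY
projection of that slab isolates one cluster per trunk (or one merged
cluster per group of trunks closer than the neighborhood radius); the
equal-weight center of mass of each cluster is the tree-location estimate.

The DBSCAN here is deliberately deterministic: neighbor counts include the
point itself, clusters are grown from core points in ascending index order,
and a border point reachable from several clusters joins the cluster of its
lowest-indexed core neighbor. This pins down exactly the ambiguities that
change results at ``min_points`` boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import NoTreesDetectedError, NoTrunkLayerError
from .io_formats import PointCloud

__all__ = [
    "SegmentationParams",
    "TrunkCluster",
    "dbscan_labels",
    "dbscan",
    "extract_trunk_layer",
    "detect_trunks",
]


@dataclass
class SegmentationParams:
    """Parameters of the trunk / cylinder / merge stages (lengths in meters).

    eps_trunk
        DBSCAN radius for trunk identification in the slab's XY projection.
    eps_cylinder
        DBSCAN radius for the 3D subclustering inside each cylinder; small
        values deliberately oversegment so crown fragments of neighboring
        trees stay separable.
    min_points
        Minimum neighbors (self included) for a core point in the trunk step.
    min_points_cyl
        Same for the per-cylinder subclustering; permissive by design.
    noise_threshold
        d*: a discarded point closer than this to a segment joins it,
        otherwise it is noise. Default is the sensitivity-sweep optimum.
    slab_zmin, slab_zmax
        Normalized-height bounds of the trunk layer (inclusive).
    continuity_bin, continuity_ground_max, continuity_gap_bins
        Vertical-continuity test: z-histogram bin width, maximum height of
        the lowest occupied bin's lower edge for a ground-connected segment,
        and the number of consecutive empty bins that counts as a gap.
    """

    eps_trunk: float = 0.1
    eps_cylinder: float = 0.9
    min_points: int = 40
    min_points_cyl: int = 10
    noise_threshold: float = 0.87
    slab_zmin: float = 1.0
    slab_zmax: float = 1.5
    continuity_bin: float = 0.25
    continuity_ground_max: float = 0.5
    continuity_gap_bins: int = 2
    max_candidate_radius: float | None = None  # optional cap on cylinder radii

    def __post_init__(self) -> None:
        if self.eps_trunk <= 0 or self.eps_cylinder <= 0:
            raise ValueError("DBSCAN radii must be > 0")
        if self.min_points < 1 or self.min_points_cyl < 1:
            raise ValueError("min_points must be >= 1")
        if self.noise_threshold <= 0:
            raise ValueError("noise_threshold must be > 0")
        if self.slab_zmin >= self.slab_zmax:
            raise ValueError("slab_zmin must be < slab_zmax")
        if self.continuity_bin <= 0 or self.continuity_gap_bins < 1:
            raise ValueError("invalid continuity parameters")


@dataclass
class TrunkCluster:
    """A DBSCAN trunk cluster with its XY center of mass (the stem estimate)."""

    trunk_id: int
    member_indices: np.ndarray  # indices into the normalized cloud
    centroid_xy: tuple[float, float]


def dbscan_labels(points: np.ndarray, eps: float, min_points: int) -> np.ndarray:
    """Deterministic DBSCAN; returns per-point labels (-1 noise, 0..k-1 clusters).

    Core iff >= ``min_points`` neighbors within ``eps`` (counting itself);
    clusters are connected components of core points under eps-reachability,
    numbered in ascending order of their smallest core index; border points
    join the cluster of their lowest-indexed core neighbor.
    """
    points = np.asarray(points, dtype=np.float64)
    n = len(points)
    labels = np.full(n, -1, dtype=np.int64)
    if n == 0:
        return labels
    tree = cKDTree(points)
    counts = tree.query_ball_point(points, r=eps, return_length=True)
    core = counts >= min_points
    core_idx = np.flatnonzero(core)
    if len(core_idx) == 0:
        return labels

    # connected components of the core-core eps graph
    core_tree = cKDTree(points[core_idx])
    pairs = core_tree.query_pairs(eps, output_type="ndarray")
    m = len(core_idx)
    graph = coo_matrix(
        (np.ones(len(pairs), dtype=np.int8), (pairs[:, 0], pairs[:, 1])),
        shape=(m, m),
    )
    _, comp = connected_components(graph, directed=False)
    # number clusters by ascending smallest core index (core_idx is sorted,
    # so first occurrence order over comp gives exactly that numbering)
    _, first = np.unique(comp, return_index=True)
    rank = np.empty(comp.max() + 1, dtype=np.int64)
    rank[comp[np.sort(first)]] = np.arange(len(first))
    labels[core_idx] = rank[comp]

    # border points: the lowest-indexed core neighbor decides the cluster
    noncore_idx = np.flatnonzero(~core)
    if len(noncore_idx):
        neigh = core_tree.query_ball_point(points[noncore_idx], r=eps)
        for p, lst in zip(noncore_idx, neigh):
            if lst:
                labels[p] = labels[core_idx[min(lst)]]
    return labels


def dbscan(
    points: np.ndarray, eps: float, min_points: int
) -> tuple[list[np.ndarray], np.ndarray]:
    """DBSCAN returning (clusters as index arrays, noise index array)."""
    labels = dbscan_labels(points, eps, min_points)
    n_clusters = labels.max() + 1
    clusters = [np.flatnonzero(labels == c) for c in range(n_clusters)]
    return clusters, np.flatnonzero(labels == -1)


def extract_trunk_layer(
    cloud: PointCloud, params: SegmentationParams
) -> tuple[PointCloud, np.ndarray]:
    """Points of the normalized cloud with slab_zmin <= z <= slab_zmax.

    Returns the slab cloud together with its indices into ``cloud``.
    """
    mask = (cloud.z >= params.slab_zmin) & (cloud.z <= params.slab_zmax)
    if not mask.any():
        raise NoTrunkLayerError(
            f"no points in trunk layer [{params.slab_zmin}, {params.slab_zmax}] m; "
            "is the cloud height-normalized?"
        )
    return cloud.subset(mask), np.flatnonzero(mask)


def detect_trunks(
    cloud: PointCloud, params: SegmentationParams
) -> list[TrunkCluster]:
    """Cluster the trunk layer and return per-trunk centroids (tree locations).

    The centroid is the equal-weight center of mass of the cluster's XY
    coordinates, i.e. the arithmetic mean.
    """
    slab, slab_idx = extract_trunk_layer(cloud, params)
    clusters, _ = dbscan(slab.xy, params.eps_trunk, params.min_points)
    if not clusters:
        raise NoTreesDetectedError(
            "trunk-layer DBSCAN found no clusters; consider increasing "
            "eps_trunk or decreasing min_points"
        )
    trunks = []
    for i, members in enumerate(clusters, start=1):
        xy = slab.xy[members]
        centroid = xy.mean(axis=0)
        trunks.append(
            TrunkCluster(
                trunk_id=i,
                member_indices=slab_idx[members],
                centroid_xy=(float(centroid[0]), float(centroid[1])),
            )
        )
    return trunks
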