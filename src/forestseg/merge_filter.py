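"""Floating-segment merging, discarded-point assignment, final labeling.

Subclusters from the cylinder stage are either *ground-connected* (their
vertical point-density profile reaches the ground without interruption) or
*floating* (crown fragments detached from their stem by occlusion or by the
deliberate oversegmentation). Floating segments merge into the closest
ground-connected segment; discarded points join the closest segment if it
is nearer than the noise threshold d*, otherwise they form the noise set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import UnmergeableError
from .cylinder_segment import CylinderCell
from .io_formats import PointCloud
from .trunk_detect import SegmentationParams

__all__ = [
    "Segment",
    "SegmentationResult",
    "classify_continuity",
    "build_segments",
    "merge_floating",
    "assign_discarded",
    "finalize",
]


@dataclass
class Segment:
    """A candidate tree part: one cylinder subcluster and its provenance."""

    tree_id: int
    point_indices: np.ndarray
    ground_connected: bool
    stem_xy: tuple[float, float]


@dataclass
class SegmentationResult:
    """Final per-point labeling (0 = noise, >= 1 = tree id) plus stem map."""

    labels: np.ndarray
    tree_locations: dict[int, tuple[float, float]]
    params_used: SegmentationParams | None = None
    stage_counts: dict = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return len(self.tree_locations)


def classify_continuity(
    cloud: PointCloud, subcluster: np.ndarray, params: SegmentationParams
) -> bool:
    """True iff the subcluster's z-histogram reaches the ground without a gap.

    Bins of width ``continuity_bin`` are anchored at z = 0. The segment is
    ground-connected iff (a) the lower edge of its lowest occupied bin is at
    most ``continuity_ground_max`` and (b) no run of ``continuity_gap_bins``
    consecutive empty bins occurs below its top occupied bin.
    """
    z = cloud.z[np.asarray(subcluster)]
    if len(z) == 0:
        raise ValueError("empty subcluster")
    h = params.continuity_bin
    lo_bin = int(np.floor(z.min() / h))
    hi_bin = int(np.floor(z.max() / h))
    if lo_bin * h > params.continuity_ground_max:
        return False
    occupied = np.zeros(hi_bin - lo_bin + 1, dtype=bool)
    occupied[(np.floor(z / h).astype(int) - lo_bin)] = True
    run = best = 0
    for filled in occupied:
        run = 0 if filled else run + 1
        best = max(best, run)
    return best < params.continuity_gap_bins


def build_segments(
    cloud: PointCloud, cells: list[CylinderCell], params: SegmentationParams
) -> list[Segment]:
    """Wrap every cylinder subcluster as a Segment with a continuity verdict."""
    segments = []
    tid = 1
    for cell in cells:
        for sub in cell.subclusters:
            segments.append(
                Segment(
                    tree_id=tid,
                    point_indices=np.asarray(sub),
                    ground_connected=classify_continuity(cloud, sub, params),
                    stem_xy=cell.center_xy,
                )
            )
            tid += 1
    return segments


def merge_floating(
    segments: list[Segment], cloud: PointCloud
) -> list[Segment]:
    """Merge each floating segment into its closest ground-connected segment.

    Distance is the minimum 3D point-to-point distance; ties go to the lower
    tree_id. Returns the surviving (ground-connected) segments, which from
    here on are the trees.
    """
    grounded = [s for s in segments if s.ground_connected]
    floating = [s for s in segments if not s.ground_connected]
    if floating and not grounded:
        raise UnmergeableError(
            "floating segments exist but no segment reaches the ground"
        )
    grounded = sorted(grounded, key=lambda s: s.tree_id)
    trees = [
        Segment(s.tree_id, np.array(s.point_indices), True, s.stem_xy)
        for s in grounded
    ]
    if floating:
        kdtrees = [cKDTree(cloud.coords[t.point_indices]) for t in trees]
        merged: dict[int, list[np.ndarray]] = {i: [] for i in range(len(trees))}
        for seg in floating:
            pts = cloud.coords[seg.point_indices]
            dists = [kd.query(pts)[0].min() for kd in kdtrees]
            target = int(np.argmin(dists))  # first minimum = lowest tree_id
            merged[target].append(seg.point_indices)
        for i, extras in merged.items():
            if extras:
                trees[i].point_indices = np.concatenate(
                    [trees[i].point_indices, *extras]
                )
    return trees


def assign_discarded(
    discarded: np.ndarray,
    segments: list[Segment],
    cloud: PointCloud,
    d_star: float,
) -> tuple[dict[int, np.ndarray], np.ndarray]:
    """Attach discarded points closer than d* to their nearest segment.

    Distance is to the nearest member point of each segment. The comparison
    is strict (< d*); points at or beyond the threshold become noise.
    Returns ({segment tree_id: assigned indices}, noise indices).
    """
    discarded = np.asarray(discarded, dtype=int)
    assignments: dict[int, np.ndarray] = {s.tree_id: np.empty(0, int) for s in segments}
    if len(discarded) == 0 or not segments:
        return assignments, discarded
    pts = cloud.coords[discarded]
    dist = np.column_stack(
        [cKDTree(cloud.coords[s.point_indices]).query(pts)[0] for s in segments]
    )
    nearest = dist.argmin(axis=1)  # ties resolve to the lower tree_id
    keep = dist[np.arange(len(discarded)), nearest] < d_star
    for j, seg in enumerate(segments):
        assignments[seg.tree_id] = discarded[keep & (nearest == j)]
    return assignments, discarded[~keep]


def finalize(
    segments: list[Segment],
    assignments: dict[int, np.ndarray],
    noise: np.ndarray,
    n_points: int,
    params: SegmentationParams | None = None,
    stage_counts: dict | None = None,
) -> SegmentationResult:
    """Relabel trees 1..N in ascending stem (x, y) order and build the labels."""
    order = sorted(segments, key=lambda s: (s.stem_xy[0], s.stem_xy[1], s.tree_id))
    labels = np.zeros(n_points, dtype=np.int64)
    locations: dict[int, tuple[float, float]] = {}
    counts = dict(stage_counts or {})
    for new_id, seg in enumerate(order, start=1):
        idx = np.concatenate(
            [seg.point_indices, assignments.get(seg.tree_id, np.empty(0, int))]
        ).astype(int)
        labels[idx] = new_id
        locations[new_id] = seg.stem_xy
    counts.setdefault("n_trees", len(order))
    counts.setdefault("n_noise", int(len(noise)))
    return SegmentationResult(
        labels=labels,
        tree_locations=locations,
        params_used=params,
        stage_counts=counts,
    )
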