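"""End-to-end segmentation: preprocess -> trunks -> cylinders -> merge.

The preprocessing product is cached in a :class:`PreprocessedScene` so the
sensitivity sweep can rerun only the stages the swept parameters touch.
Ground points feed the DTM and are excluded from segmentation (they are
terrain, not vegetation); they are labeled 0 in the final result, as are
points removed by the trajectory-hull gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import PointCloud, Trajectory
from .merge_filter import (
    SegmentationResult,
    assign_discarded,
    build_segments,
    finalize,
    merge_floating,
)
from .preprocess import (
    DTMGrid,
    PreprocessParams,
    build_dtm,
    ground_mask,
    hull_retention_mask,
    normalize_heights,
)
from .cylinder_segment import run_voxelization
from .trunk_detect import SegmentationParams, detect_trunks

__all__ = ["PreprocessedScene", "preprocess_scene", "segment_preprocessed",
           "segment_cloud"]

log = logging.getLogger(__name__)


@dataclass
class PreprocessedScene:
    """Height-normalized vegetation cloud plus the bookkeeping to map back."""

    vegetation: PointCloud  # normalized, segmentation substrate
    veg_indices: np.ndarray  # indices of vegetation points in the input cloud
    dtm: DTMGrid
    n_input: int
    n_hull_removed: int
    n_ground: int


def preprocess_scene(
    cloud: PointCloud,
    trajectory: Trajectory | None = None,
    params: PreprocessParams | None = None,
) -> PreprocessedScene:
    """Hull-gate, ground-filter, and height-normalize an input cloud."""
    params = params or PreprocessParams()
    if trajectory is not None:
        inside = hull_retention_mask(cloud, trajectory, params.hull_buffer)
    else:
        log.warning("no trajectory given; skipping hull outlier filter")
        inside = np.ones(len(cloud), dtype=bool)
    inside_idx = np.flatnonzero(inside)
    filtered = cloud.subset(inside)

    g_mask = ground_mask(filtered, params)
    ground = filtered.subset(g_mask)
    veg = filtered.subset(~g_mask)
    extent = (*filtered.xy.min(0), *filtered.xy.max(0))
    dtm = build_dtm(ground, params, extent=extent)
    veg_norm = normalize_heights(veg, dtm)
    return PreprocessedScene(
        vegetation=veg_norm,
        veg_indices=inside_idx[~g_mask],
        dtm=dtm,
        n_input=len(cloud),
        n_hull_removed=int((~inside).sum()),
        n_ground=int(g_mask.sum()),
    )


def segment_preprocessed(
    prep: PreprocessedScene, params: SegmentationParams | None = None
) -> SegmentationResult:
    """Run trunk detection through final labeling on a preprocessed scene."""
    params = params or SegmentationParams()
    veg = prep.vegetation
    trunks = detect_trunks(veg, params)
    cells, discarded = run_voxelization(veg, trunks, params)
    segments = build_segments(veg, cells, params)
    n_floating = sum(not s.ground_connected for s in segments)
    trees = merge_floating(segments, veg)
    assignments, noise = assign_discarded(
        discarded, trees, veg, params.noise_threshold
    )
    counts = {
        "n_input": prep.n_input,
        "n_hull_removed": prep.n_hull_removed,
        "n_ground": prep.n_ground,
        "n_vegetation": len(veg),
        "n_trunks": len(trunks),
        "n_segments": len(segments),
        "n_floating_merged": n_floating,
        "n_discarded": int(len(discarded)),
        "n_assigned": int(sum(len(v) for v in assignments.values())),
    }
    local = finalize(trees, assignments, noise, len(veg), params, counts)
    # lift the vegetation-local labels onto the full input cloud
    labels = np.zeros(prep.n_input, dtype=np.int64)
    labels[prep.veg_indices] = local.labels
    return SegmentationResult(
        labels=labels,
        tree_locations=local.tree_locations,
        params_used=params,
        stage_counts=local.stage_counts,
    )


def segment_cloud(
    cloud: PointCloud,
    trajectory: Trajectory | None = None,
    pre_params: PreprocessParams | None = None,
    seg_params: SegmentationParams | None = None,
) -> SegmentationResult:
    """Full pipeline on a raw cloud; labels cover every input point."""
    prep = preprocess_scene(cloud, trajectory, pre_params)
    return segment_preprocessed(prep, seg_params)
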