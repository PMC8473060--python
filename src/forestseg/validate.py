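"""Reference-vs-algorithm tree matching, accuracy metrics, sensitivity sweep.

Matching iterates reference trees in ascending id. For reference tree R with
closest reference neighbor R', the search radius d_min is the mean distance
from R's points to their nearest point of R' — an estimate of how far apart
neighboring trees are locally. Algorithm trees whose stem lies within d_min
of R's stem are tried nearest-first:

* N* > N1 and N* >= N1 + N2 -> the algorithm tree straddles two reference
  trees: false positive; it is consumed and the next candidate is tried;
* N* > N1 and N* < N1 + N2  -> true positive (some excess points);
* N* <= N1                  -> true positive (possibly incomplete);

where N* = |algorithm tree|, N1 = |R|, N2 = |R'|. A reference tree with no
surviving candidate is a false negative. From the verdict counts:

    DR = N_TP / N_R,  E_COM = N_FN / (N_TP + N_FN),  E_OM = N_FP / (N_TP + N_FP).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import AlignmentError, ForestSegError
from .io_formats import PointCloud, Trajectory
from .merge_filter import SegmentationResult
from .pipeline import PreprocessedScene, preprocess_scene, segment_preprocessed
from .preprocess import PreprocessParams
from .trunk_detect import SegmentationParams

__all__ = [
    "MatchOutcome",
    "Metrics",
    "match_trees",
    "compute_metrics",
    "stems_from_labels",
    "sensitivity_sweep",
    "report_dict",
]


@dataclass
class MatchOutcome:
    """Per-tree verdicts of the matching procedure."""

    ref_verdicts: dict[int, str]  # reference id -> "TP" | "FN"
    seg_verdicts: dict[int, str]  # algorithm id -> "TP" | "FP" | "unmatched"
    matches: dict[int, int]  # reference id -> matched algorithm id
    d_min: dict[int, float]  # reference id -> search radius used
    n_tp: int = 0
    n_fp: int = 0
    n_fn: int = 0


@dataclass
class Metrics:
    """Detection rate and commission/omission errors (fractions in [0, 1])."""

    dr: float | None
    e_com: float | None
    e_om: float | None
    n_tp: int
    n_fn: int
    n_fp: int
    n_ref: int


def _tree_points(labels: np.ndarray) -> dict[int, np.ndarray]:
    ids = np.unique(labels)
    return {int(t): np.flatnonzero(labels == t) for t in ids if t >= 1}


def stems_from_labels(
    cloud: PointCloud,
    labels: np.ndarray,
    slab: tuple[float, float] = (1.0, 1.5),
) -> dict[int, tuple[float, float]]:
    """Per-tree stem estimate: XY centroid of the tree's trunk-slab points.

    Falls back to the all-point XY centroid when the slab is empty (e.g. for
    clouds whose heights are not normalized).
    """
    stems = {}
    for tid, idx in _tree_points(labels).items():
        z = cloud.z[idx]
        in_slab = (z >= slab[0]) & (z <= slab[1])
        sel = idx[in_slab] if in_slab.any() else idx
        c = cloud.xy[sel].mean(axis=0)
        stems[tid] = (float(c[0]), float(c[1]))
    return stems


def match_trees(
    reference: SegmentationResult,
    predicted: SegmentationResult,
    cloud: PointCloud,
    retry_after_fp: bool = True,
) -> MatchOutcome:
    """Match algorithm trees to reference trees on a shared cloud.

    ``retry_after_fp`` keeps a reference tree in play after its nearest
    candidate is ruled a false positive (it then tries the next-nearest
    candidate inside d_min); switching it off rules the tree a false
    negative immediately.
    """
    if len(reference.labels) != len(predicted.labels):
        raise AlignmentError(
            f"labelings cover {len(reference.labels)} vs "
            f"{len(predicted.labels)} points"
        )
    ref_pts = _tree_points(reference.labels)
    pred_pts = _tree_points(predicted.labels)
    if len(ref_pts) < 2:
        raise ForestSegError(
            "matching needs >= 2 reference trees to define d_min"
        )
    ref_ids = sorted(ref_pts)
    pred_ids = sorted(pred_pts)
    ref_stems = {
        t: np.asarray(reference.tree_locations.get(t))
        if reference.tree_locations.get(t) is not None
        else cloud.xy[ref_pts[t]].mean(axis=0)
        for t in ref_ids
    }
    pred_stems = {
        t: np.asarray(predicted.tree_locations.get(t))
        if predicted.tree_locations.get(t) is not None
        else cloud.xy[pred_pts[t]].mean(axis=0)
        for t in pred_ids
    }

    kdtrees = {t: cKDTree(cloud.coords[idx]) for t, idx in ref_pts.items()}
    outcome = MatchOutcome({}, {t: "unmatched" for t in pred_ids}, {}, {})
    consumed: set[int] = set()

    for rid in ref_ids:
        stem = ref_stems[rid]
        # closest reference neighbor R' by stem distance
        others = [o for o in ref_ids if o != rid]
        neighbor = min(
            others, key=lambda o: float(np.linalg.norm(ref_stems[o] - stem))
        )
        d_min = float(
            kdtrees[neighbor].query(cloud.coords[ref_pts[rid]])[0].mean()
        )
        outcome.d_min[rid] = d_min
        n1 = len(ref_pts[rid])
        n2 = len(ref_pts[neighbor])

        candidates = sorted(
            (
                (float(np.linalg.norm(pred_stems[pid] - stem)), pid)
                for pid in pred_ids
                if pid not in consumed
            ),
        )
        verdict = "FN"
        for dist, pid in candidates:
            if dist > d_min:
                break
            n_star = len(pred_pts[pid])
            if n_star > n1 and n_star >= n1 + n2:
                consumed.add(pid)
                outcome.seg_verdicts[pid] = "FP"
                outcome.n_fp += 1
                if retry_after_fp:
                    continue
                break
            consumed.add(pid)
            outcome.seg_verdicts[pid] = "TP"
            outcome.matches[rid] = pid
            verdict = "TP"
            break
        outcome.ref_verdicts[rid] = verdict
        if verdict == "TP":
            outcome.n_tp += 1
        else:
            outcome.n_fn += 1
    return outcome


def compute_metrics(outcome: MatchOutcome, n_ref: int) -> Metrics:
    """Evaluate DR, E_COM, E_OM; undefined ratios come back as None."""
    if n_ref < 1:
        raise ForestSegError("metrics need at least one reference tree")
    tp, fn, fp = outcome.n_tp, outcome.n_fn, outcome.n_fp
    return Metrics(
        dr=tp / n_ref,
        e_com=fn / (tp + fn) if tp + fn else None,
        e_om=fp / (tp + fp) if tp + fp else None,
        n_tp=tp,
        n_fn=fn,
        n_fp=fp,
        n_ref=n_ref,
    )


def report_dict(outcome: MatchOutcome, metrics: Metrics) -> dict:
    """JSON-ready validation report."""
    return {
        "n_ref": metrics.n_ref,
        "n_tp": metrics.n_tp,
        "n_fp": metrics.n_fp,
        "n_fn": metrics.n_fn,
        "dr": metrics.dr,
        "e_com": metrics.e_com,
        "e_om": metrics.e_om,
        "per_tree": [
            {
                "ref_id": rid,
                "verdict": outcome.ref_verdicts[rid],
                "matched_segment": outcome.matches.get(rid),
                "d_min": outcome.d_min[rid],
            }
            for rid in sorted(outcome.ref_verdicts)
        ],
    }


DEFAULT_GRID = {
    "eps_trunk": (0.05, 0.1, 0.2, 0.3, 0.4, 0.5),
    "eps_cylinder": (0.4, 0.65, 0.9, 1.15, 1.4),
    "d_star": (0.3, 0.6, 0.87, 1.2, 1.5),
}


def sensitivity_sweep(
    cloud: PointCloud,
    reference: SegmentationResult,
    grid: dict[str, tuple] | None = None,
    trajectory: Trajectory | None = None,
    pre_params: PreprocessParams | None = None,
    base_params: SegmentationParams | None = None,
    prep: PreprocessedScene | None = None,
) -> tuple[pd.DataFrame, pd.Series | None]:
    """Rerun the pipeline over a (eps_trunk, eps_cylinder, d*) grid.

    Preprocessing does not depend on the swept parameters and is computed
    once. Returns the full table and the best row (highest DR; ties broken
    by lower E_OM then lower E_COM). Grid points where the pipeline fails
    are recorded as failed rows.
    """
    grid = {**DEFAULT_GRID, **(grid or {})}
    base = base_params or SegmentationParams()
    if prep is None:
        prep = preprocess_scene(cloud, trajectory, pre_params)
    rows = []
    for et, ec, ds in product(
        grid["eps_trunk"], grid["eps_cylinder"], grid["d_star"]
    ):
        row = {"eps_trunk": et, "eps_cylinder": ec, "d_star": ds}
        try:
            params = SegmentationParams(
                **{
                    **base.__dict__,
                    "eps_trunk": et,
                    "eps_cylinder": ec,
                    "noise_threshold": ds,
                }
            )
            result = segment_preprocessed(prep, params)
            outcome = match_trees(reference, result, cloud)
            m = compute_metrics(outcome, len(reference.tree_locations)
                                or outcome.n_tp + outcome.n_fn)
            row.update(
                n_trees=result.n_trees,
                n_tp=m.n_tp,
                n_fp=m.n_fp,
                n_fn=m.n_fn,
                dr=m.dr,
                e_com=m.e_com,
                e_om=m.e_om,
                error="",
            )
        except ForestSegError as exc:
            row.update(
                n_trees=np.nan, n_tp=np.nan, n_fp=np.nan, n_fn=np.nan,
                dr=np.nan, e_com=np.nan, e_om=np.nan, error=str(exc),
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table[table["error"] == ""].copy()
    best = None
    if len(ok):
        ok = ok.sort_values(
            ["dr", "e_om", "e_com"], ascending=[False, True, True],
            kind="stable",
        )
        best = ok.iloc[0]
    return table, best
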