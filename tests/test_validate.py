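from fractions import Fraction

import numpy as np
import pytest

from forestseg.errors import AlignmentError, ForestSegError
from forestseg.io_formats import PointCloud
from forestseg.merge_filter import SegmentationResult
from forestseg.synthetic_forest import truth_to_reference
from forestseg.validate import (
    MatchOutcome,
    compute_metrics,
    match_trees,
    sensitivity_sweep,
    stems_from_labels,
)
from conftest import small_scene


def blob(rng, center, n, spread=0.3):
    return rng.normal(center, spread, size=(n, 3))


def two_tree_setup(rng, n_star, n1=30, n2=25):
    """Reference trees at x=0 and x=10; one algorithm tree of n_star points
    at the first stem. Returns (reference, predicted, cloud)."""
    t1 = blob(rng, [0, 0, 2], n1)
    t2 = blob(rng, [10, 0, 2], n2)
    alg = blob(rng, [0, 0, 2], n_star)
    coords = np.vstack([t1, t2, alg])
    ref_labels = np.concatenate(
        [np.full(n1, 1), np.full(n2, 2), np.zeros(n_star, int)]
    )
    pred_labels = np.concatenate(
        [np.zeros(n1 + n2, int), np.full(n_star, 1)]
    )
    cloud = PointCloud(coords)
    reference = SegmentationResult(ref_labels, {1: (0.0, 0.0), 2: (10.0, 0.0)})
    predicted = SegmentationResult(pred_labels, {1: (0.0, 0.0)})
    return reference, predicted, cloud


class TestMatchingRules:
    def test_excess_points_but_below_both_trees_is_tp(self, rng):
        ref, pred, cloud = two_tree_setup(rng, n_star=50)
        out = match_trees(ref, pred, cloud)  # 50 > 30 and 50 < 55
        assert out.ref_verdicts[1] == "TP"
        assert out.seg_verdicts[1] == "TP"

    def test_segment_straddling_two_trees_is_fp(self, rng):
        ref, pred, cloud = two_tree_setup(rng, n_star=60)
        out = match_trees(ref, pred, cloud)  # 60 >= 55
        assert out.seg_verdicts[1] == "FP"
        assert out.ref_verdicts[1] == "FN"  # no other candidate remains
        assert out.n_fp == 1

    def test_incomplete_segment_is_tp(self, rng):
        ref, pred, cloud = two_tree_setup(rng, n_star=20)
        out = match_trees(ref, pred, cloud)  # 20 <= 30
        assert out.ref_verdicts[1] == "TP"

    def test_far_segment_is_out_of_reach(self, rng):
        ref, pred, cloud = two_tree_setup(rng, n_star=20)
        # push the algorithm stem far beyond d_min (~10 m here)
        pred.tree_locations[1] = (500.0, 0.0)
        out = match_trees(ref, pred, cloud)
        assert out.ref_verdicts[1] == "FN"
        assert out.seg_verdicts[1] == "unmatched"

    def test_consumed_segments_are_never_rematched(self, rng):
        # one algorithm tree equidistant from both reference stems and inside
        # both search radii: once reference 1 consumes it, reference 2 cannot
        ref, pred, cloud = two_tree_setup(rng, n_star=20)
        pred.tree_locations[1] = (5.0, 0.0)
        out = match_trees(ref, pred, cloud)
        assert out.ref_verdicts[1] == "TP"
        assert out.ref_verdicts[2] == "FN"
        assert out.n_tp == 1

    def test_single_reference_tree_has_no_dmin(self, rng):
        coords = blob(rng, [0, 0, 0], 10)
        ref = SegmentationResult(np.full(10, 1), {1: (0.0, 0.0)})
        pred = SegmentationResult(np.full(10, 1), {1: (0.0, 0.0)})
        with pytest.raises(ForestSegError, match="d_min"):
            match_trees(ref, pred, PointCloud(coords))

    def test_mismatched_clouds_raise_alignment_error(self, rng):
        ref, pred, cloud = two_tree_setup(rng, n_star=20)
        short = SegmentationResult(pred.labels[:-1], pred.tree_locations)
        with pytest.raises(AlignmentError):
            match_trees(ref, short, cloud)


class TestMetrics:
    def test_detection_rate_formula(self):
        out = MatchOutcome({}, {}, {}, {}, n_tp=8, n_fp=0, n_fn=2)
        m = compute_metrics(out, n_ref=10)
        assert m.dr == 0.8
        assert m.e_com == 0.2

    def test_omission_error_formula(self):
        out = MatchOutcome({}, {}, {}, {}, n_tp=8, n_fp=1, n_fn=0)
        m = compute_metrics(out, n_ref=10)
        assert m.e_om == pytest.approx(1 / 9)

    def test_random_tuples_match_rational_oracle(self, rng):
        for _ in range(20):
            tp, fn, fp = (int(v) for v in rng.integers(0, 30, 3))
            n_ref = tp + fn if tp + fn > 0 else 1
            out = MatchOutcome({}, {}, {}, {}, n_tp=tp, n_fp=fp, n_fn=fn)
            m = compute_metrics(out, n_ref)
            assert m.dr == pytest.approx(float(Fraction(tp, n_ref)), abs=1e-15)
            if tp + fn:
                assert m.e_com == pytest.approx(
                    float(Fraction(fn, tp + fn)), abs=1e-15
                )
            else:
                assert m.e_com is None
            if tp + fp:
                assert m.e_om == pytest.approx(
                    float(Fraction(fp, tp + fp)), abs=1e-15
                )
            else:
                assert m.e_om is None

    def test_zero_reference_is_invalid(self):
        out = MatchOutcome({}, {}, {}, {})
        with pytest.raises(ForestSegError):
            compute_metrics(out, n_ref=0)

    def test_dr_plus_ecom_is_one_when_all_trees_verdicted(self, rng):
        ref, pred, cloud = two_tree_setup(rng, n_star=50)
        out = match_trees(ref, pred, cloud)
        m = compute_metrics(out, n_ref=2)
        assert m.dr + m.e_com == pytest.approx(1.0, abs=1e-15)


class TestInvariances:
    def test_metrics_invariant_under_rigid_motion(self):
        scene = small_scene(seed=5)
        ref = truth_to_reference(scene)
        # a deliberately imperfect prediction: drop one tree
        pred_labels = np.where(ref.labels == 2, 0, ref.labels)
        pred = SegmentationResult(
            pred_labels,
            {k: v for k, v in ref.tree_locations.items() if k != 2},
        )
        base = compute_metrics(
            match_trees(ref, pred, scene.cloud), len(ref.tree_locations)
        )

        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        xy = scene.cloud.xy @ R.T + np.array([100.0, -40.0])
        moved = PointCloud(np.column_stack([xy, scene.cloud.z]))

        def move(stems):
            return {
                k: tuple(np.array(v) @ R.T + np.array([100.0, -40.0]))
                for k, v in stems.items()
            }

        ref_m = SegmentationResult(ref.labels, move(ref.tree_locations))
        pred_m = SegmentationResult(pred.labels, move(pred.tree_locations))
        rotated = compute_metrics(
            match_trees(ref_m, pred_m, moved), len(ref.tree_locations)
        )
        assert (base.dr, base.e_com, base.e_om) == (
            rotated.dr,
            rotated.e_com,
            rotated.e_om,
        )


class TestStemsFromLabels:
    def test_slab_centroid_when_available(self, rng):
        slab_pts = np.column_stack(
            [rng.normal([3, 4], 0.01, (50, 2)), np.full(50, 1.2)]
        )
        crown_pts = np.column_stack(
            [rng.normal([5, 6], 0.5, (50, 2)), np.full(50, 7.0)]
        )
        cloud = PointCloud(np.vstack([slab_pts, crown_pts]))
        stems = stems_from_labels(cloud, np.full(100, 1))
        np.testing.assert_allclose(stems[1], (3, 4), atol=0.05)


class TestSweep:
    def test_degenerate_grid_equals_direct_run(self):
        scene = small_scene(seed=1)
        ref = truth_to_reference(scene)
        grid = {"eps_trunk": (0.1,), "eps_cylinder": (0.9,), "d_star": (0.87,)}
        table, best = sensitivity_sweep(
            scene.cloud, ref, grid, trajectory=scene.trajectory
        )
        assert len(table) == 1
        from forestseg.pipeline import segment_cloud

        direct = segment_cloud(scene.cloud, scene.trajectory)
        out = match_trees(ref, direct, scene.cloud)
        m = compute_metrics(out, len(ref.tree_locations))
        row = table.iloc[0]
        assert (row.dr, row.e_com, row.e_om) == (m.dr, m.e_com, m.e_om)
        assert best is not None and best.dr == m.dr

    def test_trunk_merging_degrades_detection(self, rng):
        # two stems 0.4 m apart merge at large eps_trunk
        scene = small_scene(
            seed=2,
            n_trees=2,
            min_spacing=0.4,
            stem_positions=((8.8, 9.0), (9.2, 9.0)),
            trunk_radius_range=(0.08, 0.10),
            trunk_ring_sigma=0.01,
            n_shrubs=0,
            n_outliers=0,
        )
        ref = truth_to_reference(scene)
        grid = {"eps_trunk": (0.1, 0.5), "eps_cylinder": (0.9,), "d_star": (0.87,)}
        table, _ = sensitivity_sweep(
            scene.cloud, ref, grid, trajectory=scene.trajectory
        )
        dr = {row.eps_trunk: row.dr for row in table.itertuples()}
        assert dr[0.5] <= dr[0.1]

    def test_failed_grid_point_is_recorded_not_raised(self):
        scene = small_scene(seed=1)
        ref = truth_to_reference(scene)
        # an absurdly small eps_trunk finds no clusters -> failed row
        grid = {
            "eps_trunk": (1e-6, 0.1),
            "eps_cylinder": (0.9,),
            "d_star": (0.87,),
        }
        table, best = sensitivity_sweep(
            scene.cloud, ref, grid, trajectory=scene.trajectory
        )
        failed = table[table.error != ""]
        assert len(failed) == 1 and len(table) == 2
        assert best is not None and best.eps_trunk == 0.1
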