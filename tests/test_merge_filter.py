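import numpy as np
import pytest

from forestseg.errors import UnmergeableError
from forestseg.io_formats import PointCloud
from forestseg.merge_filter import (
    Segment,
    assign_discarded,
    classify_continuity,
    finalize,
    merge_floating,
)
from forestseg.trunk_detect import SegmentationParams

PARAMS = SegmentationParams()


def column(rng, xy, z_lo, z_hi, n=200, spread=0.05):
    return np.column_stack(
        [rng.normal(xy, spread, (n, 2)), rng.uniform(z_lo, z_hi, n)]
    )


class TestContinuity:
    def test_contiguous_column_from_ground_is_connected(self):
        z = np.arange(0.1, 5.0, 0.125)
        cloud = PointCloud(np.column_stack([np.zeros((len(z), 2)), z]))
        assert classify_continuity(cloud, np.arange(len(z)), PARAMS)

    def test_high_blob_is_floating(self):
        z = np.linspace(4.0, 6.0, 40)
        cloud = PointCloud(np.column_stack([np.zeros((40, 2)), z]))
        assert not classify_continuity(cloud, np.arange(40), PARAMS)

    def test_two_empty_bins_inside_extent_mean_floating(self):
        # occupied near ground and again above a 0.5-1.25 m void
        z = np.concatenate([np.linspace(0.0, 0.45, 10), np.linspace(1.3, 3.0, 20)])
        cloud = PointCloud(np.column_stack([np.zeros((30, 2)), z]))
        assert not classify_continuity(cloud, np.arange(30), PARAMS)

    def test_single_empty_bin_is_tolerated(self):
        z = np.concatenate([np.linspace(0.0, 0.45, 10), np.linspace(0.8, 3.0, 20)])
        cloud = PointCloud(np.column_stack([np.zeros((30, 2)), z]))
        assert classify_continuity(cloud, np.arange(30), PARAMS)

    def test_generator_style_columns_and_blobs_agree_with_truth(self, rng):
        trunk = column(rng, (0, 0), 0.0, 4.0)
        crown_blob = rng.normal([3.0, 0, 6.0], 0.3, size=(80, 3))
        cloud = PointCloud(np.vstack([trunk, crown_blob]))
        assert classify_continuity(cloud, np.arange(200), PARAMS)
        assert not classify_continuity(cloud, np.arange(200, 280), PARAMS)


class TestMergeFloating:
    def make_segments(self, rng):
        a = column(rng, (0, 0), 0, 4)
        b = column(rng, (8, 0), 0, 4)
        blob = rng.normal([0.5, 0, 4.5], 0.1, size=(40, 3))
        cloud = PointCloud(np.vstack([a, b, blob]))
        segments = [
            Segment(1, np.arange(200), True, (0.0, 0.0)),
            Segment(2, np.arange(200, 400), True, (8.0, 0.0)),
            Segment(3, np.arange(400, 440), False, (0.0, 0.0)),
        ]
        return cloud, segments

    def test_floating_blob_joins_nearest_tree(self, rng):
        cloud, segments = self.make_segments(rng)
        trees = merge_floating(segments, cloud)
        assert len(trees) == 2
        sizes = {t.tree_id: len(t.point_indices) for t in trees}
        assert sizes == {1: 240, 2: 200}

    def test_equidistant_tie_goes_to_lower_tree_id(self):
        cloud = PointCloud(
            [[0, 0, 0], [10, 0, 0], [5, 0, 0]]  # blob exactly between
        )
        segments = [
            Segment(1, np.array([0]), True, (0.0, 0.0)),
            Segment(2, np.array([1]), True, (10.0, 0.0)),
            Segment(3, np.array([2]), False, (0.0, 0.0)),
        ]
        trees = merge_floating(segments, cloud)
        assert sorted(trees[0].point_indices.tolist()) == [0, 2]

    def test_no_ground_connected_segment_is_an_error(self):
        cloud = PointCloud([[0, 0, 5], [1, 0, 5]])
        segments = [Segment(1, np.array([0, 1]), False, (0.0, 0.0))]
        with pytest.raises(UnmergeableError):
            merge_floating(segments, cloud)

    def test_random_blobs_match_minimum_distance_oracle(self, rng):
        centers = rng.uniform(0, 40, size=(5, 2))
        cols = [column(rng, c, 0, 4) for c in centers]
        cloud_parts = list(cols)
        segments = [
            Segment(i + 1, np.arange(i * 200, (i + 1) * 200), True, tuple(c))
            for i, c in enumerate(centers)
        ]
        blob_ranges = []
        offset = 1000
        for _ in range(30):
            c = rng.uniform(0, 40, size=2)
            blob = rng.normal([c[0], c[1], 5.0], 0.2, size=(20, 3))
            cloud_parts.append(blob)
            blob_ranges.append(np.arange(offset, offset + 20))
            offset += 20
        cloud = PointCloud(np.vstack(cloud_parts))
        floating = [
            Segment(100 + i, r, False, (0.0, 0.0))
            for i, r in enumerate(blob_ranges)
        ]
        trees = merge_floating(segments + floating, cloud)
        # oracle: each blob point set joins the tree with min pairwise distance
        expected_sizes = {i + 1: 200 for i in range(5)}
        for r in blob_ranges:
            dmins = []
            for i in range(5):
                tree_pts = cloud.coords[i * 200 : (i + 1) * 200]
                d = np.sqrt(
                    ((cloud.coords[r][:, None] - tree_pts[None]) ** 2).sum(-1)
                ).min()
                dmins.append(d)
            expected_sizes[int(np.argmin(dmins)) + 1] += 20
        got_sizes = {t.tree_id: len(t.point_indices) for t in trees}
        assert got_sizes == expected_sizes


class TestAssignDiscarded:
    def setup_scene(self):
        cloud = PointCloud(
            [[0, 0, 0], [0, 0, 1], [10, 0, 0], [0.5, 0, 0.0], [5, 0, 0], [0, 1.2, 0]]
        )
        segments = [
            Segment(1, np.array([0, 1]), True, (0.0, 0.0)),
            Segment(2, np.array([2]), True, (10.0, 0.0)),
        ]
        return cloud, segments

    def test_point_below_threshold_is_assigned(self):
        cloud, segments = self.setup_scene()
        assignments, noise = assign_discarded(
            np.array([3]), segments, cloud, d_star=0.87
        )
        assert assignments[1].tolist() == [3] and len(noise) == 0

    def test_point_beyond_threshold_is_noise(self):
        cloud, segments = self.setup_scene()
        assignments, noise = assign_discarded(
            np.array([5]), segments, cloud, d_star=0.87
        )
        assert noise.tolist() == [5]

    def test_threshold_is_strict(self):
        cloud, segments = self.setup_scene()
        # point 3 sits exactly 0.5 m from segment 1
        _, noise = assign_discarded(np.array([3]), segments, cloud, d_star=0.5)
        assert noise.tolist() == [3]

    def test_noise_shrinks_monotonically_with_threshold(self, rng):
        cloud = PointCloud(rng.uniform(0, 10, size=(200, 3)))
        segments = [
            Segment(1, np.arange(0, 50), True, (0.0, 0.0)),
            Segment(2, np.arange(50, 100), True, (5.0, 5.0)),
        ]
        discarded = np.arange(100, 200)
        previous = None
        for d_star in (0.2, 0.5, 1.0, 2.0, 5.0):
            _, noise = assign_discarded(discarded, segments, cloud, d_star)
            current = set(noise.tolist())
            if previous is not None:
                assert current <= previous
            previous = current


class TestFinalize:
    def test_two_tree_labels_are_contiguous(self):
        segments = [
            Segment(7, np.array([0, 1]), True, (5.0, 0.0)),
            Segment(3, np.array([2, 3]), True, (1.0, 0.0)),
        ]
        result = finalize(segments, {}, np.array([4]), n_points=5)
        # ascending stem x: the segment at x=1 becomes tree 1
        assert result.labels.tolist() == [2, 2, 1, 1, 0]
        assert result.tree_locations[1] == (1.0, 0.0)

    def test_no_noise_means_no_zero_labels(self):
        segments = [Segment(1, np.array([0, 1, 2]), True, (0.0, 0.0))]
        result = finalize(segments, {}, np.empty(0, int), n_points=3)
        assert (result.labels > 0).all()

    def test_label_counts_match_segment_sizes(self, rng):
        sizes = [30, 50, 20]
        start = 0
        segments = []
        assignments = {}
        for i, s in enumerate(sizes):
            segments.append(
                Segment(i + 1, np.arange(start, start + s), True, (float(i), 0.0))
            )
            start += s
        assignments[2] = np.arange(start, start + 7)  # discarded joins tree 2
        result = finalize(segments, assignments, np.empty(0, int), start + 7)
        counts = np.bincount(result.labels)
        assert counts[1:].tolist() == [30, 57, 20]
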