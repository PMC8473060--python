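import numpy as np
import pytest

from forestseg.pipeline import segment_cloud
from forestseg.synthetic_forest import ForestSpec, generate, truth_to_reference

# A small, fast stand used by most scene-level tests: 5 trees on an 18 m
# plot with the same per-area densities as the default 20-tree stand.
SMALL_KW = dict(
    n_trees=5,
    plot_size=(18.0, 18.0),
    min_spacing=4.0,
    points_per_tree=3000,
    trunk_radius_range=(0.08, 0.12),
    trunk_height_range=(3.0, 4.0),
    crown_radius_range=(0.8, 1.2),
    crown_depth_range=(1.5, 2.5),
    ground_point_density=8.0,
    n_shrubs=3,
    n_outliers=60,
)


def small_scene(seed=0, **overrides):
    return generate(ForestSpec(seed=seed, **{**SMALL_KW, **overrides}))


@pytest.fixture(scope="session")
def stand_scene():
    """The packaged 20-tree synthetic stand (generator defaults, seed 0)."""
    return generate(ForestSpec(seed=0))


@pytest.fixture(scope="session")
def stand_result(stand_scene):
    return segment_cloud(stand_scene.cloud, stand_scene.trajectory)


@pytest.fixture(scope="session")
def stand_reference(stand_scene):
    return truth_to_reference(stand_scene)


@pytest.fixture(scope="session")
def five_tree_scene():
    return small_scene(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
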