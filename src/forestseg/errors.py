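"""Exception hierarchy for the segmentation pipeline.

Every anticipated failure mode raises a subclass of :class:`ForestSegError`
so callers (and the CLI) can distinguish pipeline diagnostics from bugs.
"""


class ForestSegError(Exception):
    """Base class for all forestseg errors."""


class FormatError(ForestSegError):
    """A file could not be parsed; the message names the offending record."""


class EmptyCloudError(ForestSegError):
    """An input point cloud contains no points."""


class CapacityError(ForestSegError):
    """Output format cannot represent the data (e.g. > 65535 tree ids)."""


class InsufficientTrajectoryError(ForestSegError):
    """A trajectory has fewer than three positions."""


class DegenerateHullError(ForestSegError):
    """Trajectory XY positions are collinear; no convex-hull polygon exists."""


class CannotBuildDTMError(ForestSegError):
    """No ground points are available to interpolate a terrain model."""


class NoTrunkLayerError(ForestSegError):
    """The trunk-layer slab of the normalized cloud is empty."""


class NoTreesDetectedError(ForestSegError):
    """Trunk-layer DBSCAN produced zero clusters."""


class DegenerateRadiusError(ForestSegError):
    """Two trunk centroids coincide, so a candidate radius would be zero."""


class UnmergeableError(ForestSegError):
    """A scene has floating segments but no ground-connected segment."""


class InfeasibleSpecError(ForestSegError):
    """Synthetic-forest rejection sampling could not honor min_spacing."""


class AlignmentError(ForestSegError):
    """Two labelings do not refer to the same point cloud."""
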