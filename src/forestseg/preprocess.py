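"""Outlier gating and height normalization.

The raw cloud of a walking survey contains long-range returns far outside the
plot. A polygon built from the convex hull of the scanner trajectory gates
them out: a point survives iff its XY position lies inside the polygon or
within a buffer distance of its boundary.

Height normalization then removes terrain relief. A grayscale morphological
opening (erosion then dilation) of the minimum-z raster separates ground from
vegetation; ground points are interpolated by inverse distance weighting
(IDW) onto a regular grid — the digital terrain model (DTM) — and each
point's z is replaced by its height above the bilinearly interpolated DTM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, Polygon

from .errors import CannotBuildDTMError, DegenerateHullError
from .io_formats import PointCloud, Trajectory

__all__ = [
    "PreprocessParams",
    "DTMGrid",
    "hull_retention_mask",
    "hull_outlier_filter",
    "ground_mask",
    "morphological_ground_filter",
    "build_dtm",
    "normalize_heights",
]

log = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    """Tunable knobs of the outlier filter and DTM construction.

    All lengths are meters. Defaults are conventional for centimeter-accuracy
    terrestrial clouds under closed canopy.
    """

    hull_buffer: float = 1.0  # retain points within this distance of the hull
    morph_window: float = 2.0  # structuring-element width of the opening
    morph_height_tol: float = 0.3  # max residual above opened surface = ground
    idw_power: float = 2.0
    idw_neighbors: int = 8
    dtm_cell: float = 0.5

    def __post_init__(self) -> None:
        if self.hull_buffer < 0:
            raise ValueError("hull_buffer must be >= 0")
        for name in (
            "morph_window",
            "morph_height_tol",
            "idw_power",
            "idw_neighbors",
            "dtm_cell",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class DTMGrid:
    """Regular XY grid of ground elevations (cell centers at origin + (i+1/2)h)."""

    origin: tuple[float, float]
    cell_size: float
    elevations: np.ndarray  # shape (ny, nx), row i = y index, col j = x index

    def __post_init__(self) -> None:
        self.elevations = np.asarray(self.elevations, dtype=np.float64)
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.elevations.ndim != 2:
            raise ValueError("elevations must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevations.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.elevations.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.cell_size
        return xs, ys

    def interpolate(self, xy: np.ndarray) -> np.ndarray:
        """Bilinear elevation at arbitrary XY; clamped beyond the cell centers."""
        xy = np.atleast_2d(np.asarray(xy, dtype=np.float64))
        ny, nx = self.elevations.shape
        # continuous index space where integer k sits on cell-center k
        u = (xy[:, 0] - self.origin[0]) / self.cell_size - 0.5
        v = (xy[:, 1] - self.origin[1]) / self.cell_size - 0.5
        u = np.clip(u, 0.0, nx - 1.0)
        v = np.clip(v, 0.0, ny - 1.0)
        j0 = np.clip(np.floor(u).astype(int), 0, max(nx - 2, 0))
        i0 = np.clip(np.floor(v).astype(int), 0, max(ny - 2, 0))
        j1 = np.minimum(j0 + 1, nx - 1)
        i1 = np.minimum(i0 + 1, ny - 1)
        fu = u - j0
        fv = v - i0
        e = self.elevations
        return (
            e[i0, j0] * (1 - fu) * (1 - fv)
            + e[i0, j1] * fu * (1 - fv)
            + e[i1, j0] * (1 - fu) * fv
            + e[i1, j1] * fu * fv
        )

    def to_esri_ascii(self, path) -> None:
        """Export as an ESRI ASCII raster (row 0 of the file = northernmost)."""
        ny, nx = self.elevations.shape
        with open(path, "w") as fh:
            fh.write(f"ncols {nx}\n")
            fh.write(f"nrows {ny}\n")
            fh.write(f"xllcorner {self.origin[0]:.6f}\n")
            fh.write(f"yllcorner {self.origin[1]:.6f}\n")
            fh.write(f"cellsize {self.cell_size:.6f}\n")
            fh.write("NODATA_value -9999\n")
            np.savetxt(fh, self.elevations[::-1], fmt="%.4f")


# ---------------------------------------------------------------------------
# Trajectory-hull outlier filter
# ---------------------------------------------------------------------------


def trajectory_hull(traj: Trajectory) -> Polygon:
    """Convex hull polygon of the trajectory's XY positions."""
    hull = MultiPoint([tuple(p) for p in traj.xy]).convex_hull
    if not isinstance(hull, Polygon):
        raise DegenerateHullError(
            "trajectory XY positions are collinear; convex hull is degenerate"
        )
    return hull


def hull_retention_mask(
    cloud: PointCloud, traj: Trajectory, buffer: float
) -> np.ndarray:
    """Boolean mask of points inside the trajectory hull or within ``buffer``."""
    hull = trajectory_hull(traj)
    pts = shapely.points(cloud.xy)
    return shapely.distance(pts, hull) <= buffer


def hull_outlier_filter(
    cloud: PointCloud, traj: Trajectory, buffer: float
) -> PointCloud:
    """Remove far-range points beyond ``buffer`` of the trajectory hull."""
    mask = hull_retention_mask(cloud, traj, buffer)
    log.info("hull filter removed %d / %d points", int((~mask).sum()), len(cloud))
    return cloud.subset(mask)


# ---------------------------------------------------------------------------
# Morphological ground filter
# ---------------------------------------------------------------------------


def _min_z_raster(
    cloud: PointCloud, cell: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[float, float]]:
    origin = cloud.xy.min(axis=0)
    ij = np.floor((cloud.xy - origin) / cell).astype(int)
    nx = ij[:, 0].max() + 1
    ny = ij[:, 1].max() + 1
    raster = np.full((ny, nx), np.inf)
    np.minimum.at(raster, (ij[:, 1], ij[:, 0]), cloud.z)
    empty = ~np.isfinite(raster)
    if empty.any():
        # fill cells with no returns from their nearest occupied cell
        _, (fi, fj) = ndimage.distance_transform_edt(empty, return_indices=True)
        raster = raster[fi, fj]
    return raster, ij[:, 1], ij[:, 0], tuple(origin)


def ground_mask(cloud: PointCloud, params: PreprocessParams) -> np.ndarray:
    """Boolean ground mask from a grayscale opening of the min-z raster.

    The raster uses a sub-grid of a quarter of the structuring-element width
    so the opening acts on several cells; a point is ground iff its height
    above the opened surface of its own cell is at most ``morph_height_tol``.
    """
    if len(cloud) == 0:
        return np.zeros(0, dtype=bool)
    cell = params.morph_window / 4.0
    raster, rows, cols, _ = _min_z_raster(cloud, cell)
    half_cells = max(1, int(round(params.morph_window / (2.0 * cell))))
    size = 2 * half_cells + 1
    opened = ndimage.grey_opening(raster, size=(size, size), mode="nearest")
    residual = cloud.z - opened[rows, cols]
    mask = residual <= params.morph_height_tol
    if not mask.any():
        log.warning("morphological filter found no ground points")
    return mask


def morphological_ground_filter(
    cloud: PointCloud, params: PreprocessParams
) -> tuple[PointCloud, PointCloud]:
    """Partition a cloud into (ground, nonground) by morphological opening."""
    mask = ground_mask(cloud, params)
    return cloud.subset(mask), cloud.subset(~mask)


# ---------------------------------------------------------------------------
# DTM construction and normalization
# ---------------------------------------------------------------------------


def build_dtm(
    ground: PointCloud,
    params: PreprocessParams,
    extent: tuple[float, float, float, float] | None = None,
) -> DTMGrid:
    """IDW-interpolate ground points onto a regular grid.

    Each cell center's elevation is sum(w_k z_k) / sum(w_k) over the
    ``idw_neighbors`` nearest ground points with w_k = 1 / d_k**idw_power;
    a ground point closer than 1e-9 m to the center supplies its z directly.
    ``extent`` is (xmin, ymin, xmax, ymax); default is the ground bounding box.
    """
    if len(ground) == 0:
        raise CannotBuildDTMError("no ground points to interpolate")
    if extent is None:
        (xmin, ymin), (xmax, ymax) = ground.xy.min(0), ground.xy.max(0)
    else:
        xmin, ymin, xmax, ymax = extent
    h = params.dtm_cell
    nx = max(1, int(np.ceil((xmax - xmin) / h)))
    ny = max(1, int(np.ceil((ymax - ymin) / h)))
    xs = xmin + (np.arange(nx) + 0.5) * h
    ys = ymin + (np.arange(ny) + 0.5) * h
    gx, gy = np.meshgrid(xs, ys)
    centers = np.column_stack([gx.ravel(), gy.ravel()])

    tree = cKDTree(ground.xy)
    k = min(params.idw_neighbors, len(ground))
    dist, idx = tree.query(centers, k=k)
    dist = np.atleast_2d(dist.reshape(len(centers), k))
    idx = idx.reshape(len(centers), k)
    z = ground.z[idx]
    with np.errstate(divide="ignore"):
        w = 1.0 / dist**params.idw_power
    exact = dist[:, 0] < 1e-9
    elev = np.empty(len(centers))
    elev[exact] = z[exact, 0]
    if (~exact).any():
        elev[~exact] = (w[~exact] * z[~exact]).sum(1) / w[~exact].sum(1)
    return DTMGrid((xmin, ymin), h, elev.reshape(ny, nx))


def normalize_heights(cloud: PointCloud, dtm: DTMGrid) -> PointCloud:
    """Replace z by height above the DTM; XY and point order are preserved."""
    ny, nx = dtm.shape
    xmax = dtm.origin[0] + nx * dtm.cell_size
    ymax = dtm.origin[1] + ny * dtm.cell_size
    outside = (
        (cloud.xy[:, 0] < dtm.origin[0])
        | (cloud.xy[:, 0] > xmax)
        | (cloud.xy[:, 1] < dtm.origin[1])
        | (cloud.xy[:, 1] > ymax)
    )
    if outside.any():
        log.info(
            "%d points outside DTM extent; extrapolating from nearest cells",
            int(outside.sum()),
        )
    coords = cloud.coords.copy()
    coords[:, 2] -= dtm.interpolate(cloud.xy)
    return PointCloud(coords, cloud.labels, cloud.source_id)
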