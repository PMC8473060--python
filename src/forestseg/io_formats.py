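"""Reading and writing of point clouds, trajectories, stem maps and reports.

Supported containers
--------------------
* LAS 1.2 (point record format 0) with the per-tree label carried as an
  Extra Bytes dimension named ``tree_id`` (unsigned 16-bit, 0 = noise).
  The codec is self-contained and reads point formats 0-3 written by other
  producers; compressed LAZ is not supported.
* PLY, ascii or binary little-endian, vertex properties x/y/z.
* Plain text XYZ (whitespace- or comma-separated, optional header) and CSV
  with header ``x,y,z,tree_id``.
* Trajectory CSV with columns ``x,y,z`` and optional ``t``.

All coordinates are planimetric meters with z up; no CRS handling.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    CapacityError,
    EmptyCloudError,
    FormatError,
    InsufficientTrajectoryError,
)

__all__ = [
    "PointCloud",
    "Trajectory",
    "read_point_cloud",
    "write_labeled_cloud",
    "read_trajectory",
    "write_stem_map",
    "read_stem_map",
    "write_report",
]


@dataclass
class PointCloud:
    """N x 3 coordinates in meters with optional per-point integer labels.

    Labels follow the convention 0 = noise / unassigned, >= 1 = tree id.
    """

    coords: np.ndarray
    labels: np.ndarray | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (len(self.coords),):
                raise ValueError("labels length must match number of points")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def xy(self) -> np.ndarray:
        return self.coords[:, :2]

    @property
    def z(self) -> np.ndarray:
        return self.coords[:, 2]

    def subset(self, index: np.ndarray) -> "PointCloud":
        labels = None if self.labels is None else self.labels[index]
        return PointCloud(self.coords[index], labels, self.source_id)

    def with_labels(self, labels: np.ndarray) -> "PointCloud":
        return PointCloud(self.coords, labels, self.source_id)


@dataclass
class Trajectory:
    """Ordered scanner positions (a walking path through the plot)."""

    positions: np.ndarray
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if len(self.positions) < 3:
            raise InsufficientTrajectoryError(
                f"trajectory needs >= 3 positions, got {len(self.positions)}"
            )
        if self.timestamps is not None:
            self.timestamps = np.asarray(self.timestamps, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def xy(self) -> np.ndarray:
        return self.positions[:, :2]


# ---------------------------------------------------------------------------
# LAS 1.2 codec (point format 0, extra-bytes tree_id)
# ---------------------------------------------------------------------------

_LAS_HEADER_FMT = "<4sHHLHH8sBB32s32sHHHLLBHL5L3d3d6d"
_LAS_HEADER_SIZE = struct.calcsize(_LAS_HEADER_FMT)  # 227
_LAS_BASE_RECORD_LEN = {0: 20, 1: 28, 2: 26, 3: 34}
_VLR_HEADER_FMT = "<H16sHH32s"


def _las_extra_bytes_vlr() -> bytes:
    """Extra Bytes VLR describing one unsigned-short dimension 'tree_id'."""
    descriptor = struct.pack(
        "<2B B B 32s 4s 24s 24s 24s 24s 24s 32s",
        0,
        0,
        3,  # data type 3 = unsigned short
        0,
        b"tree_id",
        b"",
        b"",
        b"",
        b"",
        b"",
        b"",
        b"tree id (0 = noise)",
    )
    header = struct.pack(
        _VLR_HEADER_FMT, 0, b"LASF_Spec", 4, len(descriptor), b"extra bytes"
    )
    return header + descriptor


def _write_las(cloud: PointCloud, path: Path) -> None:
    labels = cloud.labels
    if labels.min() < 0 or labels.max() > 0xFFFF:
        raise CapacityError(
            f"LAS tree_id is unsigned 16-bit; labels span "
            f"[{labels.min()}, {labels.max()}]"
        )
    scale = 0.001  # millimeter precision covers scanner accuracy
    offset = np.floor(cloud.coords.min(axis=0))
    ints = np.round((cloud.coords - offset) / scale)
    if np.abs(ints).max() >= 2**31:
        raise CapacityError("coordinates exceed int32 range at 1 mm scale")

    point_dtype = np.dtype(
        [
            ("X", "<i4"),
            ("Y", "<i4"),
            ("Z", "<i4"),
            ("intensity", "<u2"),
            ("flags", "u1"),
            ("classification", "u1"),
            ("scan_angle", "i1"),
            ("user_data", "u1"),
            ("point_source", "<u2"),
            ("tree_id", "<u2"),
        ]
    )
    records = np.zeros(len(cloud), dtype=point_dtype)
    records["X"], records["Y"], records["Z"] = ints.astype(np.int32).T
    records["tree_id"] = labels.astype(np.uint16)

    vlr = _las_extra_bytes_vlr()
    offset_to_points = _LAS_HEADER_SIZE + len(vlr)
    mins = cloud.coords.min(axis=0)
    maxs = cloud.coords.max(axis=0)
    header = struct.pack(
        _LAS_HEADER_FMT,
        b"LASF",
        0,
        0,
        0,
        0,
        0,
        b"\0" * 8,
        1,
        2,
        b"forestseg".ljust(32, b"\0"),
        b"forestseg".ljust(32, b"\0"),
        0,
        0,
        _LAS_HEADER_SIZE,
        offset_to_points,
        1,  # one VLR
        0,  # point data format 0
        point_dtype.itemsize,
        len(cloud),
        len(cloud),
        0,
        0,
        0,
        0,
        scale,
        scale,
        scale,
        offset[0],
        offset[1],
        offset[2],
        maxs[0],
        mins[0],
        maxs[1],
        mins[1],
        maxs[2],
        mins[2],
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(vlr)
        fh.write(records.tobytes())


def _read_las(path: Path) -> PointCloud:
    raw = Path(path).read_bytes()
    if len(raw) < _LAS_HEADER_SIZE or raw[:4] != b"LASF":
        raise FormatError(f"{path}: not a LAS file (bad signature)")
    fields = struct.unpack(_LAS_HEADER_FMT, raw[:_LAS_HEADER_SIZE])
    header_size = fields[13]
    offset_to_points = fields[14]
    n_vlrs = fields[15]
    point_format = fields[16] & 0x3F
    record_len = fields[17]
    n_points = fields[18]
    scales = np.array(fields[24:27])
    offsets = np.array(fields[27:30])
    if fields[16] & 0x80:
        raise FormatError(f"{path}: compressed LAZ data is not supported")
    if point_format not in _LAS_BASE_RECORD_LEN:
        raise FormatError(f"{path}: unsupported point format {point_format}")
    base_len = _LAS_BASE_RECORD_LEN[point_format]
    if record_len < base_len:
        raise FormatError(
            f"{path}: record length {record_len} < format minimum {base_len}"
        )

    # scan VLRs for an extra-bytes dimension called tree_id
    tree_id_offset: int | None = None
    cursor = header_size
    vlr_header_size = struct.calcsize(_VLR_HEADER_FMT)
    for _ in range(n_vlrs):
        if cursor + vlr_header_size > len(raw):
            raise FormatError(f"{path}: truncated VLR block")
        _, user_id, record_id, length, _ = struct.unpack(
            _VLR_HEADER_FMT, raw[cursor : cursor + vlr_header_size]
        )
        payload = raw[cursor + vlr_header_size : cursor + vlr_header_size + length]
        cursor += vlr_header_size + length
        if user_id.rstrip(b"\0") == b"LASF_Spec" and record_id == 4:
            extra_cursor = 0
            for i in range(length // 192):
                desc = payload[i * 192 : (i + 1) * 192]
                data_type = desc[2]
                name = desc[4:36].rstrip(b"\0")
                size = {1: 1, 2: 1, 3: 2, 4: 2, 5: 4, 6: 4, 9: 4, 10: 8}.get(
                    data_type, 0
                )
                if name == b"tree_id" and data_type == 3:
                    tree_id_offset = base_len + extra_cursor
                extra_cursor += size

    if n_points == 0:
        raise EmptyCloudError(f"{path}: LAS file contains no points")
    point_bytes = raw[offset_to_points : offset_to_points + n_points * record_len]
    if len(point_bytes) != n_points * record_len:
        raise FormatError(
            f"{path}: expected {n_points} records of {record_len} B, file truncated"
        )
    records = np.frombuffer(point_bytes, dtype=np.uint8).reshape(n_points, record_len)
    xyz_int = np.ascontiguousarray(records[:, :12]).view("<i4").reshape(n_points, 3)
    coords = xyz_int * scales + offsets
    labels = None
    if tree_id_offset is not None and tree_id_offset + 2 <= record_len:
        labels = (
            np.ascontiguousarray(records[:, tree_id_offset : tree_id_offset + 2])
            .view("<u2")
            .reshape(n_points)
            .astype(np.int64)
        )
    return PointCloud(coords, labels, source_id=str(path))


# ---------------------------------------------------------------------------
# PLY codec
# ---------------------------------------------------------------------------

_PLY_TYPES = {
    "char": "i1",
    "int8": "i1",
    "uchar": "u1",
    "uint8": "u1",
    "short": "i2",
    "int16": "i2",
    "ushort": "u2",
    "uint16": "u2",
    "int": "i4",
    "int32": "i4",
    "uint": "u4",
    "uint32": "u4",
    "float": "f4",
    "float32": "f4",
    "double": "f8",
    "float64": "f8",
}


def _read_ply(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise FormatError(f"{path}: not a PLY file")
        fmt = None
        n_vertices = None
        properties: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise FormatError(f"{path}: unterminated PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                if tokens[1] == "vertex":
                    in_vertex = True
                    n_vertices = int(tokens[2])
                elif in_vertex:
                    in_vertex = False  # vertex properties complete
                if tokens[1] != "vertex" and n_vertices is None:
                    raise FormatError(
                        f"{path}: element '{tokens[1]}' precedes vertex element"
                    )
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise FormatError(f"{path}: list property in vertex element")
                properties.append((tokens[2], _PLY_TYPES[tokens[1]]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise FormatError(f"{path}: unsupported PLY format '{fmt}'")
        if n_vertices is None:
            raise FormatError(f"{path}: no vertex element")
        if n_vertices == 0:
            raise EmptyCloudError(f"{path}: PLY file contains no vertices")
        names = [name for name, _ in properties]
        for axis in ("x", "y", "z"):
            if axis not in names:
                raise FormatError(f"{path}: vertex element lacks property '{axis}'")
        if fmt == "ascii":
            data = np.loadtxt(fh, max_rows=n_vertices, ndmin=2)
            if data.shape != (n_vertices, len(properties)):
                raise FormatError(
                    f"{path}: expected {n_vertices} x {len(properties)} ascii "
                    f"vertex table, got {data.shape}"
                )
            coords = data[:, [names.index(a) for a in ("x", "y", "z")]]
        else:
            dtype = np.dtype([(name, "<" + t) for name, t in properties])
            buf = fh.read(n_vertices * dtype.itemsize)
            if len(buf) != n_vertices * dtype.itemsize:
                raise FormatError(f"{path}: truncated binary vertex data")
            table = np.frombuffer(buf, dtype=dtype)
            coords = np.column_stack(
                [table["x"], table["y"], table["z"]]
            ).astype(np.float64)
    return PointCloud(coords, source_id=str(path))


def _write_ply(cloud: PointCloud, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(cloud)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write("end_header\n")
        np.savetxt(fh, cloud.coords, fmt="%.6f")


# ---------------------------------------------------------------------------
# Text formats
# ---------------------------------------------------------------------------


def _parse_xyz_text(path: Path) -> PointCloud:
    rows: list[list[float]] = []
    labels: list[int] = []
    has_labels: bool | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.replace(",", " ").split()
            try:
                values = [float(v) for v in parts]
            except ValueError:
                if lineno == 1:  # tolerated header
                    continue
                raise FormatError(f"{path}: line {lineno}: cannot parse '{text}'")
            if len(values) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 3 columns, got {len(values)}"
                )
            row_has_label = len(values) >= 4
            if has_labels is None:
                has_labels = row_has_label
            elif has_labels != row_has_label:
                raise FormatError(
                    f"{path}: line {lineno}: inconsistent column count"
                )
            rows.append(values[:3])
            if row_has_label:
                labels.append(int(values[3]))
    if not rows:
        raise EmptyCloudError(f"{path}: no points found")
    return PointCloud(
        np.array(rows),
        np.array(labels) if has_labels else None,
        source_id=str(path),
    )


def _write_csv(cloud: PointCloud, path: Path) -> None:
    frame = pd.DataFrame(cloud.coords, columns=["x", "y", "z"])
    frame["tree_id"] = cloud.labels
    frame.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

_READERS = {"las": _read_las, "ply": _read_ply, "xyz": _parse_xyz_text,
            "csv": _parse_xyz_text, "txt": _parse_xyz_text}


def read_point_cloud(path, format: str = "auto") -> PointCloud:
    """Read a point cloud from LAS, PLY, or XYZ/CSV text.

    ``format='auto'`` resolves the container from the file extension.
    Existing ``tree_id`` dimensions (LAS extra bytes, 4th text column) are
    preserved as labels; the LAS classification field is ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "auto":
        format = path.suffix.lstrip(".").lower()
    if format == "laz":
        raise FormatError(f"{path}: compressed LAZ is not supported; decompress to LAS")
    reader = _READERS.get(format)
    if reader is None:
        raise FormatError(f"{path}: unknown point-cloud format '{format}'")
    cloud = reader(path)
    if len(cloud) == 0:
        raise EmptyCloudError(f"{path}: empty point cloud")
    return cloud


def write_labeled_cloud(cloud: PointCloud, path, format: str = "auto"):
    """Write a labeled cloud to LAS (extra dimension ``tree_id``) or CSV."""
    path = Path(path)
    if cloud.labels is None:
        raise ValueError("write_labeled_cloud requires a labeled cloud")
    if format == "auto":
        format = path.suffix.lstrip(".").lower()
    if int(cloud.labels.max(initial=0)) > 0xFFFF:
        raise CapacityError("more than 65535 trees cannot be stored as uint16")
    if format == "las":
        _write_las(cloud, path)
    elif format == "csv":
        _write_csv(cloud, path)
    elif format == "laz":
        raise FormatError("compressed LAZ output is not supported")
    else:
        raise FormatError(f"unknown labeled-cloud format '{format}'")
    return path


def write_point_cloud(cloud: PointCloud, path, format: str = "auto"):
    """Write coordinates only (PLY ascii or XYZ text)."""
    path = Path(path)
    if format == "auto":
        format = path.suffix.lstrip(".").lower()
    if format == "ply":
        _write_ply(cloud, path)
    elif format in ("xyz", "txt"):
        np.savetxt(path, cloud.coords, fmt="%.6f")
    else:
        raise FormatError(f"unknown point-cloud output format '{format}'")
    return path


def read_trajectory(path) -> Trajectory:
    """Read an ordered scanner trajectory from CSV (columns x,y,z[,t])."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        first = open(path).readline()
        header = 0 if any(c.isalpha() for c in first) else None
        frame = pd.read_csv(path, header=header)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise FormatError(f"{path}: {exc}") from exc
    if frame.shape[1] < 3:
        raise FormatError(f"{path}: trajectory needs >= 3 columns (x,y,z)")
    if header == 0:
        cols = [c.strip().lower() for c in frame.columns]
        frame.columns = cols
        missing = [c for c in ("x", "y", "z") if c not in cols]
        if missing:
            raise FormatError(f"{path}: missing trajectory columns {missing}")
        positions = frame[["x", "y", "z"]].to_numpy(float)
        timestamps = frame["t"].to_numpy(float) if "t" in cols else None
    else:
        positions = frame.iloc[:, :3].to_numpy(float)
        timestamps = (
            frame.iloc[:, 3].to_numpy(float) if frame.shape[1] > 3 else None
        )
    if len(positions) < 3:
        raise InsufficientTrajectoryError(
            f"{path}: trajectory has {len(positions)} positions, need >= 3"
        )
    return Trajectory(positions, timestamps)


def write_trajectory(traj: Trajectory, path):
    frame = pd.DataFrame(traj.positions, columns=["x", "y", "z"])
    if traj.timestamps is not None:
        frame["t"] = traj.timestamps
    frame.to_csv(path, index=False, float_format="%.6f")
    return path


def write_stem_map(locations: dict, path):
    """Write per-tree stem locations as CSV ``tree_id,x,y``."""
    rows = [
        {"tree_id": tid, "x": xy[0], "y": xy[1]}
        for tid, xy in sorted(locations.items())
    ]
    pd.DataFrame(rows, columns=["tree_id", "x", "y"]).to_csv(
        path, index=False, float_format="%.6f"
    )
    return path


def read_stem_map(path) -> dict:
    frame = pd.read_csv(path)
    return {
        int(r.tree_id): (float(r.x), float(r.y)) for r in frame.itertuples()
    }


def write_report(report: dict, path):
    """Serialize a validation or stage-count report as JSON."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
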