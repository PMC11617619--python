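"""File formats shared by the pipeline stages.

Point clouds travel as binary little-endian PLY (x/y/z float32 plus any
extra per-vertex properties, e.g. the uint8 ``semantic`` channel) with an
ASCII PCD fallback; density grids as an NPZ container with ``values``,
``origin``, ``spacing`` and optional ``iso`` arrays; masks and fused
frames as PNG; trait tables as CSV. Writers refuse to overwrite existing
files unless forced; readers fail with positioned errors instead of
crashing on truncated input.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .field import DensityField

__all__ = [
    "PLYError",
    "read_ply", "write_ply",
    "read_pcd", "write_pcd",
    "read_rgba", "write_rgba",
    "read_field", "write_field",
    "read_csv_traits", "write_csv_traits",
]

_PLY_TYPES = {
    "float": "<f4", "float32": "<f4", "double": "<f8", "float64": "<f8",
    "uchar": "u1", "uint8": "u1", "char": "i1", "int8": "i1",
    "short": "<i2", "ushort": "<u2", "int": "<i4", "int32": "<i4",
    "uint": "<u4", "uint32": "<u4",
}
_PLY_NAMES = {"<f4": "float", "<f8": "double", "u1": "uchar", "i1": "char",
              "<i2": "short", "<u2": "ushort", "<i4": "int", "<u4": "uint"}


class PLYError(ValueError):
    """Malformed or truncated PLY input."""


def _check_overwrite(path: Path, force: bool) -> None:
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")


def write_ply(path: str | Path, points: np.ndarray,
              attrs: dict[str, np.ndarray] | None = None,
              force: bool = False) -> None:
    """Write a point cloud as binary little-endian PLY.

    ``attrs`` maps extra per-vertex property names to arrays (length N);
    integer arrays are stored at their numpy width, floats as float32.
    """
    path = Path(path)
    _check_overwrite(path, force)
    pts = np.asarray(points, dtype=np.float32).reshape(-1, 3)
    attrs = attrs or {}
    fields = [("x", "<f4"), ("y", "<f4"), ("z", "<f4")]
    for name, arr in attrs.items():
        arr = np.asarray(arr)
        if len(arr) != len(pts):
            raise ValueError(f"attribute {name!r} length mismatch")
        code = "u1" if arr.dtype == np.uint8 else (
            np.dtype(arr.dtype).newbyteorder("<").str.lstrip("=|"))
        if code not in _PLY_NAMES:
            code = "<f4"
        fields.append((name, code))
    rec = np.empty(len(pts), dtype=fields)
    rec["x"], rec["y"], rec["z"] = pts[:, 0], pts[:, 1], pts[:, 2]
    for name, arr in attrs.items():
        rec[name] = np.asarray(arr).astype(rec.dtype[name])
    header = ["ply", "format binary_little_endian 1.0",
              f"element vertex {len(pts)}"]
    header += [f"property {_PLY_NAMES[code]} {name}" for name, code in fields]
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        fh.write(rec.tobytes())


def read_ply(path: str | Path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Read a binary little-endian or ASCII PLY point cloud.

    Returns (N x 3 float coordinates, dict of the remaining per-vertex
    properties) so unknown extra properties survive a round-trip.
    """
    path = Path(path)
    raw = path.read_bytes()
    end = raw.find(b"end_header")
    if not raw.startswith(b"ply") or end < 0:
        raise PLYError(f"{path}: missing PLY header")
    header_end = raw.find(b"\n", end) + 1
    lines = raw[:end].decode("ascii", "replace").splitlines()
    fmt = None
    n_vertex = None
    fields: list[tuple[str, str]] = []
    in_vertex = False
    for ln in lines[1:]:
        parts = ln.split()
        if not parts or parts[0] == "comment":
            continue
        if parts[0] == "format":
            fmt = parts[1]
        elif parts[0] == "element":
            in_vertex = parts[1] == "vertex"
            if in_vertex:
                n_vertex = int(parts[2])
        elif parts[0] == "property" and in_vertex:
            if parts[1] == "list":
                raise PLYError(f"{path}: list properties unsupported")
            if parts[1] not in _PLY_TYPES:
                raise PLYError(f"{path}: unknown property type {parts[1]!r}")
            fields.append((parts[2], _PLY_TYPES[parts[1]]))
    if n_vertex is None:
        raise PLYError(f"{path}: no vertex element")
    if fmt == "binary_little_endian":
        dtype = np.dtype(fields)
        expected = header_end + n_vertex * dtype.itemsize
        if len(raw) < expected:
            raise PLYError(
                f"{path}: truncated at byte {len(raw)}, expected {expected}")
        rec = np.frombuffer(raw, dtype=dtype, count=n_vertex,
                            offset=header_end)
    elif fmt == "ascii":
        body = raw[header_end:].decode("ascii", "replace").split()
        n_cols = len(fields)
        if len(body) < n_vertex * n_cols:
            raise PLYError(f"{path}: truncated ASCII body")
        arr = np.array(body[:n_vertex * n_cols]).reshape(n_vertex, n_cols)
        rec = np.zeros(n_vertex, dtype=np.dtype(fields))
        for i, (name, code) in enumerate(fields):
            rec[name] = arr[:, i].astype(np.dtype(code))
    else:
        raise PLYError(f"{path}: unsupported format {fmt!r}")
    names = [name for name, _ in fields]
    for axis in ("x", "y", "z"):
        if axis not in names:
            raise PLYError(f"{path}: missing coordinate property {axis!r}")
    points = np.column_stack([rec["x"], rec["y"], rec["z"]]).astype(float)
    attrs = {name: np.array(rec[name]) for name in names
             if name not in ("x", "y", "z")}
    return points, attrs


def write_pcd(path: str | Path, points: np.ndarray,
              semantic: np.ndarray | None = None,
              force: bool = False) -> None:
    """Write an ASCII PCD point cloud (optional uint8 semantic column)."""
    path = Path(path)
    _check_overwrite(path, force)
    pts = np.asarray(points, dtype=np.float32).reshape(-1, 3)
    fields, sizes, types, counts = ["x", "y", "z"], ["4"] * 3, ["F"] * 3, ["1"] * 3
    cols: list[np.ndarray] = [pts[:, 0], pts[:, 1], pts[:, 2]]
    if semantic is not None:
        semantic = np.asarray(semantic, dtype=np.uint8).ravel()
        if len(semantic) != len(pts):
            raise ValueError("semantic length mismatch")
        fields.append("semantic")
        sizes.append("1")
        types.append("U")
        counts.append("1")
        cols.append(semantic)
    lines = [
        "# .PCD v0.7 - Point Cloud Data file format",
        "VERSION 0.7",
        "FIELDS " + " ".join(fields),
        "SIZE " + " ".join(sizes),
        "TYPE " + " ".join(types),
        "COUNT " + " ".join(counts),
        f"WIDTH {len(pts)}",
        "HEIGHT 1",
        "VIEWPOINT 0 0 0 1 0 0 0",
        f"POINTS {len(pts)}",
        "DATA ascii",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for row in zip(*cols):
            fh.write(" ".join(f"{v:.9g}" if isinstance(v, np.floating)
                              else str(int(v)) for v in row) + "\n")


def read_pcd(path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read an ASCII PCD point cloud; returns (points, semantic-or-None)."""
    path = Path(path)
    fields: list[str] = []
    n_points = None
    data_started = False
    rows = []
    for lineno, ln in enumerate(path.read_text().splitlines(), 1):
        if data_started:
            rows.append(ln.split())
            continue
        parts = ln.split()
        if not parts or parts[0] == "#":
            continue
        if parts[0] == "FIELDS":
            fields = parts[1:]
        elif parts[0] == "POINTS":
            n_points = int(parts[1])
        elif parts[0] == "DATA":
            if parts[1] != "ascii":
                raise ValueError(f"{path}:{lineno}: only ascii DATA supported")
            data_started = True
    if n_points is None or not fields:
        raise ValueError(f"{path}: missing PCD header fields")
    if len(rows) < n_points:
        raise ValueError(f"{path}: truncated, {len(rows)}/{n_points} rows")
    arr = np.array(rows[:n_points], dtype=float)
    idx = {f: i for i, f in enumerate(fields)}
    points = arr[:, [idx["x"], idx["y"], idx["z"]]]
    semantic = (arr[:, idx["semantic"]].astype(np.uint8)
                if "semantic" in idx else None)
    return points, semantic


def write_rgba(path: str | Path, rgba: np.ndarray, force: bool = False) -> None:
    path = Path(path)
    _check_overwrite(path, force)
    iio.imwrite(path, np.asarray(rgba, dtype=np.uint8))


def read_rgba(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(path))


def write_field(path: str | Path, fld: DensityField, force: bool = False) -> None:
    """Write a density grid as an NPZ container."""
    path = Path(path)
    _check_overwrite(path, force)
    np.savez(path, values=fld.values, origin=fld.origin,
             spacing=np.array(fld.spacing), iso=np.array(fld.iso))


def read_field(path: str | Path) -> DensityField:
    with np.load(path) as data:
        missing = {"values", "origin", "spacing"} - set(data.files)
        if missing:
            raise ValueError(f"{path}: missing arrays {sorted(missing)}")
        iso = float(data["iso"]) if "iso" in data.files else None
        return DensityField(values=data["values"], origin=data["origin"],
                            spacing=float(data["spacing"]), iso=iso)


def write_csv_traits(path: str | Path, table: pd.DataFrame,
                     force: bool = False) -> None:
    path = Path(path)
    _check_overwrite(path, force)
    table.to_csv(path, index=False)


def read_csv_traits(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
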