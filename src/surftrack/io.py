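"""File formats: PLY point clouds, 6-DoF trace CSV, depth PNG, fiducials.

PLY dialect: vertex element with float32 properties ``x,y,z`` and optionally
``nx,ny,nz``, in mm, ASCII or binary little-endian.  Trace CSV dialect:
header ``t_s,tx_mm,ty_mm,tz_mm,rx_deg,ry_deg,rz_deg``, UTF-8, '.' decimal,
one row per frame.  Depth images are 16-bit PNG at 0.1 mm per unit with a
JSON sidecar holding the camera intrinsics.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .cloud import SurfaceCloud

__all__ = [
    "read_ply",
    "write_ply",
    "read_trace_csv",
    "write_trace_csv",
    "read_depth_png",
    "write_depth_png",
    "read_fiducials_csv",
    "write_fiducials_csv",
    "read_calibration_json",
    "write_calibration_json",
    "TRACE_COLUMNS",
]

TRACE_COLUMNS = ["t_s", "tx_mm", "ty_mm", "tz_mm", "rx_deg", "ry_deg", "rz_deg"]

_PLY_TYPES = {
    "float": np.float32, "float32": np.float32,
    "double": np.float64, "float64": np.float64,
    "uchar": np.uint8, "uint8": np.uint8,
    "int": np.int32, "int32": np.int32,
    "uint": np.uint32, "uint32": np.uint32,
    "short": np.int16, "ushort": np.uint16,
}

DEPTH_MM_PER_UNIT = 0.1


def write_ply(path: str | Path, cloud: SurfaceCloud, binary: bool = True) -> None:
    """Write a point cloud (x,y,z[,nx,ny,nz] float32, mm)."""
    path = Path(path)
    n = len(cloud)
    props = ["x", "y", "z"]
    cols = [cloud.points.astype(np.float32)]
    if cloud.normals is not None:
        props += ["nx", "ny", "nz"]
        cols.append(cloud.normals.astype(np.float32))
    data = np.hstack(cols).astype("<f4")

    fmt = "binary_little_endian" if binary else "ascii"
    header = ["ply", f"format {fmt} 1.0", f"element vertex {n}"]
    header += [f"property float {p}" for p in props]
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(data.tobytes())
        else:
            np.savetxt(fh, data, fmt="%.6g")


def read_ply(path: str | Path) -> SurfaceCloud:
    """Read a PLY vertex cloud (ASCII or binary little-endian)."""
    path = Path(path)
    with open(path, "rb") as fh:
        line = fh.readline().strip()
        if line != b"ply":
            raise ValueError(f"{path} is not a PLY file")
        fmt = None
        n = None
        props: list[tuple[str, np.dtype]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise ValueError("unexpected end of PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise ValueError("list properties unsupported in vertex element")
                props.append((tokens[2], np.dtype(_PLY_TYPES[tokens[1]])))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise ValueError(f"unsupported PLY format {fmt!r}")
        if n is None:
            raise ValueError("PLY file has no vertex element")

        dtype = np.dtype([(name, dt.newbyteorder("<")) for name, dt in props])
        if fmt == "ascii":
            raw = np.loadtxt(fh, dtype=float, max_rows=n, ndmin=2)
            rec = {name: raw[:, i] for i, (name, _) in enumerate(props)}
        else:
            buf = fh.read(dtype.itemsize * n)
            arr = np.frombuffer(buf, dtype=dtype, count=n)
            rec = {name: arr[name].astype(float) for name, _ in props}

    points = np.column_stack([rec["x"], rec["y"], rec["z"]])
    normals = None
    if all(k in rec for k in ("nx", "ny", "nz")):
        normals = np.column_stack([rec["nx"], rec["ny"], rec["nz"]])
    return SurfaceCloud(points, normals)


def write_trace_csv(path: str | Path, t_s: np.ndarray, sixdof: np.ndarray) -> None:
    """Write a 6-DoF trace: ``sixdof`` is (N, 6) = tx,ty,tz (mm), rx,ry,rz (deg)."""
    df = pd.DataFrame(
        np.column_stack([np.asarray(t_s, float), np.asarray(sixdof, float)]),
        columns=TRACE_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_trace_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV missing columns {missing}")
    return df["t_s"].to_numpy(float), df[TRACE_COLUMNS[1:]].to_numpy(float)


def write_depth_png(path: str | Path, depth_mm: np.ndarray,
                    intrinsics: dict | None = None) -> None:
    """16-bit PNG at 0.1 mm/unit; 0 marks invalid pixels.

    ``intrinsics`` (fx, fy, cx, cy, width, height, ...) go to a ``.json``
    sidecar next to the image.
    """
    path = Path(path)
    depth = np.asarray(depth_mm, dtype=float)
    units = np.zeros(depth.shape, dtype=np.uint16)
    ok = np.isfinite(depth) & (depth > 0)
    units[ok] = np.clip(np.round(depth[ok] / DEPTH_MM_PER_UNIT), 1, 65535)
    iio.imwrite(path, units)
    if intrinsics is not None:
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(intrinsics, indent=1))


def read_depth_png(path: str | Path) -> tuple[np.ndarray, dict | None]:
    """Return (depth in mm with NaN for invalid, sidecar intrinsics or None)."""
    path = Path(path)
    units = iio.imread(path)
    depth = units.astype(float) * DEPTH_MM_PER_UNIT
    depth[units == 0] = np.nan
    sidecar = path.with_suffix(".json")
    intr = json.loads(sidecar.read_text()) if sidecar.exists() else None
    return depth, intr


def write_fiducials_csv(path: str | Path, labels: list[str],
                        points: np.ndarray) -> None:
    df = pd.DataFrame(np.asarray(points, float), columns=["x_mm", "y_mm", "z_mm"])
    df.insert(0, "label", labels)
    df.to_csv(path, index=False, float_format="%.9g")


def read_fiducials_csv(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path)
    for c in ("label", "x_mm", "y_mm", "z_mm"):
        if c not in df.columns:
            raise ValueError(f"fiducial CSV missing column {c!r}")
    return (df["label"].astype(str).tolist(),
            df[["x_mm", "y_mm", "z_mm"]].to_numpy(float))


def write_calibration_json(path: str | Path, matrix: np.ndarray,
                           rms_mm: float, timestamp: str,
                           fiducial_count: int | None = None) -> None:
    """Calibration record: 4x4 row-major matrix + RMS residual + timestamp."""
    m = np.asarray(matrix, float).reshape(4, 4)
    payload = {
        "sensor_to_room": m.flatten().tolist(),
        "rms_mm": float(rms_mm),
        "timestamp": timestamp,
    }
    if fiducial_count is not None:
        payload["fiducial_count"] = int(fiducial_count)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_calibration_json(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    payload["sensor_to_room"] = np.asarray(
        payload["sensor_to_room"], float).reshape(4, 4)
    return payload
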