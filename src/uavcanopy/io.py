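"""File formats: XYZ-CSV and ASCII-PLY clouds, ESRI ASCII grids, layouts, reports.

LAS/LAZ and GeoTIFF are supported only when the optional ``laspy`` /
``rasterio`` packages are importable; the plain-text formats have native
readers and writers so the pipeline runs with no optional dependencies.
Local-frame cloud files carry their frame in a ``<file>.frame.json`` sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .canopy_height import DsmGrid, PlotLayout
from .errors import FormatError, ValidationError
from .geodesy import GeorefPointCloud, LocalFrame

__all__ = [
    "read_cloud",
    "write_cloud",
    "read_layout",
    "write_layout",
    "write_esri_ascii",
    "read_esri_ascii",
    "read_measurements",
]

_WGS_COLS = ("lat", "lon", "h")
_XYZ_COLS = ("x", "y", "z")


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".frame.json")


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".csv", ".xyz", ".txt"):
        return "xyz-csv"
    if suffix == ".ply":
        return "ply"
    if suffix in (".las", ".laz"):
        return "las"
    raise FormatError(f"cannot infer point-cloud format from {path.name!r}")


def read_cloud(path, fmt: Optional[str] = None, frame: Optional[str] = None) -> GeorefPointCloud:
    """Read a point cloud; format inferred from the suffix unless given."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = _infer_format(path, fmt)
    if fmt == "xyz-csv":
        return _read_csv(path, frame)
    if fmt == "ply":
        return _read_ply(path, frame)
    if fmt == "las":
        return _read_las(path)
    raise FormatError(f"unknown point-cloud format {fmt!r}")


def write_cloud(path, cloud: GeorefPointCloud, fmt: Optional[str] = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "xyz-csv":
        cols = _WGS_COLS if cloud.frame == "WGS84" else _XYZ_COLS
        df = pd.DataFrame(cloud.points, columns=list(cols))
        if cloud.e is not None:
            df["e"] = cloud.e
        df.to_csv(path, index=False, float_format="%.10f")
    elif fmt == "ply":
        _write_ply(path, cloud)
    else:
        raise FormatError(f"writing format {fmt!r} is not supported")
    _write_sidecar(path, cloud)


def _write_sidecar(path: Path, cloud: GeorefPointCloud) -> None:
    meta = {"frame": cloud.frame}
    if cloud.local_frame is not None:
        meta["local_frame"] = cloud.local_frame.to_dict()
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def _load_sidecar(path: Path):
    sc = _sidecar(path)
    if not sc.exists():
        return None, None
    meta = json.loads(sc.read_text())
    lf = meta.get("local_frame")
    return meta.get("frame"), LocalFrame.from_dict(lf) if lf else None


def _resolve_frame(path, columns, frame_arg):
    sidecar_frame, local_frame = _load_sidecar(path)
    if set(_WGS_COLS).issubset(columns):
        return "WGS84", list(_WGS_COLS), local_frame
    if set(_XYZ_COLS).issubset(columns):
        frame = frame_arg or sidecar_frame
        if frame is None:
            raise FormatError(
                f"{path.name}: Cartesian columns but no frame declared "
                "(pass frame=... or provide a .frame.json sidecar)"
            )
        return frame, list(_XYZ_COLS), local_frame
    raise FormatError(
        f"{path.name}: header must name either {_WGS_COLS} or {_XYZ_COLS}, got {list(columns)}"
    )


def _read_csv(path: Path, frame_arg) -> GeorefPointCloud:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - rewrap for uniform error surface
        raise FormatError(f"{path.name}: cannot parse CSV ({exc})") from exc
    frame, cols, local_frame = _resolve_frame(path, df.columns, frame_arg)
    vals = df[cols].apply(pd.to_numeric, errors="coerce")
    bad = vals.isna().any(axis=1)
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # 1-based + header
        raise FormatError(f"{path.name}: malformed row(s) at line(s) {lines[:20]}")
    e = None
    if "e" in df.columns:
        e = pd.to_numeric(df["e"], errors="coerce").to_numpy()
    return GeorefPointCloud(
        frame=frame, points=vals.to_numpy(dtype=float), e=e, local_frame=local_frame
    )


def _write_ply(path: Path, cloud: GeorefPointCloud) -> None:
    n = len(cloud)
    props = ["property double x", "property double y", "property double z"]
    data = cloud.points
    if cloud.e is not None:
        props.append("property double e")
        data = np.column_stack([cloud.points, cloud.e])
    header = "\n".join(
        [
            "ply",
            "format ascii 1.0",
            f"comment frame {cloud.frame}",
            f"element vertex {n}",
            *props,
            "end_header",
        ]
    )
    with path.open("w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, data, fmt="%.10f")


def _read_ply(path: Path, frame_arg) -> GeorefPointCloud:
    with path.open() as fh:
        first = fh.readline().strip()
        if first != "ply":
            raise FormatError(f"{path.name}: not a PLY file (missing 'ply' magic)")
        n = None
        frame = None
        props = []
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "format":
                if tok[1] != "ascii":
                    raise FormatError(f"{path.name}: only ASCII PLY is supported")
            elif tok[0] == "comment" and len(tok) >= 3 and tok[1] == "frame":
                frame = tok[2]
            elif tok[0] == "element":
                if tok[1] != "vertex":
                    raise FormatError(f"{path.name}: unsupported element {tok[1]!r}")
                n = int(tok[2])
            elif tok[0] == "property":
                props.append(tok[2])
            elif tok[0] == "end_header":
                break
        else:
            raise FormatError(f"{path.name}: truncated PLY header (no end_header)")
        if n is None:
            raise FormatError(f"{path.name}: PLY header lacks a vertex element")
        if props[:3] != ["x", "y", "z"]:
            raise FormatError(f"{path.name}: PLY vertex must start with x y z, got {props}")
        data = np.loadtxt(fh, dtype=float, ndmin=2, max_rows=n)
    if data.shape != (n, len(props)):
        raise FormatError(
            f"{path.name}: expected {n} x {len(props)} vertex values, got {data.shape}"
        )
    sidecar_frame, local_frame = _load_sidecar(path)
    frame = frame_arg or frame or sidecar_frame
    if frame is None:
        raise FormatError(f"{path.name}: no frame declared in PLY comment or sidecar")
    e = data[:, props.index("e")] if "e" in props else None
    return GeorefPointCloud(frame=frame, points=data[:, :3], e=e, local_frame=local_frame)


def _read_las(path: Path) -> GeorefPointCloud:
    try:
        import laspy
    except ImportError as exc:
        raise FormatError(
            "LAS/LAZ support requires the optional 'laspy' package"
        ) from exc
    las = laspy.read(path)
    return GeorefPointCloud(
        frame="WGS84", points=np.column_stack([las.x, las.y, las.z])
    )


def write_layout(path, layout: PlotLayout) -> None:
    Path(path).write_text(json.dumps(layout.to_geojson(), indent=2))


def read_layout(path) -> PlotLayout:
    try:
        gj = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid GeoJSON ({exc})") from exc
    return PlotLayout.from_geojson(gj)


def write_esri_ascii(path, dsm: DsmGrid) -> None:
    """Single-band ESRI ASCII grid; rows written north-up per the convention."""
    ny, nx = dsm.shape
    header = (
        f"ncols {nx}\nnrows {ny}\nxllcorner {dsm.x0}\nyllcorner {dsm.y0}\n"
        f"cellsize {dsm.cell_size}\nNODATA_value -9999\n"
    )
    vals = np.where(np.isfinite(dsm.values), dsm.values, -9999.0)
    with Path(path).open("w") as fh:
        fh.write(header)
        np.savetxt(fh, vals[::-1], fmt="%.6f")


def read_esri_ascii(path) -> DsmGrid:
    lines = Path(path).read_text().splitlines()
    hdr = {}
    for i, line in enumerate(lines):
        tok = line.split()
        if len(tok) == 2 and tok[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            hdr[tok[0].lower()] = float(tok[1])
        else:
            break
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not required.issubset(hdr):
        raise FormatError(f"{path}: incomplete ESRI ASCII header {sorted(hdr)}")
    vals = np.loadtxt(lines[i:], dtype=float, ndmin=2)[::-1]
    nodata = hdr.get("nodata_value", -9999.0)
    vals = np.where(vals == nodata, np.nan, vals)
    if vals.shape != (int(hdr["nrows"]), int(hdr["ncols"])):
        raise FormatError(f"{path}: grid shape {vals.shape} disagrees with header")
    return DsmGrid(
        cell_size=hdr["cellsize"],
        x0=hdr["xllcorner"],
        y0=hdr["yllcorner"],
        values=vals,
        fill_method="none",
    )


def write_geotiff(path, dsm: DsmGrid) -> None:
    """GeoTIFF export; needs the optional ``rasterio`` package."""
    try:
        import rasterio
        from rasterio.transform import from_origin
    except ImportError as exc:
        raise FormatError("GeoTIFF export requires the optional 'rasterio' package") from exc
    ny, nx = dsm.shape
    transform = from_origin(
        dsm.x0, dsm.y0 + ny * dsm.cell_size, dsm.cell_size, dsm.cell_size
    )
    with rasterio.open(
        path,
        "w",
        driver="GTiff",
        height=ny,
        width=nx,
        count=1,
        dtype="float64",
        nodata=-9999.0,
        transform=transform,
    ) as dst:
        dst.write(np.where(np.isfinite(dsm.values), dsm.values, -9999.0)[::-1], 1)


def read_measurements(path) -> pd.DataFrame:
    """Quadrat measurement CSV: quadrat_id, plot_id, bounds, h_c and/or lai."""
    df = pd.read_csv(path)
    needed = {"quadrat_id", "plot_id"}
    if not needed.issubset(df.columns):
        raise ValidationError(
            f"measurements need columns {sorted(needed)}, got {list(df.columns)}"
        )
    return df
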