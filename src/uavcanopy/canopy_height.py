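"""DSM rasterization and percentile-based plot height extraction."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ValidationError
from .geodesy import GeorefPointCloud
from .terrain import GroundModel

__all__ = [
    "Quadrat",
    "Plot",
    "PlotLayout",
    "DsmGrid",
    "rasterize_dsm",
    "upper_boundary_p99",
    "estimate_heights",
]

Bounds = Tuple[float, float, float, float]  # xmin, ymin, xmax, ymax


def _contains(outer: Bounds, inner: Bounds, tol: float = 1e-9) -> bool:
    return (
        inner[0] >= outer[0] - tol
        and inner[1] >= outer[1] - tol
        and inner[2] <= outer[2] + tol
        and inner[3] <= outer[3] + tol
    )


def _overlap(a: Bounds, b: Bounds) -> bool:
    return a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]


@dataclass(frozen=True)
class Quadrat:
    id: str
    bounds: Bounds


@dataclass(frozen=True)
class Plot:
    id: str
    bounds: Bounds
    quadrats: Tuple[Quadrat, ...]


@dataclass
class PlotLayout:
    """Field layout: plots, each holding its sampling quadrats."""

    plots: List[Plot]

    def __post_init__(self) -> None:
        for i, p in enumerate(self.plots):
            for q in p.quadrats:
                if not _contains(p.bounds, q.bounds):
                    raise ValidationError(
                        f"quadrat {q.id} lies outside plot {p.id}"
                    )
            for other in self.plots[i + 1 :]:
                if _overlap(p.bounds, other.bounds):
                    raise ValidationError(
                        f"plots {p.id} and {other.id} overlap"
                    )

    @property
    def quadrats(self) -> List[Quadrat]:
        return [q for p in self.plots for q in p.quadrats]

    def quadrat_plot(self) -> dict:
        """Map quadrat id -> plot id."""
        return {q.id: p.id for p in self.plots for q in p.quadrats}

    def to_geojson(self) -> dict:
        feats = []
        for p in self.plots:
            feats.append(_bounds_feature(p.bounds, {"kind": "plot", "plot_id": p.id}))
            for q in p.quadrats:
                feats.append(
                    _bounds_feature(
                        q.bounds,
                        {"kind": "quadrat", "quadrat_id": q.id, "plot_id": p.id},
                    )
                )
        return {"type": "FeatureCollection", "features": feats}

    @classmethod
    def from_geojson(cls, gj: dict) -> "PlotLayout":
        plots: dict = {}
        quads: dict = {}
        for f in gj["features"]:
            props = f.get("properties", {})
            b = _feature_bounds(f)
            if props.get("kind") == "plot":
                plots[props["plot_id"]] = b
            elif props.get("kind") == "quadrat":
                quads.setdefault(props["plot_id"], []).append(
                    Quadrat(id=props["quadrat_id"], bounds=b)
                )
        return cls(
            plots=[
                Plot(id=pid, bounds=b, quadrats=tuple(quads.get(pid, ())))
                for pid, b in plots.items()
            ]
        )


def _bounds_feature(b: Bounds, props: dict) -> dict:
    x0, y0, x1, y1 = b
    ring = [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]
    return {
        "type": "Feature",
        "properties": props,
        "geometry": {"type": "Polygon", "coordinates": [ring]},
    }


def _feature_bounds(f: dict) -> Bounds:
    ring = np.asarray(f["geometry"]["coordinates"][0], dtype=float)
    return (
        float(ring[:, 0].min()),
        float(ring[:, 1].min()),
        float(ring[:, 0].max()),
        float(ring[:, 1].max()),
    )


@dataclass
class DsmGrid:
    """Max-elevation surface raster over the local x-y plane.

    ``values[iy, ix]`` covers the half-open cell
    [x0 + ix*s, x0 + (ix+1)*s) x [y0 + iy*s, y0 + (iy+1)*s).
    """

    cell_size: float
    x0: float
    y0: float
    values: np.ndarray
    fill_method: str = "none"
    nodata: float = np.nan

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> Tuple[np.ndarray, np.ndarray]:
        ny, nx = self.values.shape
        cx = self.x0 + (np.arange(nx) + 0.5) * self.cell_size
        cy = self.y0 + (np.arange(ny) + 0.5) * self.cell_size
        return cx, cy


def rasterize_dsm(
    cloud: GeorefPointCloud,
    cell_size: float = 0.05,
    use_e: bool = False,
    fill: str = "nearest",
) -> DsmGrid:
    """Bin a local cloud to a max-value DSM; empty cells filled by nearest cell."""
    if cell_size <= 0:
        raise ValidationError("cell_size must be > 0")
    if len(cloud) == 0:
        raise ValidationError("cannot rasterize an empty cloud")
    z = cloud.e if use_e else cloud.z
    if z is None:
        raise ValidationError("cloud has no e values; run terrain processing first")
    x, y = cloud.x, cloud.y
    x0, y0 = float(x.min()), float(y.min())
    ix = np.floor((x - x0) / cell_size).astype(np.int64)
    iy = np.floor((y - y0) / cell_size).astype(np.int64)
    nx, ny = int(ix.max()) + 1, int(iy.max()) + 1
    values = np.full((ny, nx), -np.inf)
    np.maximum.at(values, (iy, ix), z)
    empty = ~np.isfinite(values)
    if empty.any():
        if fill == "nearest":
            idx = ndimage.distance_transform_edt(
                empty, return_distances=False, return_indices=True
            )
            values = values[tuple(idx)]
        elif fill == "none":
            values[empty] = np.nan
        else:
            raise ValidationError(f"unknown fill method {fill!r}")
    return DsmGrid(cell_size=cell_size, x0=x0, y0=y0, values=values, fill_method=fill)


def upper_boundary_p99(
    dsm: DsmGrid, region: Bounds, percentile: float = 99.0
) -> float:
    """Percentile of DSM cells whose centers fall inside ``region``.

    Uses the linear-interpolation percentile definition.
    """
    xmin, ymin, xmax, ymax = region
    cx, cy = dsm.cell_centers()
    mx = (cx >= xmin) & (cx < xmax)
    my = (cy >= ymin) & (cy < ymax)
    if not (mx.any() and my.any()):
        raise ValidationError(f"region {region} covers no DSM cell centers")
    vals = dsm.values[np.ix_(my, mx)]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValidationError(f"region {region} contains only nodata cells")
    return float(np.percentile(vals, percentile, method="linear"))


def estimate_heights(
    dsm: DsmGrid,
    ground: GroundModel,
    layout: PlotLayout,
    percentile: float = 99.0,
) -> pd.DataFrame:
    """Per-plot and per-quadrat height table: h = P99 - plot ground elevation.

    Quadrat rows carry a ``quadrat_id``; plot-level rows have it empty.
    """
    rows = []
    for plot in layout.plots:
        h_gf = ground.plot_elevation(plot.id)
        p99_f = upper_boundary_p99(dsm, plot.bounds, percentile)
        rows.append(
            {
                "plot_id": plot.id,
                "quadrat_id": None,
                "p99": p99_f,
                "h_ground": h_gf,
                "h_est": p99_f - h_gf,
            }
        )
        for q in plot.quadrats:
            p99_i = upper_boundary_p99(dsm, q.bounds, percentile)
            rows.append(
                {
                    "plot_id": plot.id,
                    "quadrat_id": q.id,
                    "p99": p99_i,
                    "h_ground": h_gf,
                    "h_est": p99_i - h_gf,
                }
            )
    return pd.DataFrame(rows)
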