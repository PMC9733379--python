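"""Ground-elevation modelling.

Two complementary routes are provided:

* orthogonal-least-squares terrain planes fitted between adjacent sampling
  regions, giving per-point relative heights above the fitted plane;
* the sampled-height inversion, which recovers per-quadrat ground elevation
  as (99th-percentile surface) - (measured tallest-plant height) and
  averages the four quadrats of each plot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, ValidationError
from .geodesy import GeorefPointCloud

__all__ = [
    "Plane",
    "SampleRegion",
    "GroundModel",
    "fit_plane_orthogonal",
    "plane_objective",
    "lowest_region",
    "relative_heights",
    "ground_from_samples",
    "extract_region",
    "corridor_planes",
]


@dataclass(frozen=True)
class Plane:
    """Plane through ``centroid`` with unit normal (o, p, q), q > 0."""

    normal: np.ndarray
    centroid: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        c = np.asarray(self.centroid, dtype=float)
        if n.shape != (3,) or c.shape != (3,):
            raise ValidationError("normal and centroid must be 3-vectors")
        norm = float(np.linalg.norm(n))
        if norm == 0.0:
            raise DegenerateGeometryError("zero plane normal")
        n = n / norm
        if n[2] < 0:
            n = -n
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "centroid", c)

    @property
    def o(self) -> float:
        return float(self.normal[0])

    @property
    def p(self) -> float:
        return float(self.normal[1])

    @property
    def q(self) -> float:
        return float(self.normal[2])

    def height_at(self, x, y):
        """Plane surface elevation at horizontal position (x, y)."""
        if self.q == 0.0:
            raise DegenerateGeometryError("vertical plane has no height function")
        cx, cy, cz = self.centroid
        return cz - (self.o * (np.asarray(x) - cx) + self.p * (np.asarray(y) - cy)) / self.q


def plane_objective(points: np.ndarray, normal: np.ndarray, centroid: np.ndarray) -> float:
    """Sum of squared plane offsets normalised by the squared normal length."""
    pts = np.asarray(points, dtype=float)
    n = np.asarray(normal, dtype=float)
    d = (pts - np.asarray(centroid, dtype=float)) @ n
    return float(np.sum(d * d) / np.dot(n, n))


def fit_plane_orthogonal(points: Iterable) -> Plane:
    """Orthogonal-distance plane fit.

    The minimiser of the normalised squared-offset objective is the plane
    through the centroid whose normal is the smallest principal direction of
    the centred scatter; computed by SVD.
    """
    pts = np.atleast_2d(np.asarray(list(points) if not isinstance(points, np.ndarray) else points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError(f"expected (N, 3) points, got {pts.shape}")
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("plane fit needs at least 3 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # Collinear input: the two smallest singular values both vanish.
    scale = s[0] if s[0] > 0 else 1.0
    if s[1] / scale < 1e-10:
        raise DegenerateGeometryError("points are collinear; plane is not unique")
    return Plane(normal=vt[2], centroid=centroid)


@dataclass
class SampleRegion:
    """A sampling quadrat: bounds, member points and optional measured height."""

    id: str
    bounds: tuple  # (xmin, ymin, xmax, ymax)
    points: np.ndarray
    h_c: Optional[float] = None

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.bounds
        if not (xmin < xmax and ymin < ymax):
            raise ValidationError(f"region {self.id}: bounds not well-ordered")
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        if len(self) == 0:
            raise ValidationError(f"region {self.id} has no member points")
        return self.points.mean(axis=0)


def extract_region(
    cloud: GeorefPointCloud,
    bounds: tuple,
    id: str = "",
    h_c: Optional[float] = None,
    lowest_fraction: Optional[float] = None,
) -> SampleRegion:
    """Collect the cloud points inside rectangular x-y ``bounds``.

    ``lowest_fraction`` optionally keeps only the lowest-z fraction of the
    members, a cheap proxy for ground points under canopy.
    """
    xmin, ymin, xmax, ymax = bounds
    m = (
        (cloud.x >= xmin)
        & (cloud.x < xmax)
        & (cloud.y >= ymin)
        & (cloud.y < ymax)
    )
    pts = cloud.points[m]
    if lowest_fraction is not None and len(pts):
        k = max(3, int(np.ceil(lowest_fraction * len(pts))))
        pts = pts[np.argsort(pts[:, 2])[:k]]
    return SampleRegion(id=id, bounds=bounds, points=pts, h_c=h_c)


def lowest_region(a: SampleRegion, b: SampleRegion) -> SampleRegion:
    """The region whose point centroid sits lower; ties go to ``a``."""
    if len(a) == 0 or len(b) == 0:
        empty = a.id if len(a) == 0 else b.id
        raise ValidationError(f"region {empty} is empty")
    return a if a.centroid[2] <= b.centroid[2] else b


def corridor_planes(regions: Sequence[SampleRegion]):
    """Fit a terrain plane per corridor between consecutive regions.

    Regions must be ordered along the field's long axis.  Each consecutive
    pair contributes one plane, fitted to the lower region's points, covering
    the corridor spanned by the pair's bounds.
    """
    if len(regions) < 2:
        raise ValidationError("need at least two regions to form a corridor")
    out = []
    for a, b in zip(regions[:-1], regions[1:]):
        low = lowest_region(a, b)
        plane = fit_plane_orthogonal(low.points)
        corridor = (
            min(a.bounds[0], b.bounds[0]),
            min(a.bounds[1], b.bounds[1]),
            max(a.bounds[2], b.bounds[2]),
            max(a.bounds[3], b.bounds[3]),
        )
        out.append((plane, corridor))
    return out


def relative_heights(cloud: GeorefPointCloud | np.ndarray, plane: Plane) -> np.ndarray:
    """Vertical offset of each point from the plane surface at its (x, y)."""
    if abs(plane.q) < 1e-12:
        raise DegenerateGeometryError("vertical plane: relative height undefined")
    pts = cloud.points if isinstance(cloud, GeorefPointCloud) else np.asarray(cloud, dtype=float)
    cx, cy, cz = plane.centroid
    return (
        pts[:, 2]
        + (plane.o * (pts[:, 0] - cx) + plane.p * (pts[:, 1] - cy)) / plane.q
        - cz
    )


@dataclass
class GroundModel:
    """Per-plot and per-quadrat ground elevations, plus optional terrain planes."""

    per_plot: dict
    per_quadrat: dict
    planes: list = field(default_factory=list)
    mode: str = "inverted"

    def plot_elevation(self, plot_id) -> float:
        try:
            return self.per_plot[plot_id]
        except KeyError:
            raise ValidationError(f"no ground elevation for plot {plot_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"plot_id": list(self.per_plot), "h_gf": list(self.per_plot.values())}
        )


def ground_from_samples(
    p99_per_quadrat: pd.DataFrame,
    measured_heights: pd.DataFrame,
    layout=None,
    mode: str = "inverted",
) -> GroundModel:
    """Ground elevations from per-quadrat surface percentiles and measured heights.

    ``p99_per_quadrat`` needs columns (quadrat_id, plot_id, p99);
    ``measured_heights`` needs (quadrat_id, h_c).  In the default
    ``"inverted"`` mode the quadrat ground is p99 - h_c and the plot ground
    is the mean over its four quadrats.  ``"as-printed"`` reproduces the
    literal published formula, averaging the raw p99 values instead.
    """
    if mode not in ("inverted", "as-printed"):
        raise ValidationError(f"unknown ground-model mode {mode!r}")
    df = p99_per_quadrat.merge(
        measured_heights[["quadrat_id", "h_c"]], on="quadrat_id", how="left"
    )
    if mode == "inverted":
        bad = df[df["h_c"].isna() | df["p99"].isna()]
        if len(bad):
            plots = sorted(set(bad["plot_id"].astype(str)))
            raise ValidationError(
                f"missing quadrat measurement(s) in plot(s): {', '.join(plots)}"
            )
        df["h_g"] = df["p99"] - df["h_c"]
    else:
        if df["p99"].isna().any():
            plots = sorted(set(df.loc[df["p99"].isna(), "plot_id"].astype(str)))
            raise ValidationError(
                f"missing quadrat p99 in plot(s): {', '.join(plots)}"
            )
        df["h_g"] = df["p99"]
    counts = df.groupby("plot_id")["h_g"].count()
    short = counts[counts != 4]
    if len(short):
        warnings.warn(
            f"plots without exactly 4 quadrats: {list(short.index)}", stacklevel=2
        )
    per_quadrat = dict(zip(df["quadrat_id"], df["h_g"].astype(float)))
    per_plot = df.groupby("plot_id")["h_g"].mean().astype(float).to_dict()
    return GroundModel(per_plot=per_plot, per_quadrat=per_quadrat, mode=mode)
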