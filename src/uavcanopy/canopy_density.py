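"""Above-ground segmentation, 2-D point-density grids and canopy diameter.

The density grid bins canopy points into square cells of side eps along a
horizontal axis and the relative-height axis (or x-y), stores per-cell point
density count/eps^2, and summarises a grid by its occupancy ratio: the
fraction of cells whose density reaches 0.2 times the grid mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import ValidationError
from .geodesy import GeorefPointCloud

__all__ = [
    "CanopyCloud",
    "DensityGrid",
    "segment_above_ground",
    "density_grid",
    "occupancy_ratio",
    "canopy_diameter",
]


@dataclass
class CanopyCloud:
    """Above-ground subset of a local cloud, with per-point relative heights."""

    points: np.ndarray
    e: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.e = np.asarray(self.e, dtype=float)
        if self.e.shape != (self.points.shape[0],):
            raise ValidationError("e must have one value per canopy point")

    def __len__(self) -> int:
        return self.points.shape[0]


def segment_above_ground(
    cloud: GeorefPointCloud, threshold: float = 0.0
) -> CanopyCloud:
    """Keep points with relative height strictly above ``threshold``."""
    if cloud.e is None:
        raise ValidationError("cloud has no relative heights; attach e first")
    keep = cloud.e > threshold
    return CanopyCloud(points=cloud.points[keep], e=cloud.e[keep])


@dataclass
class DensityGrid:
    """Point densities a[u, v] (points/m^2) on a regular eps grid.

    ``axes`` is "xe", "ye" or "xy": the first letter names the horizontal
    binning coordinate, the second the vertical one (e = relative height).
    Index u runs along the first axis, v along the second; both bins are
    half-open and measured from the respective axis minimum.
    """

    eps: float
    axes: str
    extents: Tuple[Tuple[float, float], Tuple[float, float]]
    a: np.ndarray

    @property
    def counts(self) -> np.ndarray:
        return np.rint(self.a * self.eps**2).astype(np.int64)


_AXIS_COLUMNS = {"x": 0, "y": 1}


def _grid_coords(canopy: CanopyCloud, axes: str) -> Tuple[np.ndarray, np.ndarray]:
    if axes not in ("xe", "ye", "xy"):
        raise ValidationError(f"unknown axes spec {axes!r} (expected xe, ye or xy)")
    u = canopy.points[:, _AXIS_COLUMNS[axes[0]]]
    v = canopy.e if axes[1] == "e" else canopy.points[:, _AXIS_COLUMNS[axes[1]]]
    return u, v


def density_grid(canopy: CanopyCloud, eps: float = 1.0, axes: str = "xe") -> DensityGrid:
    """Bin canopy points into an eps x eps grid of point densities.

    Bins are half-open relative to each axis minimum; points exactly on the
    upper extent fall into the last bin, so the count identity
    sum(a) * eps^2 == len(canopy) holds exactly.
    """
    if eps <= 0:
        raise ValidationError("eps must be > 0")
    if len(canopy) == 0:
        raise ValidationError("cannot grid an empty canopy cloud")
    cu, cv = _grid_coords(canopy, axes)
    u0, v0 = float(cu.min()), float(cv.min())
    iu = np.floor((cu - u0) / eps).astype(np.int64)
    iv = np.floor((cv - v0) / eps).astype(np.int64)
    nu, nv = int(iu.max()) + 1, int(iv.max()) + 1
    counts = np.zeros((nu, nv), dtype=np.int64)
    np.add.at(counts, (iu, iv), 1)
    extents = ((u0, u0 + nu * eps), (v0, v0 + nv * eps))
    return DensityGrid(eps=eps, axes=axes, extents=extents, a=counts / eps**2)


def occupancy_ratio(grid: DensityGrid) -> float:
    """Fraction of cells with density >= 0.2 x the all-cell mean density."""
    a = np.asarray(grid.a, dtype=float)
    if a.size == 0:
        raise ValidationError("empty density grid")
    rho = a.mean()
    if rho == 0.0:
        warnings.warn(
            "density grid is all-zero; occupancy ratio degenerates to 1.0",
            stacklevel=2,
        )
    return float(np.mean(a >= 0.2 * rho))


def _all_pairs_diameter(xy: np.ndarray) -> float:
    d2 = np.sum((xy[:, None, :] - xy[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def canopy_diameter(
    canopy: CanopyCloud | np.ndarray,
    region: Optional[Tuple[float, float, float, float]] = None,
    method: str = "hull",
) -> float:
    """Maximum horizontal extent of the canopy points inside ``region``.

    ``method="hull"`` takes the exact pairwise maximum over convex-hull
    vertices; ``method="bbox"`` returns the bounding-box diagonal.
    """
    pts = canopy.points if isinstance(canopy, CanopyCloud) else np.atleast_2d(
        np.asarray(canopy, dtype=float)
    )
    xy = pts[:, :2]
    if region is not None:
        xmin, ymin, xmax, ymax = region
        m = (xy[:, 0] >= xmin) & (xy[:, 0] < xmax) & (xy[:, 1] >= ymin) & (xy[:, 1] < ymax)
        xy = xy[m]
    if xy.shape[0] < 2:
        raise ValidationError("canopy diameter needs at least 2 points in the region")
    if method == "bbox":
        span = xy.max(axis=0) - xy.min(axis=0)
        return float(np.hypot(*span))
    if method != "hull":
        raise ValidationError(f"unknown diameter method {method!r}")
    if xy.shape[0] > 4:
        try:
            xy = xy[ConvexHull(xy).vertices]
        except QhullError:
            # Degenerate (collinear) input: fall back to the extreme points
            # along the principal axis, which realise the diameter exactly.
            centered = xy - xy.mean(axis=0)
            t = centered @ np.linalg.svd(centered, full_matrices=False)[2][0]
            xy = xy[[int(np.argmin(t)), int(np.argmax(t))]]
    return _all_pairs_diameter(xy)
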