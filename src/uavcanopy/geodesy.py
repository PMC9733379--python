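"""WGS84 <-> ECEF <-> local east-north-up (ENU) transforms for georeferenced clouds.

The local Cartesian frame is anchored at the componentwise-minimum geodetic
corner of the cloud ("southwest low corner"), with x pointing east, y north
and z up.  The frame travels with the localized cloud so every downstream
product can be mapped back to geodetic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np

from .errors import NumericError, ValidationError

__all__ = [
    "WGS84_A",
    "WGS84_F",
    "WGS84_B",
    "WGS84_E2",
    "GeoPoint",
    "EcefPoint",
    "LocalFrame",
    "GeorefPointCloud",
    "wgs84_to_ecef",
    "ecef_to_wgs84",
    "select_origin",
    "build_local_frame",
    "to_local",
    "from_local",
    "localize_cloud",
    "delocalize_cloud",
]

#: WGS84 semi-major axis (m) and flattening.
WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563
WGS84_B = WGS84_A * (1.0 - WGS84_F)
WGS84_E2 = WGS84_F * (2.0 - WGS84_F)

FrameTag = Literal["WGS84", "ECEF", "LOCAL"]


@dataclass(frozen=True)
class GeoPoint:
    """Geodetic coordinate: latitude/longitude in degrees, ellipsoidal height in m."""

    lat: float
    lon: float
    h: float = 0.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"lat out of range [-90, 90]: {self.lat!r}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValidationError(f"lon out of range [-180, 180]: {self.lon!r}")


@dataclass(frozen=True)
class EcefPoint:
    """Earth-centered Earth-fixed Cartesian coordinate (m)."""

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


def _ecef_arrays(lat_deg: np.ndarray, lon_deg: np.ndarray, h: np.ndarray):
    phi = np.radians(lat_deg)
    lam = np.radians(lon_deg)
    sphi, cphi = np.sin(phi), np.cos(phi)
    n = WGS84_A / np.sqrt(1.0 - WGS84_E2 * sphi * sphi)
    x = (n + h) * cphi * np.cos(lam)
    y = (n + h) * cphi * np.sin(lam)
    z = (n * (1.0 - WGS84_E2) + h) * sphi
    return x, y, z


def wgs84_to_ecef(p: GeoPoint) -> EcefPoint:
    """Geodetic to ECEF via the closed form with prime-vertical radius N(phi)."""
    x, y, z = _ecef_arrays(np.float64(p.lat), np.float64(p.lon), np.float64(p.h))
    return EcefPoint(float(x), float(y), float(z))


def wgs84_to_ecef_array(llh: np.ndarray) -> np.ndarray:
    """Vectorised geodetic-to-ECEF for an (N, 3) array of (lat, lon, h)."""
    llh = np.asarray(llh, dtype=float)
    lat, lon = llh[:, 0], llh[:, 1]
    if np.any(np.abs(lat) > 90.0):
        raise ValidationError("lat out of range [-90, 90] in cloud")
    if np.any(np.abs(lon) > 180.0):
        raise ValidationError("lon out of range [-180, 180] in cloud")
    return np.column_stack(_ecef_arrays(lat, lon, llh[:, 2]))


def _wgs84_from_ecef_arrays(x, y, z, max_iter: int = 30, tol: float = 1e-13):
    # Iterative latitude recovery; converges in a handful of steps near the surface.
    lon = np.arctan2(y, x)
    p = np.hypot(x, y)
    phi = np.arctan2(z, p * (1.0 - WGS84_E2))
    for _ in range(max_iter):
        sphi = np.sin(phi)
        n = WGS84_A / np.sqrt(1.0 - WGS84_E2 * sphi * sphi)
        h = p / np.cos(phi) - n
        phi_new = np.arctan2(z, p * (1.0 - WGS84_E2 * n / (n + h)))
        if np.all(np.abs(phi_new - phi) < tol):
            phi = phi_new
            break
        phi = phi_new
    else:
        raise NumericError("ecef_to_wgs84 did not converge")
    sphi = np.sin(phi)
    n = WGS84_A / np.sqrt(1.0 - WGS84_E2 * sphi * sphi)
    h = p / np.cos(phi) - n
    return np.degrees(phi), np.degrees(lon), h


def ecef_to_wgs84(p: EcefPoint) -> GeoPoint:
    """ECEF to geodetic (iterative); inverse of :func:`wgs84_to_ecef`."""
    if np.hypot(p.x, p.y) < 1.0:
        raise ValidationError("point on Earth rotation axis: longitude undefined")
    lat, lon, h = _wgs84_from_ecef_arrays(
        np.float64(p.x), np.float64(p.y), np.float64(p.z)
    )
    return GeoPoint(float(lat), float(lon), float(h))


def ecef_to_wgs84_array(xyz: np.ndarray) -> np.ndarray:
    """Vectorised ECEF-to-geodetic for an (N, 3) array; returns (lat, lon, h)."""
    xyz = np.asarray(xyz, dtype=float)
    if np.any(np.hypot(xyz[:, 0], xyz[:, 1]) < 1.0):
        raise ValidationError("point on Earth rotation axis: longitude undefined")
    lat, lon, h = _wgs84_from_ecef_arrays(xyz[:, 0], xyz[:, 1], xyz[:, 2])
    return np.column_stack([lat, lon, h])


@dataclass(frozen=True)
class LocalFrame:
    """East-north-up tangent frame: origin plus the ECEF-to-local rotation.

    Rotation rows are the east, north and up unit vectors expressed in ECEF,
    so local coordinates of an ECEF point m are ``rotation @ (m - origin_ecef)``.
    """

    origin_geo: GeoPoint
    origin_ecef: EcefPoint
    rotation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        if r.shape != (3, 3):
            raise ValidationError(f"rotation must be 3x3, got {r.shape}")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-12):
            raise ValidationError("rotation is not orthonormal")
        object.__setattr__(self, "rotation", r)

    def to_dict(self) -> dict:
        return {
            "origin_geo": [self.origin_geo.lat, self.origin_geo.lon, self.origin_geo.h],
            "origin_ecef": [self.origin_ecef.x, self.origin_ecef.y, self.origin_ecef.z],
            "rotation": self.rotation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LocalFrame":
        return cls(
            origin_geo=GeoPoint(*d["origin_geo"]),
            origin_ecef=EcefPoint(*d["origin_ecef"]),
            rotation=np.asarray(d["rotation"], dtype=float),
        )


def build_local_frame(origin: GeoPoint) -> LocalFrame:
    """Build the ENU frame at ``origin`` (rows: east, north, up)."""
    phi = np.radians(origin.lat)
    lam = np.radians(origin.lon)
    sphi, cphi = np.sin(phi), np.cos(phi)
    slam, clam = np.sin(lam), np.cos(lam)
    rotation = np.array(
        [
            [-slam, clam, 0.0],
            [-sphi * clam, -sphi * slam, cphi],
            [cphi * clam, cphi * slam, sphi],
        ]
    )
    return LocalFrame(
        origin_geo=origin, origin_ecef=wgs84_to_ecef(origin), rotation=rotation
    )


def to_local(frame: LocalFrame, p: EcefPoint | np.ndarray) -> np.ndarray:
    """ECEF point(s) to local ENU coordinates: R @ (p - O)."""
    o = frame.origin_ecef.as_array()
    if isinstance(p, EcefPoint):
        return frame.rotation @ (p.as_array() - o)
    xyz = np.asarray(p, dtype=float)
    return (xyz - o) @ frame.rotation.T


def from_local(frame: LocalFrame, xyz: np.ndarray) -> np.ndarray:
    """Local ENU coordinates back to ECEF: R^T @ p + O."""
    xyz = np.asarray(xyz, dtype=float)
    return xyz @ frame.rotation + frame.origin_ecef.as_array()


@dataclass
class GeorefPointCloud:
    """A point cloud tagged with the frame its coordinates live in.

    ``points`` is an (N, 3) float array; in WGS84 the columns are
    (lat, lon, h), otherwise Cartesian (x, y, z) in metres.  ``e`` holds
    per-point heights relative to the ground model once terrain processing
    has run.  ``local_frame`` is attached by :func:`localize_cloud` so the
    transform stays invertible.
    """

    frame: FrameTag
    points: np.ndarray
    e: Optional[np.ndarray] = None
    local_frame: Optional[LocalFrame] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValidationError(f"points must be (N, 3), got {pts.shape}")
        if self.frame not in ("WGS84", "ECEF", "LOCAL"):
            raise ValidationError(f"unknown frame tag {self.frame!r}")
        if self.e is not None:
            e = np.asarray(self.e, dtype=float)
            if e.shape != (pts.shape[0],):
                raise ValidationError("e must have one value per point")
            self.e = e
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]

    def with_e(self, e: np.ndarray) -> "GeorefPointCloud":
        return replace(self, e=np.asarray(e, dtype=float))


def select_origin(cloud: GeorefPointCloud) -> GeoPoint:
    """Componentwise-minimum geodetic corner of a WGS84 cloud.

    Reads "lowest point southwest of the area" as independent minima of
    latitude, longitude and height.
    """
    if cloud.frame != "WGS84":
        raise ValidationError("select_origin requires a WGS84 cloud")
    if len(cloud) == 0:
        raise ValidationError("cannot select origin of an empty cloud")
    mins = cloud.points.min(axis=0)
    return GeoPoint(float(mins[0]), float(mins[1]), float(mins[2]))


def localize_cloud(
    cloud: GeorefPointCloud, frame: Optional[LocalFrame] = None
) -> GeorefPointCloud:
    """Transform a WGS84 cloud into the local ENU frame (count preserved)."""
    if cloud.frame != "WGS84":
        raise ValidationError(f"localize_cloud expects WGS84 input, got {cloud.frame}")
    if len(cloud) == 0:
        raise ValidationError("cannot localize an empty cloud")
    if frame is None:
        frame = build_local_frame(select_origin(cloud))
    ecef = wgs84_to_ecef_array(cloud.points)
    local = to_local(frame, ecef)
    return GeorefPointCloud(frame="LOCAL", points=local, e=cloud.e, local_frame=frame)


def delocalize_cloud(cloud: GeorefPointCloud) -> GeorefPointCloud:
    """Inverse of :func:`localize_cloud` using the attached frame."""
    if cloud.frame != "LOCAL" or cloud.local_frame is None:
        raise ValidationError("delocalize_cloud needs a LOCAL cloud with its frame")
    ecef = from_local(cloud.local_frame, cloud.points)
    llh = ecef_to_wgs84_array(ecef)
    return GeorefPointCloud(frame="WGS84", points=llh, e=cloud.e)
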