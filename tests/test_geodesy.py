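import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uavcanopy.errors import ValidationError
from uavcanopy.geodesy import (
    GeoPoint,
    EcefPoint,
    GeorefPointCloud,
    build_local_frame,
    delocalize_cloud,
    ecef_to_wgs84,
    ecef_to_wgs84_array,
    from_local,
    localize_cloud,
    select_origin,
    to_local,
    wgs84_to_ecef,
    wgs84_to_ecef_array,
)

ORIGIN = GeoPoint(37.947351231, 117.835755425, 4.1627)


def oracle_geodetic_to_ecef(lat_deg, lon_deg, h):
    """Independent forward transform via the reduced (parametric) latitude.

    Surface point on the ellipsoid from the parametric latitude plus the
    ellipsoidal-normal offset; an algebraically different route from the
    prime-vertical-radius closed form used by the implementation.
    """
    a, f = 6378137.0, 1.0 / 298.257223563
    b = a * (1.0 - f)
    phi, lam = np.radians(lat_deg), np.radians(lon_deg)
    beta = np.arctan2((1.0 - f) * np.sin(phi), np.cos(phi))
    surface = np.array(
        [
            a * np.cos(beta) * np.cos(lam),
            a * np.cos(beta) * np.sin(lam),
            b * np.sin(beta),
        ]
    )
    normal = np.array(
        [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)]
    )
    return surface + h * normal


class TestWgs84ToEcef:
    def test_equator_prime_meridian(self):
        p = wgs84_to_ecef(GeoPoint(0.0, 0.0, 0.0))
        assert p.x == pytest.approx(6378137.0, abs=1e-9)
        assert p.y == pytest.approx(0.0, abs=1e-9)
        assert p.z == pytest.approx(0.0, abs=1e-9)

    def test_north_pole_semi_minor_axis(self):
        p = wgs84_to_ecef(GeoPoint(90.0, 0.0, 0.0))
        assert p.z == pytest.approx(6356752.3142, abs=1e-3)
        assert abs(p.x) < 1e-8 and abs(p.y) < 1e-8

    def test_field_origin_against_oracle(self):
        # Frozen oracle output for the field-anchor coordinate.
        expected = oracle_geodetic_to_ecef(37.947351231, 117.835755425, 4.1627)
        np.testing.assert_allclose(
            expected, [-2351515.8597, 4453308.2213, 3900839.8973], atol=1e-3
        )
        got = wgs84_to_ecef(ORIGIN)
        np.testing.assert_allclose([got.x, got.y, got.z], expected, atol=1e-6)

    @pytest.mark.parametrize("bad,field", [((91.0, 0.0), "lat"), ((0.0, 181.0), "lon")])
    def test_out_of_range_names_field(self, bad, field):
        with pytest.raises(ValidationError, match=field):
            GeoPoint(*bad)

    def test_oracle_agreement_seeded(self, rng):
        lat = rng.uniform(-89.0, 89.0, 100)
        lon = rng.uniform(-180.0, 180.0, 100)
        h = rng.uniform(-100.0, 5000.0, 100)
        got = wgs84_to_ecef_array(np.column_stack([lat, lon, h]))
        want = np.array(
            [oracle_geodetic_to_ecef(a, o, hh) for a, o, hh in zip(lat, lon, h)]
        )
        assert np.abs(got - want).max() < 1e-6


class TestEcefToWgs84:
    def test_equator_point(self):
        p = ecef_to_wgs84(EcefPoint(6378137.0, 0.0, 0.0))
        assert p.lat == pytest.approx(0.0, abs=1e-12)
        assert p.lon == pytest.approx(0.0, abs=1e-12)
        assert p.h == pytest.approx(0.0, abs=1e-9)

    def test_round_trip_origin(self):
        back = ecef_to_wgs84(wgs84_to_ecef(ORIGIN))
        assert back.lat == pytest.approx(ORIGIN.lat, abs=1e-9)
        assert back.lon == pytest.approx(ORIGIN.lon, abs=1e-9)
        assert back.h == pytest.approx(ORIGIN.h, abs=1e-6)

    def test_round_trip_fuzz(self, rng):
        llh = np.column_stack(
            [
                rng.uniform(-89.0, 89.0, 100),
                rng.uniform(-180.0, 180.0, 100),
                rng.uniform(-100.0, 5000.0, 100),
            ]
        )
        ecef = wgs84_to_ecef_array(llh)
        again = wgs84_to_ecef_array(ecef_to_wgs84_array(ecef))
        assert np.abs(again - ecef).max() < 1e-6

    def test_axis_point_rejected(self):
        with pytest.raises(ValidationError):
            ecef_to_wgs84(EcefPoint(0.0, 0.0, 6356752.0))


class TestSelectOrigin:
    def test_componentwise_minimum(self):
        cloud = GeorefPointCloud("WGS84", [(1, 2, 3), (0, 5, 9), (2, 0, 1)])
        o = select_origin(cloud)
        assert (o.lat, o.lon, o.h) == (0.0, 0.0, 1.0)

    def test_single_point(self):
        cloud = GeorefPointCloud("WGS84", [(10.0, 20.0, 3.0)])
        o = select_origin(cloud)
        assert (o.lat, o.lon, o.h) == (10.0, 20.0, 3.0)

    def test_empty_cloud_rejected(self):
        cloud = GeorefPointCloud("WGS84", np.empty((0, 3)))
        with pytest.raises(ValidationError):
            select_origin(cloud)

    def test_wrong_frame_rejected(self):
        cloud = GeorefPointCloud("LOCAL", [(0, 0, 0)])
        with pytest.raises(ValidationError):
            select_origin(cloud)


class TestLocalFrame:
    def test_equator_frame(self):
        frame = build_local_frame(GeoPoint(0.0, 0.0, 0.0))
        np.testing.assert_allclose(
            frame.rotation, [[0, 1, 0], [0, 0, 1], [1, 0, 0]], atol=1e-15
        )

    def test_field_origin_entries(self):
        r = np.round(build_local_frame(ORIGIN).rotation, 4)
        assert r[0, 0] == -0.8843
        assert r[1, 1] == -0.5438
        assert r[1, 2] == 0.7886
        assert r[2, 2] == 0.6149

    @settings(max_examples=50, deadline=None)
    @given(
        lat=st.floats(-89.9, 89.9),
        lon=st.floats(-180.0, 180.0),
    )
    def test_orthonormal_and_right_handed(self, lat, lon):
        r = build_local_frame(GeoPoint(lat, lon, 0.0)).rotation
        assert np.abs(r.T @ r - np.eye(3)).max() < 1e-12
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-12)

    def test_up_row_is_geodetic_normal(self):
        frame = build_local_frame(ORIGIN)
        phi, lam = np.radians(ORIGIN.lat), np.radians(ORIGIN.lon)
        normal = [
            np.cos(phi) * np.cos(lam),
            np.cos(phi) * np.sin(lam),
            np.sin(phi),
        ]
        np.testing.assert_allclose(frame.rotation[2], normal, atol=1e-15)


class TestToLocal:
    def test_origin_maps_to_zero(self):
        frame = build_local_frame(ORIGIN)
        np.testing.assert_allclose(
            to_local(frame, frame.origin_ecef), [0, 0, 0], atol=1e-9
        )

    def test_up_offset(self):
        frame = build_local_frame(ORIGIN)
        p = frame.origin_ecef.as_array() + 10.0 * frame.rotation[2]
        np.testing.assert_allclose(to_local(frame, p[None, :])[0], [0, 0, 10], atol=1e-8)

    def test_round_trip(self, rng):
        frame = build_local_frame(ORIGIN)
        pts = frame.origin_ecef.as_array() + rng.normal(0, 50, (200, 3))
        np.testing.assert_allclose(
            from_local(frame, to_local(frame, pts)), pts, atol=1e-9
        )

    def test_isometry(self):
        frame = build_local_frame(ORIGIN)
        a = frame.origin_ecef.as_array() + np.array([3.0, 5.0, 1.0])
        b = a + np.array([0.6, 0.0, 0.8])  # 1 m apart
        la, lb = to_local(frame, np.vstack([a, b]))
        assert np.linalg.norm(la - lb) == pytest.approx(
            np.linalg.norm(a - b), abs=1e-12
        )


class TestLocalizeCloud:
    def test_origin_only_cloud(self):
        cloud = GeorefPointCloud("WGS84", [[ORIGIN.lat, ORIGIN.lon, ORIGIN.h]])
        local = localize_cloud(cloud)
        np.testing.assert_allclose(local.points[0], [0, 0, 0], atol=1e-9)
        assert local.frame == "LOCAL" and local.local_frame is not None

    def test_field_extents(self, field):
        cloud, truth, _ = field
        frame = build_local_frame(truth.config.origin)
        local = localize_cloud(cloud, frame)
        assert len(local) == len(cloud)
        assert local.x.min() == pytest.approx(0.0, abs=0.05)
        assert local.x.max() == pytest.approx(40.0, abs=0.05)
        assert local.y.max() == pytest.approx(20.0, abs=0.05)

    def test_count_preserved_and_invertible(self, rng):
        llh = np.column_stack(
            [
                ORIGIN.lat + rng.uniform(0, 1e-4, 50),
                ORIGIN.lon + rng.uniform(0, 1e-4, 50),
                ORIGIN.h + rng.uniform(0, 2, 50),
            ]
        )
        cloud = GeorefPointCloud("WGS84", llh)
        local = localize_cloud(cloud)
        assert len(local) == 50
        back = delocalize_cloud(local)
        np.testing.assert_allclose(back.points[:, :2], llh[:, :2], atol=1e-9)
        np.testing.assert_allclose(back.points[:, 2], llh[:, 2], atol=1e-6)

    def test_non_wgs84_input_rejected(self):
        with pytest.raises(ValidationError):
            localize_cloud(GeorefPointCloud("ECEF", [(1e6, 1e6, 1e6)]))
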