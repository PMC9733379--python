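import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from uavcanopy.errors import DegenerateGeometryError, ValidationError
from uavcanopy.geodesy import GeorefPointCloud
from uavcanopy.terrain import (
    Plane,
    SampleRegion,
    corridor_planes,
    extract_region,
    fit_plane_orthogonal,
    ground_from_samples,
    lowest_region,
    plane_objective,
    relative_heights,
)


def brute_force_plane_objective(points):
    """Best normalised squared-offset objective by dense search over normals.

    Coarse spherical sweep (about 1e-3 rad resolution) refined with a local
    optimiser; independent of the SVD route used in production.
    """
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)

    def objective(angles):
        t, p = angles
        n = np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])
        return plane_objective(pts, n, centroid)

    thetas = np.linspace(0.0, np.pi, 700)
    phis = np.linspace(0.0, 2.0 * np.pi, 1400)
    tt, pp = np.meshgrid(thetas, phis, indexing="ij")
    nx = np.sin(tt) * np.cos(pp)
    ny = np.sin(tt) * np.sin(pp)
    nz = np.cos(tt)
    centered = pts - centroid
    # sum_n (c_n . v)^2 is the quadratic form v' (C'C) v, evaluated densely.
    m = centered.T @ centered
    normals = np.stack([nx, ny, nz], axis=-1)
    obj = np.einsum("ijk,kl,ijl->ij", normals, m, normals)
    i, j = np.unravel_index(np.argmin(obj), obj.shape)
    best = minimize(objective, [thetas[i], phis[j]], method="Nelder-Mead")
    return min(best.fun, obj[i, j])


class TestFitPlane:
    def test_three_points_exact(self):
        pts = [(0, 0, 1.0), (1, 0, 2.0), (0, 1, 3.0)]
        plane = fit_plane_orthogonal(pts)
        assert plane_objective(pts, plane.normal, plane.centroid) < 1e-24

    def test_flat_cloud(self, rng):
        pts = np.column_stack([rng.uniform(0, 10, (100, 2)), np.zeros(100)])
        plane = fit_plane_orthogonal(pts)
        np.testing.assert_allclose(plane.normal, [0, 0, 1], atol=1e-12)
        assert plane.centroid[2] == pytest.approx(0.0, abs=1e-12)

    def test_against_brute_force_oracle(self, rng):
        x = rng.uniform(0, 5, 500)
        y = rng.uniform(0, 5, 500)
        z = 0.02 * x - 0.01 * y + 3.0 + rng.normal(0, 0.005, 500)
        pts = np.column_stack([x, y, z])
        plane = fit_plane_orthogonal(pts)
        got = plane_objective(pts, plane.normal, plane.centroid)
        want = brute_force_plane_objective(pts)
        assert got <= want + 1e-6

    def test_beats_random_normals(self, rng):
        pts = rng.normal(0, 1, (200, 3)) * [3.0, 2.0, 0.1]
        plane = fit_plane_orthogonal(pts)
        best = plane_objective(pts, plane.normal, plane.centroid)
        normals = rng.normal(size=(1000, 3))
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        centroid = pts.mean(axis=0)
        for n in normals:
            assert best <= plane_objective(pts, n, centroid) + 1e-9

    def test_rotation_invariant_objective(self, rng):
        pts = np.column_stack(
            [rng.uniform(0, 5, (300, 2)), rng.normal(0, 0.01, 300)]
        )
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), 0, np.sin(theta)],
                [0, 1, 0],
                [-np.sin(theta), 0, np.cos(theta)],
            ]
        )
        p1 = fit_plane_orthogonal(pts)
        p2 = fit_plane_orthogonal(pts @ rot.T)
        o1 = plane_objective(pts, p1.normal, p1.centroid)
        o2 = plane_objective(pts @ rot.T, p2.normal, p2.centroid)
        assert abs(o1 - o2) < 1e-9

    def test_upward_normal(self, rng):
        pts = np.column_stack([rng.uniform(0, 5, (50, 2)), rng.normal(5, 0.1, 50)])
        assert fit_plane_orthogonal(pts).q > 0

    def test_too_few_points(self):
        with pytest.raises(DegenerateGeometryError):
            fit_plane_orthogonal([(0, 0, 0), (1, 1, 1)])

    def test_collinear_points(self):
        pts = np.outer(np.linspace(0, 1, 10), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateGeometryError):
            fit_plane_orthogonal(pts)


class TestLowestRegion:
    def _region(self, rid, z):
        pts = np.column_stack([np.random.default_rng(0).uniform(0, 1, (10, 2)), np.full(10, z)])
        return SampleRegion(id=rid, bounds=(0, 0, 1, 1), points=pts)

    def test_lower_centroid_wins(self):
        a, b = self._region("a", 1.0), self._region("b", 1.2)
        assert lowest_region(a, b) is a
        assert lowest_region(b, a) is a

    def test_tie_goes_to_first(self):
        a, b = self._region("a", 1.0), self._region("b", 1.0)
        assert lowest_region(a, b) is a
        assert lowest_region(b, a) is b

    def test_empty_region_rejected(self):
        a = self._region("a", 1.0)
        empty = SampleRegion(id="e", bounds=(0, 0, 1, 1), points=np.empty((0, 3)))
        with pytest.raises(ValidationError, match="e"):
            lowest_region(a, empty)

    def test_downslope_quadrat_selected(self, rng):
        # Sloped ground: the region further down the gradient always wins.
        def ground(x0):
            x = rng.uniform(x0, x0 + 1, 200)
            y = rng.uniform(0, 1, 200)
            return np.column_stack([x, y, 0.05 * x + rng.normal(0, 0.002, 200)])

        low = SampleRegion(id="low", bounds=(0, 0, 1, 1), points=ground(0.0))
        high = SampleRegion(id="high", bounds=(5, 0, 6, 1), points=ground(5.0))
        assert lowest_region(high, low) is low


class TestRelativeHeights:
    def test_points_on_plane_are_zero(self, rng):
        plane = fit_plane_orthogonal(
            np.column_stack(
                [rng.uniform(0, 5, (100, 2)), np.zeros(100)]
            )
            + np.array([0, 0, 2.0])
        )
        x, y = rng.uniform(0, 5, (2, 50))
        pts = np.column_stack([x, y, np.full(50, 2.0)])
        np.testing.assert_allclose(relative_heights(pts, plane), 0.0, atol=1e-10)

    def test_horizontal_plane_offset(self):
        plane = Plane(normal=[0, 0, 1], centroid=[0, 0, 2.0])
        e = relative_heights(np.array([[7.0, -3.0, 5.0]]), plane)
        assert e[0] == pytest.approx(3.0, abs=1e-12)

    def test_tilted_plane_matches_surface_height(self, rng):
        x = rng.uniform(0, 5, 200)
        y = rng.uniform(0, 5, 200)
        z = 0.1 * x - 0.05 * y + 1.0
        plane = fit_plane_orthogonal(np.column_stack([x, y, z]))
        probe = np.array([[2.0, 3.0, 4.0]])
        e = relative_heights(probe, plane)
        surface = plane.height_at(2.0, 3.0)
        assert e[0] == pytest.approx(4.0 - surface, abs=1e-10)

    def test_exactly_planar_cloud(self, rng):
        x = rng.uniform(0, 5, 300)
        y = rng.uniform(0, 5, 300)
        pts = np.column_stack([x, y, 0.02 * x - 0.01 * y + 3.0])
        plane = fit_plane_orthogonal(pts)
        assert np.abs(relative_heights(pts, plane)).max() < 1e-10

    def test_vertical_plane_rejected(self):
        plane = Plane.__new__(Plane)
        object.__setattr__(plane, "normal", np.array([1.0, 0.0, 0.0]))
        object.__setattr__(plane, "centroid", np.zeros(3))
        with pytest.raises(DegenerateGeometryError):
            relative_heights(np.array([[0.0, 0.0, 1.0]]), plane)


class TestGroundFromSamples:
    def _tables(self, p99, h_c):
        ids = [f"q{i}" for i in range(len(p99))]
        p = pd.DataFrame({"quadrat_id": ids, "plot_id": "plot0", "p99": p99})
        m = pd.DataFrame({"quadrat_id": ids, "plot_id": "plot0", "h_c": h_c})
        return p, m

    def test_inverted_mode(self):
        p, m = self._tables([1.0, 1.1, 1.0, 0.9], [0.6, 0.7, 0.6, 0.5])
        gm = ground_from_samples(p, m)
        assert gm.per_plot["plot0"] == pytest.approx(0.4, abs=1e-12)
        assert gm.per_quadrat["q0"] == pytest.approx(0.4, abs=1e-12)

    def test_as_printed_mode(self):
        p, m = self._tables([1.0, 1.1, 1.0, 0.9], [0.6, 0.7, 0.6, 0.5])
        gm = ground_from_samples(p, m, mode="as-printed")
        assert gm.per_plot["plot0"] == pytest.approx(1.0, abs=1e-12)

    def test_missing_measurement_names_plot(self):
        p, m = self._tables([1.0, 1.1, 1.0, 0.9], [0.6, np.nan, 0.6, 0.5])
        with pytest.raises(ValidationError, match="plot0"):
            ground_from_samples(p, m)

    def test_constant_ground_recovered_exactly(self, rng):
        h_c = rng.uniform(0.4, 0.8, 4)
        p, m = self._tables(h_c + 0.25, h_c)
        gm = ground_from_samples(p, m)
        assert gm.per_plot["plot0"] == pytest.approx(0.25, abs=1e-12)

    def test_unknown_mode(self):
        p, m = self._tables([1.0] * 4, [0.5] * 4)
        with pytest.raises(ValidationError):
            ground_from_samples(p, m, mode="sideways")


class TestCorridorPlanes:
    def test_plane_fits_lower_region(self, rng):
        def region(rid, x0):
            x = rng.uniform(x0, x0 + 1, 100)
            y = rng.uniform(0, 1, 100)
            z = 0.05 * x + rng.normal(0, 0.001, 100)
            return SampleRegion(id=rid, bounds=(x0, 0, x0 + 1, 1), points=np.column_stack([x, y, z]))

        regions = [region("a", 0.0), region("b", 4.0), region("c", 8.0)]
        planes = corridor_planes(regions)
        assert len(planes) == 2
        for (plane, corridor), low in zip(planes, regions[:2]):
            # Lower region's centroid lies on the fitted plane.
            e = relative_heights(low.points, plane)
            assert abs(e.mean()) < 1e-6
            assert corridor[0] <= low.bounds[0]

    def test_extract_region_filters(self, rng):
        pts = np.column_stack([rng.uniform(0, 10, (500, 2)), rng.uniform(0, 1, 500)])
        cloud = GeorefPointCloud("LOCAL", pts)
        region = extract_region(cloud, (2, 2, 4, 4), id="r")
        assert np.all((region.points[:, 0] >= 2) & (region.points[:, 0] < 4))
        low = extract_region(cloud, (2, 2, 4, 4), id="r", lowest_fraction=0.2)
        assert len(low) <= max(3, int(np.ceil(0.2 * len(region))))
        assert low.points[:, 2].max() <= np.percentile(region.points[:, 2], 25)

    def test_single_region_rejected(self, rng):
        r = SampleRegion(id="a", bounds=(0, 0, 1, 1), points=rng.uniform(0, 1, (10, 3)))
        with pytest.raises(ValidationError):
            corridor_planes([r])
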