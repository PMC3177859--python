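"""Normal-ray distance maps, nearest-point and slice-constrained distances."""

import numpy as np
import pytest

from scalpmap import _geometry
from scalpmap.distances import (nearest_scalp_distance, ray_normal_distance_map,
                                slice_constrained_distance, summarize_region,
                                DistanceMap)
from scalpmap.surfaces import SurfaceMesh


class TestRayNormalDistanceMap:
    def test_concentric_sphere_gap(self, small_distance_map, small_phantom):
        _, truth = small_phantom
        mean, sd, n = summarize_region(small_distance_map)
        true_gap = truth.true_distance([0, 0, 1.0])
        spacing = truth.spacing[0]
        assert abs(mean - true_gap) < spacing
        assert n > 1000

    def test_coefficient_of_variation_small(self, small_distance_map):
        mean, sd, _ = summarize_region(small_distance_map)
        assert sd / mean < 0.05

    def test_hull_equals_scalp_gives_zero(self, icosphere):
        dmap = ray_normal_distance_map(icosphere, icosphere)
        assert dmap.valid.all()
        assert np.nanmax(dmap.distance) < 1e-6

    def test_hole_in_scalp_invalidates_polar_vertices(self, icosphere):
        # remove the polar cap (z > 19): rays from polar hull vertices escape
        hull = icosphere
        cap = hull.vertices[hull.faces].mean(axis=1)[:, 2] > 19.0
        scalp_tm = SurfaceMesh(
            vertices=hull.vertices * 1.2,  # scalp = inflated sphere
            faces=hull.faces[~cap],
        )
        dmap = ray_normal_distance_map(hull, scalp_tm, max_distance=50.0)
        polar = hull.vertices[:, 2] > 19.5
        equatorial = np.abs(hull.vertices[:, 2]) < 5.0
        assert not dmap.valid[polar].any()
        assert dmap.valid[equatorial].all()
        assert np.allclose(dmap.distance[equatorial], 4.0, atol=0.2)

    def test_no_hit_beyond_max_distance_invalid(self, icosphere):
        scalp = SurfaceMesh(vertices=icosphere.vertices * 10.0,
                            faces=icosphere.faces)
        dmap = ray_normal_distance_map(icosphere, scalp, max_distance=50.0)
        assert not dmap.valid.any()

    def test_hull_without_normals_rejected(self, icosphere):
        bare = SurfaceMesh(vertices=icosphere.vertices, faces=icosphere.faces)
        with pytest.raises(ValueError, match="normals"):
            ray_normal_distance_map(bare, icosphere)

    def test_monotone_under_scalp_inflation(self, small_surfaces,
                                            small_distance_map):
        # inflating the scalp by delta increases every distance by ~delta
        delta = 3.0
        scalp = small_surfaces["scalp"]
        r = np.linalg.norm(scalp.vertices, axis=1, keepdims=True)
        inflated = SurfaceMesh(vertices=scalp.vertices * (1 + delta / r),
                               faces=scalp.faces)
        from scalpmap.surfaces import truncate_ventral
        hull = truncate_ventral(small_surfaces["hull"], cut_fraction=0.3)
        dmap2 = ray_normal_distance_map(hull, inflated)
        both = small_distance_map.valid & dmap2.valid
        diff = dmap2.distance[both] - small_distance_map.distance[both]
        voxel = small_surfaces["volume"].spacing[0]
        assert np.abs(diff - delta).max() <= voxel


class TestNearestScalpDistance:
    def test_sphere_analytic_distance(self, small_surfaces):
        truth = small_surfaces["truth"]
        scalp = small_surfaces["scalp"]
        lm = np.array([truth.brain_semiaxes[0], 0.0, 0.0])  # +x brain pole
        res = nearest_scalp_distance(lm, scalp)
        true = truth.scalp_semiaxes[0] - truth.brain_semiaxes[0]
        assert res.distance == pytest.approx(true, abs=0.5)
        assert res.verified

    def test_landmark_on_vertex_gives_zero(self, icosphere):
        res = nearest_scalp_distance(icosphere.vertices[17], icosphere)
        assert res.distance == 0.0
        assert np.allclose(res.closest_point, icosphere.vertices[17])

    def test_invariant_distance_matches_closest_point(self, small_surfaces):
        for lm in small_surfaces["landmarks"]:
            res = nearest_scalp_distance(lm, small_surfaces["scalp"])
            d = np.linalg.norm(np.asarray(lm.position) - res.closest_point)
            assert res.distance == pytest.approx(d, abs=1e-9)

    def test_far_landmark_flagged_unverified(self, icosphere):
        res = nearest_scalp_distance(np.array([500.0, 0, 0]), icosphere,
                                     max_distance=100.0)
        assert not res.verified

    def test_indexed_equals_bruteforce(self, icosphere):
        rng = np.random.default_rng(11)
        pts = rng.uniform(-30, 30, size=(100, 3))
        for p in pts:
            d1, c1, f1 = _geometry.nearest_point(p, icosphere.vertices,
                                                 icosphere.faces)
            d2, c2, f2 = _geometry.nearest_point_bruteforce(
                p, icosphere.vertices, icosphere.faces)
            assert d1 == d2 and f1 == f2
            assert np.array_equal(c1, c2)

    def test_ray_indexed_equals_bruteforce(self, tilted_ellipsoid):
        rng = np.random.default_rng(5)
        origins = rng.uniform(-5, 5, size=(50, 3))
        dirs = rng.normal(size=(50, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        t1, f1 = _geometry.ray_first_hit(origins, dirs,
                                         tilted_ellipsoid.vertices,
                                         tilted_ellipsoid.faces, 200.0)
        t2, f2 = _geometry.ray_first_hit_bruteforce(origins, dirs,
                                                    tilted_ellipsoid.vertices,
                                                    tilted_ellipsoid.faces,
                                                    200.0)
        assert np.array_equal(t1, t2)
        assert np.array_equal(f1, f2)


class TestSliceConstrainedDistance:
    def test_slice_never_below_3d(self, tilted_ellipsoid):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-8, 8, size=(20, 3))
        for p in pts:
            d3 = nearest_scalp_distance(p, tilted_ellipsoid).distance
            for plane in ("axial", "coronal", "sagittal"):
                ds = slice_constrained_distance(p, tilted_ellipsoid, plane)
                assert ds >= d3 - 1e-9

    def test_sphere_equatorial_plane_equality(self, icosphere):
        lm = np.array([10.0, 0.0, 0.0])  # on the z=0 symmetry plane
        d3 = nearest_scalp_distance(lm, icosphere).distance
        ds = slice_constrained_distance(lm, icosphere, "axial")
        assert ds == pytest.approx(d3, abs=0.05)

    def test_tilted_ellipsoid_strict_overestimate(self, tilted_ellipsoid):
        # off-axis interior point: closest 3D point lies out of plane, so
        # the in-plane distance is strictly larger (margin via dense oracle)
        lm = np.array([5.0, -6.0, 7.0])
        d3 = nearest_scalp_distance(lm, tilted_ellipsoid).distance
        ds = slice_constrained_distance(lm, tilted_ellipsoid, "axial")
        assert ds > d3 + 0.05
        # brute-force oracle: dense sampling of the mesh cross-section
        import trimesh
        section = trimesh.intersections.mesh_plane(
            tilted_ellipsoid.as_trimesh(), (0.0, 0.0, 1.0), lm)
        samples = np.concatenate([
            s[0] + np.linspace(0, 1, 50)[:, None] * (s[1] - s[0])
            for s in section
        ])
        oracle = np.linalg.norm(samples - lm, axis=1).min()
        assert ds == pytest.approx(oracle, abs=1e-3)

    def test_empty_intersection_rejected(self, icosphere):
        with pytest.raises(ValueError, match="does not intersect"):
            slice_constrained_distance(np.array([0.0, 0, 100.0]), icosphere,
                                       "axial")

    def test_unknown_plane_rejected(self, icosphere):
        with pytest.raises(ValueError, match="unknown plane"):
            slice_constrained_distance(np.zeros(3), icosphere, "oblique")


class TestDominance:
    def test_nearest_at_most_normal_ray(self, small_surfaces):
        """The nearest-point distance is a minimum over all directions, so
        it can never exceed the normal-ray distance from the same point."""
        truth = small_surfaces["truth"]
        scalp = small_surfaces["scalp"]
        for lm in small_surfaces["landmarks"]:
            p = np.asarray(lm.position)
            normal = truth.surface_normal(p, boundary=0)
            t, _ = _geometry.ray_first_hit(p[None], normal[None],
                                           scalp.vertices, scalp.faces, 100.0)
            d_near = nearest_scalp_distance(p, scalp).distance
            assert d_near <= t[0] + 1e-9


class TestSummarizeRegion:
    @staticmethod
    def _map_from_values(icosphere, values, valid=None):
        n = icosphere.n_vertices
        valid = np.ones(n, bool) if valid is None else valid
        vals = np.where(valid, np.resize(values, n).astype(float), np.nan)
        return DistanceMap(hull=icosphere, distance=vals, valid=valid,
                           hit_point=np.zeros((n, 3)))

    def test_constant_map(self, icosphere):
        dmap = self._map_from_values(icosphere, [7.6])
        mean, sd, n = summarize_region(dmap)
        assert (mean, sd, n) == (7.6, 0.0, icosphere.n_vertices)

    def test_two_value_mean(self, icosphere):
        dmap = self._map_from_values(icosphere, [6.0, 8.0])
        mean, _, _ = summarize_region(dmap)
        assert mean == pytest.approx(7.0, abs=1e-12)

    def test_all_invalid_region_rejected(self, icosphere):
        dmap = self._map_from_values(icosphere, [7.6])
        region = np.zeros(icosphere.n_vertices, bool)
        with pytest.raises(ValueError, match="no valid vertices"):
            summarize_region(dmap, region)

    def test_invalid_vertices_excluded(self, icosphere):
        valid = np.ones(icosphere.n_vertices, bool)
        valid[::2] = False
        dmap = self._map_from_values(icosphere, [5.0], valid=valid)
        mean, sd, n = summarize_region(dmap)
        assert n == int(valid.sum())
        assert mean == 5.0
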