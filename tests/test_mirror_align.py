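import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import facesym as fs
from facesym.mirror_align import (RigidTransform, closest_points_on_mesh,
                                  reflect_points)
from .conftest import flat_grid


def brute_force_point_triangle_distance(p, tri):
    """Independent scalar oracle: barycentric interior test plus explicit
    clamped projections onto the three edges."""
    a, b, c = tri
    n = np.cross(b - a, c - a)
    n2 = n @ n
    best = np.inf
    if n2 > 0:
        # barycentric coordinates of the in-plane projection
        w = np.cross(b - a, p - a) @ n / n2
        v = np.cross(p - a, c - a) @ n / n2
        u = 1.0 - v - w
        if u >= 0 and v >= 0 and w >= 0:
            best = abs((p - a) @ n) / np.sqrt(n2)
    for e0, e1 in ((a, b), (b, c), (c, a)):
        d = e1 - e0
        t = np.clip((p - e0) @ d / (d @ d), 0.0, 1.0)
        best = min(best, np.linalg.norm(p - (e0 + t * d)))
    return best


class TestMirrorPlane:
    def test_points_in_x0_plane(self):
        lm = _landmarks_with_midline(np.array(
            [[0, 80, 10], [0, 30, 40], [0, -10, 45], [0, -45, 35]], dtype=float))
        plane = fs.fit_mirror_plane(lm)
        assert abs(abs(plane.normal[0]) - 1.0) < 1e-9
        assert abs(plane.signed_distance(np.zeros(3))) < 1e-9

    def test_coplanar_tilted_points_interpolated(self):
        # four coplanar points on a tilted plane: residual is exact zero
        basis = np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0]])
        coeffs = np.array([[0, 0], [1.0, 0], [0, 1.0], [1.0, 1.0]])
        pts = coeffs @ basis + np.array([5.0, -2.0, 3.0])
        lm = _landmarks_with_midline(pts)
        plane = fs.fit_mirror_plane(lm)
        res = plane.signed_distance(pts)
        assert float(np.sum(res ** 2)) < 1e-18

    def test_matches_dense_grid_oracle(self):
        """TLS fit within 0.5 degrees of exhaustive normal-grid minimisation."""
        rng = np.random.default_rng(11)
        pts = np.array([[0, 80, 10], [0, 30, 40], [0, -10, 45], [0, -45, 35]],
                       dtype=float) + rng.normal(scale=1.5, size=(4, 3))
        lm = _landmarks_with_midline(pts)
        plane = fs.fit_mirror_plane(lm)

        centered = pts - pts.mean(axis=0)
        # Fibonacci sphere of candidate normals (angular spacing << 0.5 deg)
        k = np.arange(300000)
        phi = np.arccos(1 - 2 * (k + 0.5) / len(k))
        theta = np.pi * (1 + 5 ** 0.5) * k
        normals = np.column_stack([np.sin(phi) * np.cos(theta),
                                   np.sin(phi) * np.sin(theta), np.cos(phi)])
        sse = np.sum((centered @ normals.T) ** 2, axis=0)
        best = normals[np.argmin(sse)]
        angle = np.degrees(np.arccos(min(1.0, abs(best @ plane.normal))))
        assert angle < 0.5

    def test_normal_points_to_anatomical_left(self, base_face):
        _, lm = base_face
        plane = fs.fit_mirror_plane(lm)
        assert plane.signed_distance(lm["En_L"]) > 0
        assert plane.signed_distance(lm["En_R"]) < 0


def _landmarks_with_midline(mid):
    coords = {name: mid[i] for i, name in enumerate(("Tr", "N", "Sn", "Li"))}
    for base, y in (("En", 30.0), ("Ex", 30.0), ("Ch", -30.0)):
        coords[f"{base}_L"] = [15.0, y, 30.0]
        coords[f"{base}_R"] = [-15.0, y, 30.0]
    return fs.LandmarkSet(coords)


class TestReflect:
    def test_involution_and_isometry(self, base_face):
        mesh, _ = base_face
        plane = fs.OrientedPlane([1.0, -2.0, 3.0], [0.3, 0.5, -0.8])
        once = fs.reflect(mesh, plane)
        twice = fs.reflect(once, plane)
        assert np.abs(twice.vertices - mesh.vertices).max() < 1e-12
        # isometry: pairwise distances of a vertex sample preserved
        idx = np.arange(0, mesh.n_vertices, 97)
        orig = mesh.vertices[idx]
        refl = once.vertices[idx]
        d0 = np.linalg.norm(orig[:, None] - orig[None], axis=-1)
        d1 = np.linalg.norm(refl[:, None] - refl[None], axis=-1)
        assert np.abs(d0 - d1).max() < 1e-9

    def test_point_on_plane_fixed(self):
        plane = fs.OrientedPlane([0, 0, 0], [1, 0, 0])
        assert np.allclose(reflect_points(np.array([0.0, 3.0, 4.0]), plane),
                           [0, 3, 4])
        assert np.allclose(reflect_points(np.array([1.0, 0.0, 0.0]), plane),
                           [-1, 0, 0])


class TestPointToSurface:
    def test_mesh_vs_itself(self, base_face):
        mesh, _ = base_face
        dmap = fs.point_to_surface_distance(mesh, mesh)
        assert dmap.distances.max() < 1e-9

    def test_parallel_planes(self):
        grid = flat_grid(n=6)
        lifted = fs.TriangleMesh(grid.vertices + [0, 0, 0.7], grid.faces)
        dmap = fs.point_to_surface_distance(grid, lifted)
        assert np.abs(dmap.distances - 0.7).max() < 1e-9

    def test_matches_brute_force_oracle(self, tetrahedron):
        """200 random points vs a small mesh: exact agreement with the
        independent per-triangle oracle."""
        rng = np.random.default_rng(5)
        # ~50-triangle mesh: a jittered flat grid
        grid = flat_grid(n=6)
        mesh = fs.TriangleMesh(
            grid.vertices + rng.normal(scale=0.2, size=grid.vertices.shape),
            grid.faces)
        points = rng.uniform(-2, 7, size=(200, 3))
        dist, _ = closest_points_on_mesh(points, mesh)
        tris = mesh.triangles()
        for i, p in enumerate(points):
            oracle = min(brute_force_point_triangle_distance(p, t) for t in tris)
            assert abs(dist[i] - oracle) < 1e-9

    def test_weights_come_from_source_mesh(self, base_face):
        mesh, _ = base_face
        dmap = fs.point_to_surface_distance(mesh, mesh)
        np.testing.assert_allclose(dmap.weights, mesh.vertex_area_weights())
        assert np.isclose(dmap.weights.sum(), mesh.area())


class TestRigidTransform:
    def test_rejects_improper_rotation(self):
        with pytest.raises(ValueError, match="proper"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_compose_inverse(self):
        r1 = RigidTransform(Rotation.from_euler("xyz", [10, 20, 30], degrees=True
                                                ).as_matrix(), [1.0, -2.0, 0.5])
        pts = np.random.default_rng(0).normal(size=(10, 3))
        round_trip = r1.inverse().apply(r1.apply(pts))
        assert np.abs(round_trip - pts).max() < 1e-9


class TestICP:
    def test_identity_on_identical_meshes(self, base_face):
        mesh, _ = base_face
        res = fs.icp_register(mesh, mesh)
        assert np.abs(res.transform.rotation - np.eye(3)).max() < 1e-9
        assert np.abs(res.transform.translation).max() < 1e-9

    def test_recovers_known_transform(self, base_face):
        """A 5 degree / (2,1,0) mm perturbation is recovered to < 0.01 mm."""
        mesh, _ = base_face
        R = Rotation.from_euler("z", 5, degrees=True).as_matrix()
        t = np.array([2.0, 1.0, 0.0])
        moving = fs.TriangleMesh(mesh.vertices @ R.T + t, mesh.faces)
        # closest-point/Kabsch iteration converges linearly; give it room
        res = fs.icp_register(moving, mesh, max_iter=400)
        recovered = res.transform.apply(moving.vertices)
        assert np.abs(recovered - mesh.vertices).max() < 0.01

    def test_rms_monotone_under_noise(self, base_face):
        mesh, _ = base_face
        rng = np.random.default_rng(2)
        verts = mesh.vertices.copy()
        idx = rng.choice(len(verts), size=int(0.3 * len(verts)), replace=False)
        verts[idx] += rng.normal(scale=0.5, size=(len(idx), 3))
        noisy = fs.TriangleMesh(verts, mesh.faces)
        res = fs.icp_register(noisy, mesh, max_iter=30)
        rms = np.asarray(res.rms_history)
        assert (np.diff(rms) <= 1e-12).all()
        assert rms[-1] <= rms[0]


class TestMirrorAndMatch:
    def test_symmetric_face_scores_zero(self, base_face):
        mesh, lm = base_face
        dmap = fs.mirror_and_match(mesh, lm)
        assert dmap.distances.max() < 0.05

    def test_chin_injection_classified_asymmetric(self, base_face):
        mesh, lm = base_face
        bumped, _ = fs.inject_asymmetry(
            mesh, lm, fs.AsymmetrySpec(region="chin", side="left",
                                       delta=3.0, sigma=10.0))
        planes = fs.build_planes(lm)
        labels = fs.assign_regions(bumped, planes).labels
        dmap = fs.mirror_and_match(bumped, lm)
        chin = labels == fs.REGION_IDS["chin"]
        peak = dmap.distances[chin].max()
        assert 1.0 < peak
        assert 2.0 <= peak <= 6.0

    def test_rigid_invariance(self, base_face):
        """A global rigid motion of the input changes no distance by 0.01 mm."""
        mesh, lm = base_face
        bumped, _ = fs.inject_asymmetry(
            mesh, lm, fs.AsymmetrySpec(region="cheek", side="right",
                                       delta=2.0, sigma=12.0))
        d0 = fs.mirror_and_match(bumped, lm).distances
        R = Rotation.from_euler("xyz", [7, -12, 25], degrees=True).as_matrix()
        t = np.array([30.0, -14.0, 8.0])
        moved = fs.TriangleMesh(bumped.vertices @ R.T + t, bumped.faces)
        moved_lm = lm.transformed(lambda pts: pts @ R.T + t)
        d1 = fs.mirror_and_match(moved, moved_lm).distances
        assert np.abs(d0 - d1).max() < 0.01
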