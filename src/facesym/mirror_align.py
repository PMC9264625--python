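"""Mirror-plane construction, mesh reflection, rigid ICP, and distance maps.

The core measurement: fit the midsagittal (mirror) plane through the four
midline landmarks, reflect the whole facial surface through it, rigidly
register the mirrored shell back onto the original by point-to-surface ICP,
and record each original vertex's unsigned distance to the registered shell.
A perfectly symmetric face maps onto itself and every distance is ~0.

Reflecting the whole mesh and registering it to the original is
mathematically equivalent, for distance mapping, to mirroring each half and
superimposing it on the opposite half — and needs no cut boundary.
Registration is rigid only (no scaling: a scale step would absorb genuine
asymmetry signal) with nearest-point-on-surface correspondence, which is
robust to unequal tessellation of shell versus original.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mesh_core import LandmarkSet, OrientedPlane, TriangleMesh

__all__ = [
    "RigidTransform",
    "DistanceMap",
    "ICPResult",
    "fit_mirror_plane",
    "reflect",
    "icp_register",
    "point_to_surface_distance",
    "closest_points_on_mesh",
    "mirror_and_match",
    "SurfaceDistanceQuery",
]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x -> R x + t (rotation + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthogonal (R^T R = I within 1e-9)")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det R = +1); reflections are not rigid")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform applying ``other`` first, then ``self``."""
        R = _reorthonormalize(self.rotation @ other.rotation)
        t = self.rotation @ other.translation + self.translation
        return RigidTransform(R, t)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def _reorthonormalize(R: np.ndarray) -> np.ndarray:
    # project back onto SO(3); guards against drift when composing many updates
    U, _, Vt = np.linalg.svd(R)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt


@dataclass
class DistanceMap:
    """Per-vertex unsigned distance to a target surface, with area weights.

    ``distances`` are millimetres; ``weights`` are the source mesh's
    barycentric vertex areas (mm^2), so weighted percentages are
    tessellation-robust.
    """

    distances: np.ndarray
    weights: np.ndarray
    source_mesh: TriangleMesh | None = None

    def __post_init__(self):
        d = np.asarray(self.distances, dtype=np.float64).reshape(-1)
        w = np.asarray(self.weights, dtype=np.float64).reshape(-1)
        if d.shape != w.shape:
            raise ValueError("distances and weights must have equal length")
        if not np.isfinite(d).all() or (d < 0).any():
            raise ValueError("distances must be finite and non-negative")
        if (w < 0).any():
            raise ValueError("area weights must be non-negative")
        self.distances = d
        self.weights = w


# ---------------------------------------------------------------------------
# Mirror plane
# ---------------------------------------------------------------------------

def fit_mirror_plane(landmarks: LandmarkSet) -> OrientedPlane:
    """Total-least-squares plane through the midline landmarks Tr, N, Sn, Li.

    Four points over-determine a plane; the TLS fit minimises the sum of
    squared point-plane distances (smallest principal direction of the
    centred points).  The normal is oriented from the subject's right toward
    the left, so the positive half-space is the anatomical left.
    """
    mid = landmarks.midline_points()
    centroid = mid.mean(axis=0)
    centered = mid - centroid
    _, svals, Vt = np.linalg.svd(centered, full_matrices=True)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        raise ValueError("degenerate configuration: midline landmarks are collinear")
    normal = Vt[2]
    left = np.mean([landmarks[n] for n in ("En_L", "Ex_L", "Ch_L")], axis=0)
    right = np.mean([landmarks[n] for n in ("En_R", "Ex_R", "Ch_R")], axis=0)
    if normal @ (left - right) < 0:
        normal = -normal
    return OrientedPlane(centroid, normal)


def reflect(mesh: TriangleMesh, plane: OrientedPlane) -> TriangleMesh:
    """Reflect every vertex through ``plane``: v -> v - 2((v-p)·n) n.

    Face winding is flipped so outward normals survive the orientation
    reversal.  Reflection is an involution and an isometry.
    """
    s = (mesh.vertices - plane.point) @ plane.normal
    verts = mesh.vertices - 2.0 * s[:, None] * plane.normal
    return TriangleMesh(verts, mesh.faces[:, ::-1])


def reflect_points(points: np.ndarray, plane: OrientedPlane) -> np.ndarray:
    pts = np.asarray(points, dtype=np.float64)
    s = (pts - plane.point) @ plane.normal
    return pts - 2.0 * s[..., None] * plane.normal


# ---------------------------------------------------------------------------
# Exact point-to-surface distance
# ---------------------------------------------------------------------------

def _closest_point_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on triangle i to point i, for aligned arrays.

    Vectorised region-based projection (Ericson, Real-Time Collision
    Detection, §5.1.5): exact for every Voronoi region of the triangle.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def settle(mask, value):
        m = mask & ~done
        out[m] = value[m]
        done[m] = True

    settle((d1 <= 0) & (d2 <= 0), a)                       # vertex A
    settle((d3 >= 0) & (d4 <= d3), b)                      # vertex B
    settle((d6 >= 0) & (d5 <= d6), c)                      # vertex C

    vc = d1 * d4 - d3 * d2
    with np.errstate(invalid="ignore", divide="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)   # edge AB

    vb = d5 * d2 - d1 * d6
    with np.errstate(invalid="ignore", divide="ignore"):
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)   # edge AC

    va = d3 * d6 - d5 * d4
    denom_bc = (d4 - d3) + (d5 - d6)
    with np.errstate(invalid="ignore", divide="ignore"):
        w_bc = np.where(denom_bc != 0, (d4 - d3) / denom_bc, 0.0)
    settle((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + w_bc[:, None] * (c - b))

    # interior: barycentric projection onto the triangle plane
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom != 0, vb / denom, 1 / 3)
        w = np.where(denom != 0, vc / denom, 1 / 3)
    interior = a + v[:, None] * ab + w[:, None] * ac
    out[~done] = interior[~done]
    return out


class SurfaceDistanceQuery:
    """Exact nearest-point queries against a triangle mesh.

    A KD-tree over triangle centroids prunes candidates: the k nearest
    centroids give an upper bound, and every triangle that could beat it
    has its centroid within (bound + max triangle circumradius), so the
    final scan is exhaustive over a provably sufficient candidate set.
    """

    def __init__(self, mesh: TriangleMesh):
        self.mesh = mesh
        self._tri = mesh.triangles()
        self._centroids = self._tri.mean(axis=1)
        self._radius = np.linalg.norm(
            self._tri - self._centroids[:, None, :], axis=2
        ).max(axis=1)
        self._rmax = float(self._radius.max())
        self._tree = cKDTree(self._centroids)

    def query(self, points: np.ndarray):
        """Return (distances, closest_points) for an (n, 3) array."""
        points = np.ascontiguousarray(points, dtype=np.float64)
        n = len(points)
        m = len(self._tri)
        k = min(8, m)
        _, knn = self._tree.query(points, k=k)
        knn = np.atleast_2d(knn.reshape(n, k))
        cand_pts = _closest_point_on_triangles(
            np.repeat(points, k, axis=0), self._tri[knn.ravel()]
        ).reshape(n, k, 3)
        d2 = np.sum((cand_pts - points[:, None, :]) ** 2, axis=2)
        best = np.argmin(d2, axis=1)
        dist = np.sqrt(d2[np.arange(n), best])
        closest = cand_pts[np.arange(n), best]
        if k == m:
            return dist, closest
        # exhaustive pass over every triangle that could still be nearer
        radius = dist + self._rmax + 1e-9
        groups = self._tree.query_ball_point(points, radius)
        counts = np.fromiter((len(g) for g in groups), dtype=np.int64, count=n)
        need = counts > 0
        if need.any():
            flat_idx = np.concatenate([np.asarray(g) for g, m_ in zip(groups, need) if m_])
            flat_pts = np.repeat(points[need], counts[need], axis=0)
            cand = _closest_point_on_triangles(flat_pts, self._tri[flat_idx])
            cd = np.linalg.norm(cand - flat_pts, axis=1)
            offsets = np.concatenate([[0], np.cumsum(counts[need])])
            rows = np.flatnonzero(need)
            for j, row in enumerate(rows):
                seg = slice(offsets[j], offsets[j + 1])
                i_best = np.argmin(cd[seg])
                if cd[seg][i_best] < dist[row]:
                    dist[row] = cd[seg][i_best]
                    closest[row] = cand[seg][i_best]
        return dist, closest


def closest_points_on_mesh(points, target_mesh: TriangleMesh):
    """Exact closest points on ``target_mesh``; returns (distances, points)."""
    return SurfaceDistanceQuery(target_mesh).query(np.atleast_2d(points))


def point_to_surface_distance(points, target_mesh: TriangleMesh,
                              source_mesh: TriangleMesh | None = None) -> DistanceMap:
    """Exact minimum Euclidean distance from each point to the target surface.

    ``points`` may be an (n, 3) array or a :class:`TriangleMesh`, in which
    case its vertices are used and its barycentric vertex areas become the
    distance map's weights.  Otherwise weights come from ``source_mesh``
    (if given) or default to 1.
    """
    if isinstance(points, TriangleMesh):
        source_mesh = points
        pts = points.vertices
    else:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    dist, _ = SurfaceDistanceQuery(target_mesh).query(pts)
    if source_mesh is not None and len(source_mesh.vertices) == len(pts):
        weights = source_mesh.vertex_area_weights()
    else:
        weights = np.ones(len(pts))
    return DistanceMap(dist, weights, source_mesh)


# ---------------------------------------------------------------------------
# ICP
# ---------------------------------------------------------------------------

@dataclass
class ICPResult:
    """Composed rigid transform plus the per-iteration RMS log."""

    transform: RigidTransform
    rms_history: list = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False

    @property
    def final_rms(self) -> float:
        return self.rms_history[-1] if self.rms_history else float("nan")


def _kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping source points onto targets."""
    sc, tc = source.mean(axis=0), target.mean(axis=0)
    H = (source - sc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, tc - R @ sc)


def icp_register(moving: TriangleMesh, fixed: TriangleMesh,
                 init: RigidTransform | None = None,
                 max_iter: int = 100, tol: float = 1e-6) -> ICPResult:
    """Point-to-surface rigid ICP of ``moving`` onto ``fixed``.

    Each iteration finds the exact nearest point on the fixed surface for
    every moving vertex, then applies the closed-form least-squares rigid
    update (Kabsch/SVD).  The RMS point-to-surface distance is non-increasing
    by construction.  Stops when the RMS improves by less than ``tol`` (mm)
    or after ``max_iter`` iterations (warning; best transform returned).
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    transform = init if init is not None else RigidTransform.identity()
    query = SurfaceDistanceQuery(fixed)
    current = transform.apply(moving.vertices)
    result = ICPResult(transform)
    prev_rms = None
    for _ in range(max_iter):
        dist, closest = query.query(current)
        rms = float(np.sqrt(np.mean(dist ** 2)))
        result.rms_history.append(rms)
        result.n_iterations += 1
        if prev_rms is not None and prev_rms - rms < tol:
            result.converged = True
            break
        prev_rms = rms
        update = _kabsch(current, closest)
        transform = update.compose(transform)
        current = update.apply(current)
        result.transform = transform
    if not result.converged:
        warnings.warn(
            f"ICP did not converge within {max_iter} iterations "
            f"(last RMS {result.rms_history[-1]:.6f} mm); best transform returned",
            stacklevel=2,
        )
    return result


# ---------------------------------------------------------------------------
# The headline composition
# ---------------------------------------------------------------------------

@dataclass
class MirrorMatchResult:
    distance_map: DistanceMap
    mirror_plane: OrientedPlane
    icp: ICPResult
    mirrored_shell: TriangleMesh


def mirror_and_match(mesh: TriangleMesh, landmarks: LandmarkSet,
                     icp_options: dict | None = None,
                     return_details: bool = False):
    """Fit the mirror plane, reflect, register, and map distances.

    The reflection through the landmark-fitted midsagittal plane already
    brings the shell into approximate alignment, so ICP starts from the
    identity.  Distances run from the *original* vertices to the registered
    mirrored shell (unsigned, as an absolute deviation map).
    """
    opts = dict(max_iter=100, tol=1e-6)
    if icp_options:
        opts.update(icp_options)
    plane = fit_mirror_plane(landmarks)
    mirrored = reflect(mesh, plane)
    icp = icp_register(mirrored, mesh, **opts)
    registered = TriangleMesh(icp.transform.apply(mirrored.vertices), mirrored.faces)
    dmap = point_to_surface_distance(mesh, registered)
    if return_details:
        return MirrorMatchResult(dmap, plane, icp, registered)
    return dmap
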