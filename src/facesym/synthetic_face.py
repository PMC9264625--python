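"""Parametric synthetic faces with known, controllable asymmetry.

The stand-in for real facial scans: a smooth height field z = f(x, y) over
an elliptical domain, built from an ellipsoidal dome plus mirror-symmetric
Gaussian feature bumps (two brows, nose ridge, nose tip, two lip rolls, a
chin boss).  By construction f(-x, y) = f(x, y), so the base face is
*exactly* symmetric under x -> -x and every landmark position is analytic.
Asymmetry of known magnitude and extent is then injected as a one-sided
Gaussian displacement, giving per-vertex ground truth against which the
1 mm symmetric/asymmetric rule can be audited.

Coordinate frame: x = subject's anatomical left (+) / right (-),
y = superior (+), z = anterior (+); units mm.

Ground truth beats realism here: these surfaces have no texture, no
expression, no scanning noise, and landmarks are exact — so a green test
establishes the geometry and the scoring rule, not robustness to real
scanner artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .face_regions import REGION_IDS, assign_regions, build_planes
from .mesh_core import LandmarkSet, RaterPanel, TriangleMesh
from .mirror_align import fit_mirror_plane

__all__ = [
    "FaceParams",
    "AsymmetrySpec",
    "RaterSimConfig",
    "CohortSubject",
    "Cohort",
    "generate_face",
    "inject_asymmetry",
    "simulate_rater_panel",
    "generate_cohort",
]


@dataclass(frozen=True)
class FaceParams:
    """Geometry of the synthetic face.

    ``resolution`` is the number of grid vertices per axis (>= 20); the
    default 49 keeps the full pipeline around a second per subject while an
    odd count places a vertex column exactly on the midline.  Scales and
    amplitudes are in mm, defaults chosen at adult-face magnitudes.
    """

    resolution: int = 49
    width: float = 140.0
    height: float = 180.0
    depth: float = 45.0
    brow_amp: float = 3.0
    nose_ridge_amp: float = 5.0
    nose_tip_amp: float = 9.0
    lip_amp: float = 3.0
    chin_amp: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.resolution < 20:
            raise ValueError("resolution must be >= 20")
        for name in ("width", "height", "depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class AsymmetrySpec:
    """A one-sided Gaussian displacement of known peak and extent.

    ``delta`` (mm) is the peak displacement — the controlled variable
    relative to the 1 mm symmetry threshold.  ``sigma`` (mm) is the spatial
    extent.  ``region`` is one of the seven region names or "global";
    ``direction`` is "normal" (along vertex normals) or "z" (anterior).
    """

    region: str = "chin"
    side: str = "left"
    delta: float = 3.0
    sigma: float = 10.0
    direction: str = "normal"

    def __post_init__(self):
        if self.region != "global" and self.region not in REGION_IDS:
            raise ValueError(
                f"unknown region {self.region!r}; expected one of "
                f"{sorted(REGION_IDS)} or 'global'"
            )
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.direction not in ("normal", "z"):
            raise ValueError("direction must be 'normal' or 'z'")


@dataclass(frozen=True)
class RaterSimConfig:
    """An i.i.d. rater panel: each rating equals truth with probability p."""

    n_raters: int = 10
    accuracy: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.n_raters < 1:
            raise ValueError("need at least one rater")
        if not 0.5 < self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in (0.5, 1]")


# ---------------------------------------------------------------------------
# Base face
# ---------------------------------------------------------------------------

def _gauss(x, y, cx, cy, sx, sy):
    return np.exp(-((x - cx) ** 2 / (2 * sx ** 2) + (y - cy) ** 2 / (2 * sy ** 2)))


# Feature layout at the reference scale (half-width a0 = 70, half-height
# b0 = 90 mm).  Positions scale with the face; spreads scale likewise.
_REF_A, _REF_B = 70.0, 90.0


def _height_field(params: FaceParams):
    """Return f(x, y) plus the landmark (x, y) anchor positions (scaled mm)."""
    a, b = params.width / 2.0, params.height / 2.0
    sx, sy = a / _REF_A, b / _REF_B

    # Ch sits exactly below En (the facial-fifths canon: the mouth corner on
    # the vertical through the inner canthus) so the En->Ch "vertical" planes
    # P6/P7 come out parasagittal.
    brow_y = 30.0 * sy
    anchors = {
        "Tr": (0.0, 76.0 * sy),
        "N": (0.0, brow_y),
        "En_L": (16.0 * sx, brow_y), "En_R": (-16.0 * sx, brow_y),
        "Ex_L": (34.0 * sx, brow_y), "Ex_R": (-34.0 * sx, brow_y),
        "Sn": (0.0, -14.0 * sy),
        "Ch_L": (16.0 * sx, -33.0 * sy), "Ch_R": (-16.0 * sx, -33.0 * sy),
        "Li": (0.0, -45.0 * sy),
    }

    def f(x, y):
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        r2 = (x / a) ** 2 + (y / b) ** 2
        z = params.depth * np.sqrt(np.clip(1.0 - r2, 0.0, None))
        for s in (+1.0, -1.0):  # brows, mirror pair spanning En..Ex
            z += params.brow_amp * _gauss(x, y, s * 25.0 * sx, brow_y, 9.0 * sx, 5.0 * sy)
        z += params.nose_ridge_amp * _gauss(x, y, 0.0, 12.0 * sy, 6.0 * sx, 18.0 * sy)
        z += params.nose_tip_amp * _gauss(x, y, 0.0, -5.0 * sy, 7.0 * sx, 7.0 * sy)
        z += params.lip_amp * _gauss(x, y, 0.0, -28.0 * sy, 14.0 * sx, 5.0 * sy)
        z += params.lip_amp * _gauss(x, y, 0.0, -38.0 * sy, 14.0 * sx, 5.0 * sy)
        z += params.chin_amp * _gauss(x, y, 0.0, -62.0 * sy, 12.0 * sx, 12.0 * sy)
        return z

    return f, anchors


def generate_face(params: FaceParams | None = None):
    """Generate the base (exactly symmetric) face mesh and its landmarks.

    Returns ``(mesh, landmarks)``.  The mesh is the height field sampled on
    a symmetric grid restricted to the elliptical facial outline; landmarks
    are evaluated analytically on f, so they lie on the mesh surface to
    within the piecewise-linear interpolation error (well under half an
    edge length for the default resolution).
    """
    params = params or FaceParams()
    a, b = params.width / 2.0, params.height / 2.0
    f, anchors = _height_field(params)

    u = np.linspace(-1.0, 1.0, params.resolution)
    gx, gy = np.meshgrid(u * a, u * b, indexing="ij")
    inside = (gx / a) ** 2 + (gy / b) ** 2 <= 0.995

    index = np.full(inside.shape, -1, dtype=np.int64)
    index[inside] = np.arange(int(inside.sum()))
    verts = np.column_stack([gx[inside], gy[inside], f(gx[inside], gy[inside])])

    faces = []
    n = params.resolution
    for i in range(n - 1):
        for j in range(n - 1):
            q = (index[i, j], index[i + 1, j], index[i + 1, j + 1], index[i, j + 1])
            if q[0] >= 0 and q[1] >= 0 and q[2] >= 0:
                faces.append((q[0], q[1], q[2]))
            if q[0] >= 0 and q[2] >= 0 and q[3] >= 0:
                faces.append((q[0], q[2], q[3]))
    mesh = TriangleMesh(verts, np.asarray(faces, dtype=np.int64))

    landmarks = LandmarkSet({
        name: (x, y, float(f(x, y))) for name, (x, y) in anchors.items()
    })
    return mesh, landmarks


# ---------------------------------------------------------------------------
# Asymmetry injection
# ---------------------------------------------------------------------------

def inject_asymmetry(mesh: TriangleMesh, landmarks: LandmarkSet,
                     spec: AsymmetrySpec):
    """Apply a one-sided Gaussian displacement field to one region.

    The displacement ``d(v) = delta * exp(-||v - c||^2 / (2 sigma^2))`` acts
    only on vertices on the chosen anatomical side of the mirror plane; the
    centre ``c`` is the on-side region vertex nearest the region centroid
    (snapped to a vertex so the peak displacement equals ``delta`` exactly).

    Returns ``(new_mesh, displacement)`` where ``displacement`` is the
    per-vertex ground-truth displacement magnitude (mm).
    """
    p1 = fit_mirror_plane(landmarks)
    side_sign = 1.0 if spec.side == "left" else -1.0
    on_side = p1.signed_distance(mesh.vertices) * side_sign > 0

    if spec.region == "global":
        region_mask = np.ones(mesh.n_vertices, dtype=bool)
    else:
        planes = build_planes(landmarks)
        labels = assign_regions(mesh, planes).labels
        region_mask = labels == REGION_IDS[spec.region]

    candidates = region_mask & on_side
    if not candidates.any():
        raise ValueError(
            f"no vertices in region {spec.region!r} on the {spec.side} side"
        )
    centroid = mesh.vertices[candidates].mean(axis=0)
    cand_idx = np.flatnonzero(candidates)
    center = mesh.vertices[cand_idx[np.argmin(
        np.linalg.norm(mesh.vertices[cand_idx] - centroid, axis=1))]]

    displacement = np.zeros(mesh.n_vertices)
    r2 = np.sum((mesh.vertices[on_side] - center) ** 2, axis=1)
    displacement[on_side] = spec.delta * np.exp(-r2 / (2.0 * spec.sigma ** 2))

    if spec.direction == "normal":
        direction = mesh.vertex_normals()
    else:
        direction = np.tile([0.0, 0.0, 1.0], (mesh.n_vertices, 1))
    new_vertices = mesh.vertices + displacement[:, None] * direction
    return TriangleMesh(new_vertices, mesh.faces.copy()), displacement


# ---------------------------------------------------------------------------
# Rater simulation
# ---------------------------------------------------------------------------

def simulate_rater_panel(true_labels, config: RaterSimConfig,
                         subjects=None) -> RaterPanel:
    """Simulate a complete binary rater panel.

    Each rating independently equals the true label (1 = symmetric) with
    probability ``config.accuracy``; otherwise it is flipped.  Seeded and
    bit-reproducible.
    """
    truth = np.asarray(true_labels, dtype=np.int64).reshape(-1)
    if truth.size == 0:
        raise ValueError("true_labels must be non-empty")
    if not np.isin(truth, (0, 1)).all():
        raise ValueError("true_labels must be 0/1")
    rng = np.random.default_rng(config.seed)
    correct = rng.random((truth.size, config.n_raters)) < config.accuracy
    ratings = np.where(correct, truth[:, None], 1 - truth[:, None])
    if subjects is None:
        subjects = [f"S{i:04d}" for i in range(truth.size)]
    raters = [f"R{j:02d}" for j in range(config.n_raters)]
    return RaterPanel(subjects=subjects, raters=raters, ratings=ratings)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Regions the asymmetric subjects draw their deformation from — the lower
#: face, where clinically relevant asymmetry concentrates.
ASYMMETRY_REGIONS = ("lip", "chin", "cheek", "lateral_mandible")


@dataclass
class CohortSubject:
    subject_id: str
    mesh: TriangleMesh
    landmarks: LandmarkSet
    symmetric: bool
    injections: list = field(default_factory=list)
    displacement: np.ndarray | None = None


@dataclass
class Cohort:
    subjects: list

    @property
    def true_labels(self) -> np.ndarray:
        return np.array([int(s.symmetric) for s in self.subjects])

    @property
    def subject_ids(self) -> list:
        return [s.subject_id for s in self.subjects]

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)


def generate_cohort(n_subjects: int, symmetric_fraction: float = 0.8,
                    delta_symmetric: tuple = (0.0, 0.8),
                    delta_asymmetric: tuple = (1.5, 5.0),
                    sigma_range: tuple = (8.0, 15.0),
                    base_params: FaceParams | None = None,
                    seed: int = 0) -> Cohort:
    """Generate a seeded cohort with known symmetric/asymmetric ground truth.

    Exactly ``round(n_subjects * symmetric_fraction)`` subjects are labeled
    symmetric; they receive a sub-threshold injection with peak delta drawn
    from ``delta_symmetric`` (below 1 mm).  Asymmetric subjects receive one
    or two supra-threshold injections (delta from ``delta_asymmetric``,
    above 1 mm) in lower-face regions.  Face proportions vary mildly
    (+-5%) between subjects.
    """
    if not 0.0 <= symmetric_fraction <= 1.0:
        raise ValueError("symmetric_fraction must lie in [0, 1]")
    if delta_symmetric[1] >= 1.0:
        raise ValueError("delta_symmetric upper bound must stay below the 1 mm threshold")
    if delta_asymmetric[0] <= 1.0:
        raise ValueError("delta_asymmetric lower bound must exceed the 1 mm threshold")
    base = base_params or FaceParams()
    rng = np.random.default_rng(seed)
    n_sym = int(round(n_subjects * symmetric_fraction))
    labels = np.array([True] * n_sym + [False] * (n_subjects - n_sym))
    rng.shuffle(labels)

    subjects = []
    for i in range(n_subjects):
        params = replace(
            base,
            width=base.width * rng.uniform(0.95, 1.05),
            height=base.height * rng.uniform(0.95, 1.05),
            depth=base.depth * rng.uniform(0.95, 1.05),
            chin_amp=base.chin_amp * rng.uniform(0.9, 1.1),
            nose_tip_amp=base.nose_tip_amp * rng.uniform(0.9, 1.1),
        )
        mesh, landmarks = generate_face(params)
        symmetric = bool(labels[i])
        if symmetric:
            lo, hi = delta_symmetric
            n_inj, lo_hi = 1, (lo, hi)
        else:
            lo, hi = delta_asymmetric
            n_inj, lo_hi = int(rng.integers(1, 3)), (lo, hi)
        total_disp = np.zeros(mesh.n_vertices)
        specs = []
        regions = rng.choice(len(ASYMMETRY_REGIONS), size=n_inj, replace=False)
        for r in regions:
            spec = AsymmetrySpec(
                region=ASYMMETRY_REGIONS[r],
                side="left" if rng.random() < 0.5 else "right",
                delta=float(rng.uniform(*lo_hi)),
                sigma=float(rng.uniform(*sigma_range)),
            )
            if spec.delta > 0:
                mesh, disp = inject_asymmetry(mesh, landmarks, spec)
                total_disp += disp
            specs.append(spec)
        subjects.append(CohortSubject(
            subject_id=f"S{i:04d}", mesh=mesh, landmarks=landmarks,
            symmetric=symmetric, injections=specs, displacement=total_disp,
        ))
    return Cohort(subjects)
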