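"""Landmark-derived reference planes and the 7-region facial partition.

Planes (all anchored on the soft-tissue landmarks):

* P1 — mirror symmetry plane through Tr, N, Sn, Li (midsagittal).
* P2 — transversal plane through the four eye commissures (En, Ex, both
  sides), oriented so its positive side is superior (toward Tr).
* P3/P4/P5 — parallels of P2 through Sn, Ch_L and Li respectively.
* P6/P7 — "vertical" planes through En and Ch on each side, constrained
  perpendicular to P2 (two points under-determine a plane; the
  perpendicularity constraint matches their vertical role), oriented away
  from the midline.

Region labels (vertex-wise, from the signed coordinates s2..s7):

====  =================  =============================================
  1   central_forehead   above P2, medial to both verticals
  2   nose               between P2 and P3, medial
  3   lip                between P3 and P5, medial
  4   chin               below P5, medial
  5   lateral_forehead   above P2, lateral
  6   cheek              between P2 and P4, lateral
  7   lateral_mandible   below P4, lateral
====  =================  =============================================

Ties (a vertex exactly on a plane) go to the inferior/lateral region via
strict ``>``; exactly on a vertical plane counts as medial.  The bounding
assignments are the single largest interpretive choice in this package and
are override-able via ``rule_fn``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh_core import LandmarkSet, OrientedPlane, TriangleMesh
from .mirror_align import fit_mirror_plane

__all__ = [
    "REGION_NAMES",
    "REGION_IDS",
    "PlaneSet",
    "RegionLabeling",
    "build_planes",
    "assign_regions",
]

REGION_NAMES = {
    1: "central_forehead",
    2: "nose",
    3: "lip",
    4: "chin",
    5: "lateral_forehead",
    6: "cheek",
    7: "lateral_mandible",
}
REGION_IDS = {name: rid for rid, name in REGION_NAMES.items()}

PLANE_NAMES = ("P1", "P2", "P3", "P4", "P5", "P6", "P7")


@dataclass(frozen=True)
class PlaneSet:
    """The seven construction planes, keyed P1..P7."""

    planes: dict

    def __post_init__(self):
        missing = [n for n in PLANE_NAMES if n not in self.planes]
        if missing:
            raise ValueError(f"PlaneSet missing plane(s): {missing}")
        n2 = self.planes["P2"].normal
        for name in ("P3", "P4", "P5"):
            if np.linalg.norm(np.cross(self.planes[name].normal, n2)) > 1e-9:
                raise ValueError(f"{name} normal must be parallel to P2's")
        for name in ("P6", "P7"):
            if abs(self.planes[name].normal @ n2) > 1e-9:
                raise ValueError(f"{name} normal must be perpendicular to P2's")

    def __getitem__(self, name: str) -> OrientedPlane:
        return self.planes[name]


@dataclass
class RegionLabeling:
    """Per-vertex region label in 1..7 (every vertex labeled exactly once)."""

    labels: np.ndarray

    def __post_init__(self):
        lab = np.asarray(self.labels, dtype=np.int64).reshape(-1)
        if lab.size and not np.isin(lab, list(REGION_NAMES)).all():
            raise ValueError("labels must lie in 1..7")
        self.labels = lab

    def counts(self) -> dict:
        return {rid: int(np.sum(self.labels == rid)) for rid in REGION_NAMES}

    def region_areas(self, mesh: TriangleMesh) -> dict:
        """Area per region via barycentric vertex weights (sums to mesh area)."""
        w = mesh.vertex_area_weights()
        return {rid: float(w[self.labels == rid].sum()) for rid in REGION_NAMES}


def _tls_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = points.mean(axis=0)
    _, svals, Vt = np.linalg.svd(points - centroid)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        raise ValueError("degenerate configuration: plane points are collinear")
    return centroid, Vt[2]


def build_planes(landmarks: LandmarkSet) -> PlaneSet:
    """Construct P1..P7 from a full landmark set.

    P2 is the total-least-squares plane through En_L, En_R, Ex_L, Ex_R with
    its normal pointing toward Tr (superior).  P6/P7 normals are
    n2 x (Ch - En) on each side, flipped if needed so the midline (nasion)
    lies on their negative side.
    """
    p1 = fit_mirror_plane(landmarks)

    eye_pts = np.stack([landmarks[n] for n in ("En_L", "En_R", "Ex_L", "Ex_R")])
    centroid, n2 = _tls_plane(eye_pts)
    if n2 @ (landmarks["Tr"] - centroid) < 0:
        n2 = -n2
    p2 = OrientedPlane(centroid, n2)
    p3 = OrientedPlane(landmarks["Sn"], n2)
    p4 = OrientedPlane(landmarks["Ch_L"], n2)
    p5 = OrientedPlane(landmarks["Li"], n2)

    midline_ref = landmarks["N"]
    verticals = {}
    for name, en, ch in (("P6", "En_L", "Ch_L"), ("P7", "En_R", "Ch_R")):
        seg = landmarks[ch] - landmarks[en]
        normal = np.cross(n2, seg)
        if np.linalg.norm(normal) < 1e-9 * max(np.linalg.norm(seg), 1.0):
            raise ValueError(
                f"degenerate configuration for {name}: {en}->{ch} segment is "
                "parallel to P2's normal (or the points coincide)"
            )
        plane = OrientedPlane(landmarks[en], normal)
        if plane.signed_distance(midline_ref) > 0:
            plane = plane.flipped()
        verticals[name] = plane

    return PlaneSet({"P1": p1, "P2": p2, "P3": p3, "P4": p4, "P5": p5,
                     "P6": verticals["P6"], "P7": verticals["P7"]})


def _default_rules(s2, s3, s4, s5, medial) -> np.ndarray:
    # decision tree, top-down: exhaustive and mutually exclusive
    medial_label = np.select([s2 > 0, s3 > 0, s5 > 0], [1, 2, 3], default=4)
    lateral_label = np.select([s2 > 0, s4 > 0], [5, 6], default=7)
    return np.where(medial, medial_label, lateral_label)


def assign_regions(mesh: TriangleMesh, planes: PlaneSet,
                   rule_fn=None) -> RegionLabeling:
    """Label every vertex with its region (1..7).

    The default rule table is exhaustive and exclusive; pass ``rule_fn`` with
    signature ``(s2, s3, s4, s5, medial) -> labels`` to override the
    boundary assignments.
    """
    v = mesh.vertices
    s2 = planes["P2"].signed_distance(v)
    s3 = planes["P3"].signed_distance(v)
    s4 = planes["P4"].signed_distance(v)
    s5 = planes["P5"].signed_distance(v)
    s6 = planes["P6"].signed_distance(v)
    s7 = planes["P7"].signed_distance(v)
    medial = (s6 <= 0) & (s7 <= 0)
    rules = rule_fn if rule_fn is not None else _default_rules
    return RegionLabeling(rules(s2, s3, s4, s5, medial))
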