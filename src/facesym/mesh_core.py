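"""Domain types and file I/O for triangle meshes, landmarks and rater panels.

All coordinates are in millimetres; the 1 mm symmetry threshold downstream
makes the unit semantic, so no unit metadata is read from files.  Left/right
suffixes (``_L``/``_R``) always refer to the subject's anatomical side, never
to image axes.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LANDMARK_NAMES",
    "MIDLINE_LANDMARKS",
    "TriangleMesh",
    "LandmarkSet",
    "OrientedPlane",
    "RaterPanel",
    "MeshFormatError",
    "LandmarkValidationError",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "crop_by_plane",
]

#: Canonical soft-tissue landmark names.  Tr = trichion, N = soft-tissue
#: nasion, Sn = subnasale, Li = labiale inferius, En/Ex = inner/outer eye
#: commissures, Ch = cheilion (mouth corner).
LANDMARK_NAMES = ("Tr", "N", "Sn", "Li", "En_L", "En_R", "Ex_L", "Ex_R", "Ch_L", "Ch_R")

#: The four midline landmarks through which the mirror symmetry plane passes.
MIDLINE_LANDMARKS = ("Tr", "N", "Sn", "Li")

_DEGENERATE_AREA = 1e-12  # mm^2; faces below this are dropped on construction


class MeshFormatError(ValueError):
    """Raised for unreadable or malformed mesh files."""


class LandmarkValidationError(ValueError):
    """Raised when a landmark file or set fails validation."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class TriangleMesh:
    """A triangulated surface: vertices (mm) and vertex-index triples.

    Zero-area (degenerate) faces are removed on construction; face indices
    are validated to be in range.

    Parameters
    ----------
    vertices : (n, 3) array_like
        Vertex coordinates in millimetres, n >= 3.
    faces : (m, 3) array_like of int
        Vertex indices of each triangle.
    """

    def __init__(self, vertices, faces):
        vertices = np.ascontiguousarray(vertices, dtype=np.float64)
        faces = np.ascontiguousarray(faces, dtype=np.int64)
        if vertices.ndim != 2 or vertices.shape[1] != 3 or vertices.shape[0] < 3:
            raise MeshFormatError(
                f"vertices must be an (n>=3, 3) array, got shape {vertices.shape}"
            )
        if not np.isfinite(vertices).all():
            raise MeshFormatError("vertices contain non-finite coordinates")
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise MeshFormatError(
                f"faces must be an (m, 3) index array, got shape {faces.shape}"
            )
        if faces.shape[0] == 0:
            raise MeshFormatError("empty mesh: no faces")
        if faces.min() < 0 or faces.max() >= len(vertices):
            raise MeshFormatError("face index out of range")
        self.vertices = vertices
        # drop degenerate faces (zero area, incl. repeated indices)
        areas = _triangle_areas(vertices[faces])
        self.faces = faces[areas > _DEGENERATE_AREA]
        if len(self.faces) == 0:
            raise MeshFormatError("empty mesh: all faces degenerate")

    # -- basic queries ------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """Return the (m, 3, 3) array of triangle corner coordinates."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        return _triangle_areas(self.triangles())

    def area(self) -> float:
        return float(self.face_areas().sum())

    def vertex_area_weights(self) -> np.ndarray:
        """Per-vertex area weight: one third of the incident face areas (mm^2).

        This is the barycentric area share used both for distance-map
        weighting and for area-weighted symmetry percentages.
        """
        w = np.zeros(self.n_vertices)
        share = np.repeat(self.face_areas() / 3.0, 3)
        np.add.at(w, self.faces.ravel(), share)
        return w

    def face_normals(self) -> np.ndarray:
        tri = self.triangles()
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        return n / np.maximum(norm, 1e-300)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident face normals, unit length."""
        tri = self.triangles()
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])  # 2*area weighted
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], n)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        return vn / np.maximum(norm, 1e-300)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"TriangleMesh({self.n_vertices} vertices, {self.n_faces} faces)"


def _triangle_areas(tri: np.ndarray) -> np.ndarray:
    return 0.5 * np.linalg.norm(
        np.cross(tri[..., 1, :] - tri[..., 0, :], tri[..., 2, :] - tri[..., 0, :]),
        axis=-1,
    )


class LandmarkSet:
    """The ten named soft-tissue points anchoring every plane construction.

    Validation requires: exactly the canonical names present, finite
    coordinates, distinct left/right pairs, and the four midline points
    (Tr, N, Sn, Li) not collinear (otherwise the mirror plane is degenerate).
    """

    def __init__(self, points: dict):
        missing = [n for n in LANDMARK_NAMES if n not in points]
        if missing:
            raise LandmarkValidationError(f"missing landmark(s): {', '.join(missing)}")
        pts = {}
        for name in LANDMARK_NAMES:
            p = np.asarray(points[name], dtype=np.float64).reshape(-1)
            if p.shape != (3,) or not np.isfinite(p).all():
                raise LandmarkValidationError(
                    f"landmark {name} must be a finite 3-vector, got {points[name]!r}"
                )
            pts[name] = p
        for base in ("En", "Ex", "Ch"):
            if np.allclose(pts[f"{base}_L"], pts[f"{base}_R"]):
                raise LandmarkValidationError(
                    f"left/right pair {base}_L/{base}_R must be distinct points"
                )
        mid = np.stack([pts[n] for n in MIDLINE_LANDMARKS])
        centered = mid - mid.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
            raise LandmarkValidationError("midline landmarks Tr, N, Sn, Li are collinear")
        self._points = pts

    def __getitem__(self, name: str) -> np.ndarray:
        return self._points[name]

    def __contains__(self, name: str) -> bool:
        return name in self._points

    def names(self):
        return LANDMARK_NAMES

    def midline_points(self) -> np.ndarray:
        """(4, 3) array of Tr, N, Sn, Li in that order."""
        return np.stack([self._points[n] for n in MIDLINE_LANDMARKS])

    def as_dict(self) -> dict:
        return {n: self._points[n].tolist() for n in LANDMARK_NAMES}

    def transformed(self, fn) -> "LandmarkSet":
        """Apply ``fn`` (points (k,3) -> (k,3)) to every landmark."""
        stacked = np.stack([self._points[n] for n in LANDMARK_NAMES])
        moved = np.asarray(fn(stacked))
        return LandmarkSet({n: moved[i] for i, n in enumerate(LANDMARK_NAMES)})


@dataclass(frozen=True)
class OrientedPlane:
    """A plane given by a point on it and a unit normal.

    The constructor normalises ``normal``; a near-zero vector is rejected.
    """

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.point, dtype=np.float64).reshape(3)
        n = np.asarray(self.normal, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise ValueError("plane normal must be non-zero")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n / norm)

    def signed_distance(self, points) -> np.ndarray:
        """Signed distance(s) along the normal; positive on the normal side."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        d = (pts - self.point) @ self.normal
        return d if np.asarray(points).ndim > 1 else float(d[0])

    def flipped(self) -> "OrientedPlane":
        return OrientedPlane(self.point, -self.normal)


@dataclass
class RaterPanel:
    """Complete binary ratings: rows are subjects, columns raters.

    1 codes "symmetric", 0 codes "asymmetric"; missing entries are disallowed.
    """

    subjects: list = field(default_factory=list)
    raters: list = field(default_factory=list)
    ratings: np.ndarray = None

    def __post_init__(self):
        r = np.asarray(self.ratings)
        if r.ndim != 2 or r.shape != (len(self.subjects), len(self.raters)):
            raise ValueError(
                "ratings must be (n_subjects, n_raters); got shape "
                f"{r.shape} for {len(self.subjects)} subjects x {len(self.raters)} raters"
            )
        if not np.isin(r, (0, 1)).all():
            raise ValueError("ratings must contain only 0 (asymmetric) or 1 (symmetric)")
        self.subjects = list(self.subjects)
        self.raters = list(self.raters)
        self.ratings = r.astype(np.int64)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_raters(self) -> int:
        return len(self.raters)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ratings, index=pd.Index(self.subjects, name="subject"),
                            columns=self.raters)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "RaterPanel":
        df = pd.read_csv(path, index_col=0)
        if df.isna().any().any():
            raise ValueError(f"rater panel {path} has missing entries")
        return cls(subjects=[str(s) for s in df.index],
                   raters=[str(c) for c in df.columns],
                   ratings=df.to_numpy())


# ---------------------------------------------------------------------------
# Mesh file I/O: PLY (ascii + binary little-endian), OBJ, STL
# ---------------------------------------------------------------------------

_FORMATS = ("ply", "obj", "stl")


def _infer_format(path, fmt):
    if fmt is not None:
        fmt = fmt.lower().lstrip(".")
    else:
        fmt = Path(path).suffix.lower().lstrip(".")
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}; expected one of {_FORMATS}")
    return fmt


def read_mesh(path, format: str | None = None) -> TriangleMesh:
    """Read a triangle mesh from PLY, OBJ or STL (format inferred from suffix).

    Raises :class:`MeshFormatError` for unreadable files, non-triangular
    faces, or empty meshes, naming the offense.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"mesh file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "ply":
        verts, faces, _ = _read_ply(path)
    elif fmt == "obj":
        verts, faces = _read_obj(path)
    else:
        verts, faces = _read_stl(path)
    return TriangleMesh(verts, faces)


def read_mesh_with_colors(path):
    """Read a PLY mesh plus its per-vertex RGB colors (or None)."""
    verts, faces, colors = _read_ply(Path(path))
    return TriangleMesh(verts, faces), colors


def write_mesh(mesh: TriangleMesh, path, format: str | None = None,
               vertex_colors=None, binary: bool = True) -> None:
    """Write a mesh to PLY (ascii or binary LE), OBJ, or binary STL.

    ``vertex_colors`` (one uchar RGB triple per vertex) are supported for PLY
    only; requesting them for OBJ/STL is an explicit error.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if vertex_colors is not None:
        vertex_colors = np.asarray(vertex_colors)
        if fmt != "ply":
            raise MeshFormatError(
                f"vertex colors are supported for PLY only, not {fmt.upper()} "
                "(the format carries no per-vertex color)"
            )
        if vertex_colors.shape != (mesh.n_vertices, 3):
            raise MeshFormatError("vertex_colors must be one RGB triple per vertex")
    if fmt == "ply":
        _write_ply(mesh, path, vertex_colors, binary)
    elif fmt == "obj":
        _write_obj(mesh, path)
    else:
        _write_stl(mesh, path)


# -- PLY --------------------------------------------------------------------

_PLY_DTYPES = {
    "float": ("<f4", 4), "float32": ("<f4", 4),
    "double": ("<f8", 8), "float64": ("<f8", 8),
    "uchar": ("<u1", 1), "uint8": ("<u1", 1),
    "char": ("<i1", 1), "int8": ("<i1", 1),
    "short": ("<i2", 2), "int16": ("<i2", 2),
    "ushort": ("<u2", 2), "uint16": ("<u2", 2),
    "int": ("<i4", 4), "int32": ("<i4", 4),
    "uint": ("<u4", 4), "uint32": ("<u4", 4),
}


def _read_ply(path: Path):
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise MeshFormatError(f"{path}: not a PLY file (missing 'ply' magic)")
        fmt = None
        elements = []  # (name, count, [(prop_name, type) or ('list', idx_t, val_t, name)])
        while True:
            line = fh.readline()
            if not line:
                raise MeshFormatError(f"{path}: unexpected end of PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
                if fmt not in ("ascii", "binary_little_endian"):
                    raise MeshFormatError(f"{path}: unsupported PLY format {fmt}")
            elif tokens[0] == "element":
                elements.append((tokens[1], int(tokens[2]), []))
            elif tokens[0] == "property":
                if tokens[1] == "list":
                    elements[-1][2].append(("list", tokens[2], tokens[3], tokens[4]))
                else:
                    elements[-1][2].append((tokens[2], tokens[1]))
            elif tokens[0] == "end_header":
                break
        data = {name: _read_ply_element(fh, fmt, count, props, path)
                for name, count, props in elements}
    if "vertex" not in data or "face" not in data:
        raise MeshFormatError(f"{path}: PLY missing vertex or face element")
    v = data["vertex"]
    try:
        verts = np.column_stack([v["x"], v["y"], v["z"]])
    except KeyError as exc:
        raise MeshFormatError(f"{path}: PLY vertex element missing {exc}") from None
    colors = None
    if all(c in v for c in ("red", "green", "blue")):
        colors = np.column_stack([v["red"], v["green"], v["blue"]]).astype(np.uint8)
    faces = data["face"].get("vertex_indices", data["face"].get("vertex_index"))
    if faces is None:
        raise MeshFormatError(f"{path}: PLY face element has no vertex index list")
    return verts, faces, colors


def _read_ply_element(fh, fmt, count, props, path):
    out = {}
    list_props = [p for p in props if p[0] == "list"]
    if fmt == "ascii":
        columns = {p[0] if p[0] != "list" else p[3]: [] for p in props}
        for _ in range(count):
            tokens = fh.readline().split()
            i = 0
            for p in props:
                if p[0] == "list":
                    n = int(tokens[i]); i += 1
                    vals = [float(t) for t in tokens[i:i + n]]; i += n
                    if p[3] in ("vertex_indices", "vertex_index") and n != 3:
                        raise MeshFormatError(f"{path}: non-triangular face (size {n})")
                    columns[p[3]].append(vals)
                else:
                    columns[p[0]].append(float(tokens[i])); i += 1
        for p in props:
            key = p[3] if p[0] == "list" else p[0]
            arr = np.asarray(columns[key])
            out[key] = arr.astype(np.int64) if p[0] == "list" else arr
        return out
    # binary little-endian
    if not list_props:
        dtype = np.dtype([(p[0], _PLY_DTYPES[p[1]][0]) for p in props])
        raw = np.frombuffer(fh.read(dtype.itemsize * count), dtype=dtype, count=count)
        for p in props:
            out[p[0]] = raw[p[0]].astype(np.float64)
        return out
    rows = {p[0] if p[0] != "list" else p[3]: [] for p in props}
    for _ in range(count):
        for p in props:
            if p[0] == "list":
                idx_dt, idx_sz = _PLY_DTYPES[p[1]]
                val_dt, val_sz = _PLY_DTYPES[p[2]]
                n = int(np.frombuffer(fh.read(idx_sz), dtype=idx_dt)[0])
                if p[3] in ("vertex_indices", "vertex_index") and n != 3:
                    raise MeshFormatError(f"{path}: non-triangular face (size {n})")
                vals = np.frombuffer(fh.read(val_sz * n), dtype=val_dt, count=n)
                rows[p[3]].append(vals.astype(np.int64))
            else:
                dt, sz = _PLY_DTYPES[p[1]]
                rows[p[0]].append(float(np.frombuffer(fh.read(sz), dtype=dt)[0]))
    for p in props:
        key = p[3] if p[0] == "list" else p[0]
        out[key] = np.asarray(rows[key])
    return out


def _write_ply(mesh, path, colors, binary):
    n, m = mesh.n_vertices, mesh.n_faces
    header = ["ply",
              "format binary_little_endian 1.0" if binary else "format ascii 1.0",
              f"element vertex {n}",
              "property double x", "property double y", "property double z"]
    if colors is not None:
        header += ["property uchar red", "property uchar green", "property uchar blue"]
    header += [f"element face {m}", "property list uchar int vertex_indices", "end_header"]
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            if colors is None:
                fh.write(np.ascontiguousarray(mesh.vertices, dtype="<f8").tobytes())
            else:
                vdt = np.dtype([("x", "<f8"), ("y", "<f8"), ("z", "<f8"),
                                ("r", "<u1"), ("g", "<u1"), ("b", "<u1")])
                rec = np.empty(n, dtype=vdt)
                rec["x"], rec["y"], rec["z"] = mesh.vertices.T
                rec["r"], rec["g"], rec["b"] = np.asarray(colors, dtype=np.uint8).T
                fh.write(rec.tobytes())
            fdt = np.dtype([("n", "<u1"), ("i", "<i4", (3,))])
            frec = np.empty(m, dtype=fdt)
            frec["n"] = 3
            frec["i"] = mesh.faces.astype("<i4")
            fh.write(frec.tobytes())
        else:
            lines = []
            for i in range(n):
                x, y, z = mesh.vertices[i]
                row = f"{x:.17g} {y:.17g} {z:.17g}"
                if colors is not None:
                    r, g, b = (int(c) for c in colors[i])
                    row += f" {r} {g} {b}"
                lines.append(row)
            for f in mesh.faces:
                lines.append(f"3 {f[0]} {f[1]} {f[2]}")
            fh.write(("\n".join(lines) + "\n").encode("ascii"))


# -- OBJ --------------------------------------------------------------------

def _read_obj(path: Path):
    verts, faces = [], []
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            if tokens[0] == "v":
                verts.append([float(t) for t in tokens[1:4]])
            elif tokens[0] == "f":
                idx = [int(t.split("/")[0]) for t in tokens[1:]]
                if len(idx) != 3:
                    raise MeshFormatError(
                        f"{path}:{lineno}: non-triangular face with {len(idx)} vertices"
                    )
                # OBJ indices are 1-based; negative indices count from the end
                faces.append([i - 1 if i > 0 else len(verts) + i for i in idx])
    if not verts or not faces:
        raise MeshFormatError(f"{path}: empty mesh (no vertices or faces)")
    return np.asarray(verts), np.asarray(faces)


def _write_obj(mesh, path):
    with open(path, "w", encoding="ascii") as fh:
        for x, y, z in mesh.vertices:
            fh.write(f"v {x:.17g} {y:.17g} {z:.17g}\n")
        for a, b, c in mesh.faces + 1:
            fh.write(f"f {a} {b} {c}\n")


# -- STL (binary; duplicated corners are merged on read) --------------------

def _read_stl(path: Path):
    raw = path.read_bytes()
    if len(raw) < 84:
        raise MeshFormatError(f"{path}: truncated STL file")
    if raw[:5] == b"solid" and not _looks_binary_stl(raw):
        raise MeshFormatError(f"{path}: ASCII STL not supported; use binary STL")
    (ntri,) = struct.unpack("<I", raw[80:84])
    expected = 84 + 50 * ntri
    if len(raw) < expected:
        raise MeshFormatError(f"{path}: STL triangle count inconsistent with file size")
    dt = np.dtype([("normal", "<f4", (3,)), ("v", "<f4", (3, 3)), ("attr", "<u2")])
    rec = np.frombuffer(raw[84:expected], dtype=dt, count=ntri)
    corners = rec["v"].reshape(-1, 3).astype(np.float64)
    verts, inverse = np.unique(corners, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    return verts, faces


def _looks_binary_stl(raw: bytes) -> bool:
    if len(raw) < 84:
        return False
    (ntri,) = struct.unpack("<I", raw[80:84])
    return len(raw) == 84 + 50 * ntri


def _write_stl(mesh, path):
    tri = mesh.triangles().astype("<f4")
    normals = mesh.face_normals().astype("<f4")
    dt = np.dtype([("normal", "<f4", (3,)), ("v", "<f4", (3, 3)), ("attr", "<u2")])
    rec = np.zeros(mesh.n_faces, dtype=dt)
    rec["normal"] = normals
    rec["v"] = tri
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 80)
        fh.write(struct.pack("<I", mesh.n_faces))
        fh.write(rec.tobytes())


# ---------------------------------------------------------------------------
# Landmark I/O
# ---------------------------------------------------------------------------

def read_landmarks(path) -> LandmarkSet:
    """Read a flat JSON file ``{name: [x, y, z]}`` in mm.

    Unknown extra names are ignored with a warning; missing canonical names
    or non-finite coordinates raise :class:`LandmarkValidationError`.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise LandmarkValidationError(f"cannot read landmark file {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise LandmarkValidationError(f"{path}: landmark JSON must be an object")
    extra = sorted(set(data) - set(LANDMARK_NAMES))
    if extra:
        warnings.warn(
            f"{path}: ignoring unknown landmark name(s): {', '.join(extra)}",
            stacklevel=2,
        )
    return LandmarkSet({k: v for k, v in data.items() if k in LANDMARK_NAMES})


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    Path(path).write_text(json.dumps(landmarks.as_dict(), indent=1) + "\n")


# ---------------------------------------------------------------------------
# Cropping
# ---------------------------------------------------------------------------

def crop_by_plane(mesh: TriangleMesh, plane: OrientedPlane,
                  keep_side: str = "positive") -> TriangleMesh:
    """Drop triangles lying entirely on the discarded side of ``plane``.

    Triangles crossing the plane (or touching it) are retained whole — no
    re-meshing — so the cut is conservative.  ``keep_side`` is "positive"
    (normal side) or "negative".  Raises ``ValueError`` if nothing remains.
    """
    if keep_side not in ("positive", "negative"):
        raise ValueError(f"keep_side must be 'positive' or 'negative', got {keep_side!r}")
    s = plane.signed_distance(mesh.vertices)
    if keep_side == "negative":
        s = -s
    discard = (s[mesh.faces] < 0).all(axis=1)  # strictly on the wrong side
    kept_faces = mesh.faces[~discard]
    if len(kept_faces) == 0:
        raise ValueError("crop_by_plane: no triangles remain on the kept side")
    used = np.unique(kept_faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(mesh.vertices[used], remap[kept_faces])
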