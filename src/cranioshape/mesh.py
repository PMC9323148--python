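"""Triangle-mesh and landmark primitives for head-scan shape analysis.

Coordinates are millimetres throughout.  Meshes are plain vertex/face
arrays (counterclockwise winding, outward normals); landmark sets are
named 3D points following a configurable cranial/facial schema.  The
module also builds the area-weighted mass matrix used by the weighted
PCA, mirrors scans across the midsagittal plane, and extracts cranial
submeshes.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
import trimesh

__all__ = [
    "SurfaceMesh",
    "LandmarkSet",
    "Scan",
    "MassMatrix",
    "MeshParseError",
    "DEFAULT_LANDMARK_SCHEMA",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "compute_mass_matrix",
    "stretch_mass_matrix",
    "fit_midsagittal_plane",
    "mirror_scan",
    "mirror_points",
    "symmetry_vertex_map",
    "extract_cranial_submesh",
]


class MeshParseError(ValueError):
    """Raised for unreadable mesh files or non-triangular faces."""


# Default 10-landmark schema: name -> laterality.  The schema is
# configurable; any mapping with the same structure may be passed to
# LandmarkSet in its place.
DEFAULT_LANDMARK_SCHEMA: dict[str, str] = {
    "nasion": "midline",
    "sellion": "midline",
    "opisthocranion": "midline",
    "vertex": "midline",
    "exocanthion_left": "left",
    "exocanthion_right": "right",
    "tragion_left": "left",
    "tragion_right": "right",
    "euryon_left": "left",
    "euryon_right": "right",
}


@dataclass
class SurfaceMesh:
    """A triangular surface mesh (one head scan or the template).

    Parameters
    ----------
    vertices : (p, 3) float array, mm
    faces : (t, 3) int array, CCW winding / outward normals
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (p, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshParseError("faces must be triangles (t, 3)")
        p = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= p):
            raise ValueError("face index out of range")
        # degenerate = repeated vertex index within a face
        f = self.faces
        if f.size and (
            (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        ).any():
            raise ValueError("degenerate face (repeated vertex index)")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as a sorted (e, 2) int array."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals (unit length)."""
        return np.asarray(self.as_trimesh().vertex_normals, dtype=float)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy())


@dataclass
class LandmarkSet:
    """Named anatomical 3D landmarks (mm) following a laterality schema."""

    points: dict[str, np.ndarray]
    schema: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_LANDMARK_SCHEMA))

    def __post_init__(self) -> None:
        self.points = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.points.items()}
        missing = set(self.schema) - set(self.points)
        extra = set(self.points) - set(self.schema)
        if missing or extra:
            raise ValueError(f"landmark names do not match schema: missing={sorted(missing)}, extra={sorted(extra)}")

    @property
    def names(self) -> list[str]:
        return list(self.schema)

    def array(self, names: list[str] | None = None) -> np.ndarray:
        names = self.names if names is None else names
        return np.array([self.points[n] for n in names])

    def midline_names(self) -> list[str]:
        return [n for n, lat in self.schema.items() if lat == "midline"]

    def swap_laterality(self) -> "LandmarkSet":
        """Return a copy with left/right landmark names exchanged."""
        out = {}
        for name, lat in self.schema.items():
            if lat == "left":
                out[name.replace("_left", "_right")] = self.points[name]
            elif lat == "right":
                out[name.replace("_right", "_left")] = self.points[name]
            else:
                out[name] = self.points[name]
        return LandmarkSet(out, dict(self.schema))

    def transform(self, fn) -> "LandmarkSet":
        return LandmarkSet({k: fn(v[None, :])[0] for k, v in self.points.items()}, dict(self.schema))


CLASS_LABELS = ("control", "coronal", "sagittal", "metopic")


@dataclass
class Scan:
    """One subject: mesh + landmarks + diagnosis label."""

    mesh: SurfaceMesh
    landmarks: LandmarkSet
    label: str
    age_days: int = 0
    mirrored: bool = False

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise ValueError(f"label must be one of {CLASS_LABELS}, got {self.label!r}")
        if self.age_days < 0:
            raise ValueError("age_days must be nonnegative")


# ---------------------------------------------------------------------------
# mesh I/O


def read_mesh(path) -> SurfaceMesh:
    """Read an OBJ or PLY mesh.  Non-triangular faces raise MeshParseError."""
    path = str(path)
    if path.lower().endswith(".obj"):
        _check_obj_triangular(path)
    elif path.lower().endswith(".ply"):
        _check_ascii_ply_triangular(path)
    else:
        raise MeshParseError(f"unsupported mesh format: {path}")
    try:
        tm = trimesh.load(path, process=False, force="mesh")
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise MeshParseError(f"could not read mesh {path}: {exc}") from exc
    if not hasattr(tm, "faces") or len(tm.faces) == 0 and len(tm.vertices) == 0:
        raise MeshParseError(f"no mesh data in {path}")
    return SurfaceMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64))


def _check_obj_triangular(path: str) -> None:
    with open(path, "r", errors="replace") as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("f "):
                n = len(line.split()) - 1
                if n != 3:
                    raise MeshParseError(
                        f"{path}:{lineno}: face with {n} vertices (only triangles supported): {line.strip()!r}"
                    )


def _check_ascii_ply_triangular(path: str) -> None:
    with open(path, "rb") as fh:
        header = fh.read(2048)
    if not header.startswith(b"ply"):
        raise MeshParseError(f"{path}: not a PLY file")
    if b"format ascii" not in header:
        return  # binary PLY: handled by the loader
    n_vert = n_face = 0
    with open(path, "r", errors="replace") as fh:
        for line in fh:
            line = line.strip()
            if m := re.match(r"element vertex (\d+)", line):
                n_vert = int(m.group(1))
            elif m := re.match(r"element face (\d+)", line):
                n_face = int(m.group(1))
            elif line == "end_header":
                break
        for _ in range(n_vert):
            next(fh)
        for i in range(n_face):
            counts = next(fh).split()
            if counts and int(counts[0]) != 3:
                raise MeshParseError(f"{path}: face {i} has {counts[0]} vertices (only triangles supported)")


def write_mesh(mesh: SurfaceMesh, path) -> None:
    """Write OBJ (1-based indices per the standard) or PLY."""
    path = str(path)
    tm = mesh.as_trimesh()
    if path.lower().endswith(".obj"):
        tm.export(path, include_normals=False, include_texture=False)
    elif path.lower().endswith(".ply"):
        tm.export(path, encoding="ascii")
    else:
        raise MeshParseError(f"unsupported mesh format: {path}")


def read_landmarks(path, schema: dict[str, str] | None = None) -> LandmarkSet:
    """Read landmarks from CSV (name,x,y,z) or JSON {name: [x,y,z]}."""
    path = str(path)
    schema = dict(DEFAULT_LANDMARK_SCHEMA) if schema is None else schema
    if path.lower().endswith(".json"):
        with open(path) as fh:
            raw = json.load(fh)
        pts = {k: np.asarray(v, float) for k, v in raw.items()}
    else:
        df = pd.read_csv(path)
        df.columns = [c.strip().lower() for c in df.columns]
        pts = {row["name"]: np.array([row["x"], row["y"], row["z"]]) for _, row in df.iterrows()}
    return LandmarkSet(pts, schema)


def write_landmarks(lms: LandmarkSet, path) -> None:
    path = str(path)
    if path.lower().endswith(".json"):
        with open(path, "w") as fh:
            json.dump({k: list(map(float, v)) for k, v in lms.points.items()}, fh, indent=1)
    else:
        rows = [{"name": k, "x": v[0], "y": v[1], "z": v[2]} for k, v in lms.points.items()]
        pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# mass matrix

# Deterministic barycentric sampling: each face is subdivided into
# level^2 congruent subtriangles and sampled at their centroids (400
# points per face at level 20).  Centroid sampling is exactly uniform
# over the face and never hits a tie boundary of the partition.
_BARY_LEVEL = 20


def _barycentric_grid(level: int = _BARY_LEVEL) -> np.ndarray:
    pts = []
    for i in range(level):
        for j in range(level - i):
            # upward subtriangle (i, j), (i+1, j), (i, j+1)
            pts.append((3 * i + 1, 3 * j + 1))
            if i + j < level - 1:
                # downward subtriangle (i+1, j), (i, j+1), (i+1, j+1)
                pts.append((3 * i + 2, 3 * j + 2))
    ij = np.array(pts, float) / (3 * level)
    return np.column_stack([ij, 1.0 - ij.sum(axis=1)])


def _face_partition_fractions(tri: np.ndarray, bary: np.ndarray) -> np.ndarray:
    """Fractions of a triangle's area attributed to its 6 elements.

    Each barycentric sample point is assigned to the nearest of six
    representative points: the 3 corner vertices and the 3 edge
    midpoints, mimicking a barycentric-cell dual.  Returns fractions in
    order [v0, v1, v2, e01, e12, e20] summing to 1.

    `tri` may be a stack (t, 3, 3); then the result is (t, 6).
    """
    single = tri.ndim == 2
    T = tri[None] if single else tri  # (t,3,3)
    pts = np.einsum("sk,tkd->tsd", bary, T)  # (t, s, 3)
    reps = np.stack(
        [
            T[:, 0],
            T[:, 1],
            T[:, 2],
            0.5 * (T[:, 0] + T[:, 1]),
            0.5 * (T[:, 1] + T[:, 2]),
            0.5 * (T[:, 2] + T[:, 0]),
        ],
        axis=1,
    )  # (t, 6, 3)
    d2 = ((pts[:, :, None, :] - reps[:, None, :, :]) ** 2).sum(-1)  # (t, s, 6)
    dmin = d2.min(axis=2, keepdims=True)
    # samples exactly on a region boundary are split between the tied
    # elements (keeps symmetric configurations exactly symmetric)
    tied = d2 <= dmin * (1.0 + 1e-9) + 1e-30
    share = tied / tied.sum(axis=2, keepdims=True)
    frac = share.mean(axis=1)  # (t, 6)
    return frac[0] if single else frac


@dataclass
class MassMatrix:
    """Area weights of a mesh: vertex weights on the diagonal, edge
    weights off-diagonal (symmetric, mm^2)."""

    M: sp.csr_matrix

    @property
    def M3(self) -> sp.csr_matrix:
        """3p x 3p channel-replicated version (Kronecker with I3)."""
        return stretch_mass_matrix(self.M)

    @property
    def diagonal(self) -> np.ndarray:
        return self.M.diagonal()

    def total_weight(self) -> float:
        """Sum of vertex weights plus unique-edge weights (= surface area)."""
        d = self.M.diagonal().sum()
        off = (self.M.sum() - self.M.diagonal().sum()) / 2.0
        return float(d + off)


def compute_mass_matrix(mesh: SurfaceMesh, level: int = _BARY_LEVEL) -> MassMatrix:
    """Partition every face's area among its 3 vertices and 3 edges.

    The partition uses a deterministic barycentric centroid grid (400
    samples per face at the default level); each sample goes to the nearest of the
    three corners and three edge midpoints, and the face area is split
    proportionally.  Zero-area faces contribute nothing.
    """
    if mesh.n_faces == 0:
        raise ValueError("mesh has no faces")
    bary = _barycentric_grid(level)
    tris = mesh.vertices[mesh.faces]  # (t,3,3)
    areas = mesh.face_areas()
    # chunk faces to bound the (faces, samples, 6) distance workspace
    chunks = []
    step = max(1, 20_000_000 // (len(bary) * 18))
    for lo in range(0, len(tris), step):
        chunks.append(_face_partition_fractions(tris[lo:lo + step], bary))
    frac = np.concatenate(chunks, axis=0)  # (t,6)
    w = frac * areas[:, None]
    p = mesh.n_vertices
    f = mesh.faces
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2], f[:, 0], f[:, 1], f[:, 2]])
    cols = np.concatenate([f[:, 0], f[:, 1], f[:, 2], f[:, 1], f[:, 2], f[:, 0]])
    vals = np.concatenate([w[:, 0], w[:, 1], w[:, 2], w[:, 3], w[:, 4], w[:, 5]])
    M = sp.coo_matrix((vals, (rows, cols)), shape=(p, p)).tocsr()
    M = (M + M.T) - sp.diags(M.diagonal())  # symmetrize edges, keep diagonal once
    return MassMatrix(M.tocsr())


def stretch_mass_matrix(M) -> sp.csr_matrix:
    """Nearest-neighbour-stretch a p x p weight matrix to 3p x 3p.

    M3[3i+c, 3j+c] = M[i, j] for each coordinate channel c; no
    cross-channel coupling (Kronecker product with the 3x3 identity).
    """
    M = sp.csr_matrix(M)
    if M.shape[0] != M.shape[1]:
        raise ValueError("M must be square")
    return sp.kron(M, sp.identity(3, format="csr"), format="csr")


# ---------------------------------------------------------------------------
# mirroring


def fit_midsagittal_plane(landmarks: LandmarkSet) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through the midline landmarks.

    Returns (point, unit normal).  Needs >= 3 midline landmarks.
    """
    names = landmarks.midline_names()
    if len(names) < 3:
        raise ValueError("need at least 3 midline landmarks to fit the midsagittal plane")
    pts = landmarks.array(names)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[2]


def mirror_points(points: np.ndarray, origin: np.ndarray, normal: np.ndarray) -> np.ndarray:
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    d = (points - origin) @ n
    return points - 2.0 * d[:, None] * n


def mirror_scan(scan: Scan, plane: tuple[np.ndarray, np.ndarray] | None = None) -> Scan:
    """Reflect a scan across its midsagittal plane.

    Face winding is reversed so normals stay outward; lateralized
    landmark names are swapped and the mirrored flag toggled.
    """
    if plane is None:
        plane = fit_midsagittal_plane(scan.landmarks)
    origin, normal = plane
    verts = mirror_points(scan.mesh.vertices, origin, normal)
    faces = scan.mesh.faces[:, ::-1].copy()
    lms = scan.landmarks.transform(lambda P: mirror_points(P, origin, normal)).swap_laterality()
    return replace(scan, mesh=SurfaceMesh(verts, faces), landmarks=lms, mirrored=not scan.mirrored)


def symmetry_vertex_map(mesh: SurfaceMesh, origin=None, normal=(1.0, 0.0, 0.0), tol: float = 1.0) -> np.ndarray:
    """Left-right vertex involution of a (near-)symmetric template.

    Maps each vertex to the vertex nearest its reflection across the
    plane; raises if any match is farther than `tol` mm or the map is
    not a permutation.
    """
    from scipy.spatial import cKDTree

    origin = np.zeros(3) if origin is None else np.asarray(origin, float)
    refl = mirror_points(mesh.vertices, origin, np.asarray(normal, float))
    tree = cKDTree(mesh.vertices)
    dist, idx = tree.query(refl)
    if dist.max() > tol:
        raise ValueError(f"template not symmetric within {tol} mm (max {dist.max():.3g})")
    if len(np.unique(idx)) != len(idx):
        raise ValueError("symmetry map is not a permutation")
    return idx


# ---------------------------------------------------------------------------
# cranial submesh


def extract_cranial_submesh(mesh: SurfaceMesh, mask: np.ndarray) -> tuple[SurfaceMesh, np.ndarray]:
    """Restrict a mesh to a vertex mask (template cranial region).

    `mask` is a boolean array of length p or an integer index list.
    Returns the submesh (faces fully inside the mask) and the map from
    submesh vertex index to original index.
    """
    mask = np.asarray(mask)
    if mask.dtype == bool:
        idx = np.flatnonzero(mask)
    else:
        idx = np.unique(mask.astype(np.int64))
    if idx.size == 0:
        raise ValueError("empty cranial mask")
    keep = np.zeros(mesh.n_vertices, dtype=bool)
    keep[idx] = True
    new_index = -np.ones(mesh.n_vertices, dtype=np.int64)
    new_index[idx] = np.arange(idx.size)
    inside = keep[mesh.faces].all(axis=1)
    sub_faces = new_index[mesh.faces[inside]]
    return SurfaceMesh(mesh.vertices[idx], sub_faces), idx
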