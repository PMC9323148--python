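"""Point-to-surface proximity queries.

Closest point on a triangle mesh for a batch of query points: candidate
triangles come from a KD-tree over triangle centroids (k nearest,
padded by the triangle ring of the nearest vertex), and the exact
closest point on each candidate triangle is computed with the standard
Voronoi-region case analysis, vectorized over (query, candidate).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["SurfaceProximity", "closest_point_on_triangles"]


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Closest point on each triangle to each query point.

    points: (n, 3); triangles: (n, k, 3, 3).  Returns (n, k, 3).
    """
    a = triangles[..., 0, :]
    b = triangles[..., 1, :]
    c = triangles[..., 2, :]
    p = points[:, None, :]

    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("...i,...i->...", ab, ap)
    d2 = np.einsum("...i,...i->...", ac, ap)

    bp = p - b
    d3 = np.einsum("...i,...i->...", ab, bp)
    d4 = np.einsum("...i,...i->...", ac, bp)

    cp = p - c
    d5 = np.einsum("...i,...i->...", ab, cp)
    d6 = np.einsum("...i,...i->...", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    denom_vw = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v_face = np.where(denom_vw != 0, vb / denom_vw, 0.0)
        w_face = np.where(denom_vw != 0, vc / denom_vw, 0.0)
        t_ab = np.where((d1 - d3) != 0, d1 / (d1 - d3), 0.0)
        t_ac = np.where((d2 - d6) != 0, d2 / (d2 - d6), 0.0)
        t_bc_num = d4 - d3
        t_bc_den = (d4 - d3) + (d5 - d6)
        t_bc = np.where(t_bc_den != 0, t_bc_num / t_bc_den, 0.0)

    # region masks (Ericson, Real-Time Collision Detection 5.1.5)
    out = np.empty_like(np.broadcast_to(a, np.broadcast_shapes(a.shape, p.shape)).copy())
    reg_a = (d1 <= 0) & (d2 <= 0)
    reg_b = (d3 >= 0) & (d4 <= d3)
    reg_c = (d6 >= 0) & (d5 <= d6)
    reg_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    reg_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    reg_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)

    face_pt = a + v_face[..., None] * ab + w_face[..., None] * ac
    out[:] = face_pt
    np.copyto(out, b + np.clip(t_bc, 0, 1)[..., None] * (c - b), where=reg_bc[..., None])
    np.copyto(out, a + np.clip(t_ac, 0, 1)[..., None] * ac, where=reg_ac[..., None])
    np.copyto(out, a + np.clip(t_ab, 0, 1)[..., None] * ab, where=reg_ab[..., None])
    np.copyto(out, c, where=reg_c[..., None])
    np.copyto(out, b, where=reg_b[..., None])
    np.copyto(out, a, where=reg_a[..., None])
    return out


class SurfaceProximity:
    """Closest-point queries against a fixed triangle mesh."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, k_candidates: int = 12):
        self.vertices = np.asarray(vertices, float)
        self.faces = np.asarray(faces, np.int64)
        self.triangles = self.vertices[self.faces]  # (t, 3, 3)
        self._centroids = self.triangles.mean(axis=1)
        self._tree = cKDTree(self._centroids)
        self.k = min(k_candidates, len(self.faces))
        ab = self.triangles[:, 1] - self.triangles[:, 0]
        ac = self.triangles[:, 2] - self.triangles[:, 0]
        n = np.cross(ab, ac)
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        self.face_normals = n / norm

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Returns (closest points (n,3), distances (n,), face ids (n,))."""
        points = np.asarray(points, float)
        _, cand = self._tree.query(points, k=self.k)
        if self.k == 1:
            cand = cand[:, None]
        tris = self.triangles[cand]  # (n, k, 3, 3)
        cp = closest_point_on_triangles(points, tris)  # (n, k, 3)
        d2 = ((cp - points[:, None, :]) ** 2).sum(-1)
        best = d2.argmin(axis=1)
        rows = np.arange(len(points))
        closest = cp[rows, best]
        dist = np.sqrt(d2[rows, best])
        tri_id = cand[rows, best]
        return closest, dist, tri_id
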