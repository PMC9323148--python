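"""Template-to-scan correspondence establishment.

Two stages: a closed-form landmark similarity alignment (translation,
rotation, isotropic scale), followed by optimal-step nonrigid ICP with
one affine transform per template vertex (N-ICP-A).  The nonrigid stage
minimises, at each stiffness level, the sum of

* a stiffness term penalising differences between affine transforms of
  edge-adjacent template vertices (weighted ``diag(1, 1, 1, gamma)``),
* a distance term pulling each template vertex to its current closest
  point on the target surface (pruned correspondences get zero weight),
* a landmark term tying annotated template vertices to the target
  landmarks,

which is a sparse linear least-squares problem in the stacked 4x3
per-vertex affines, solved exactly per iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
import trimesh

from ._proximity import SurfaceProximity
from .mesh import LandmarkSet, SurfaceMesh

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityTransform",
    "NICPConfig",
    "MorphResult",
    "procrustes_similarity",
    "nicp_affine",
]


@dataclass
class SimilarityTransform:
    """x -> scale * R @ x + t  (isotropic scale, proper rotation)."""

    scale: float
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float).reshape(3, 3)
        self.translation = np.asarray(self.translation, float).reshape(3)
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * points @ self.rotation.T + self.translation


def procrustes_similarity(source: LandmarkSet | np.ndarray, target: LandmarkSet | np.ndarray) -> SimilarityTransform:
    """Least-squares similarity transform mapping source landmarks onto
    target landmarks (Umeyama closed form; det(R) = +1 enforced)."""
    if isinstance(source, LandmarkSet):
        names = source.names
        if isinstance(target, LandmarkSet):
            if set(names) != set(target.names):
                raise ValueError("landmark name sets differ")
            B = target.array(names)
        else:
            B = np.asarray(target, float)
        A = source.array(names)
    else:
        A = np.asarray(source, float)
        B = np.asarray(target, float)
    if A.shape != B.shape or A.shape[0] < 3:
        raise ValueError("need >= 3 matched landmarks")
    mu_a, mu_b = A.mean(0), B.mean(0)
    A0, B0 = A - mu_a, B - mu_b
    cov = B0.T @ A0 / len(A)
    U, s, Vt = np.linalg.svd(cov)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("landmarks are collinear; similarity transform is ill-posed")
    d = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    var_a = (A0**2).sum() / len(A)
    scale = float(np.trace(np.diag(s) @ D) / var_a)
    t = mu_b - scale * R @ mu_a
    return SimilarityTransform(scale, R, t)


@dataclass
class NICPConfig:
    """Hyperparameters of the optimal-step nonrigid ICP.

    ``stiffness_schedule`` must be strictly decreasing; the landmark
    weight schedule has the same length (typically decaying to zero so
    that the surface term dominates at the end).  Correspondences whose
    normal angle exceeds ``max_normal_angle_deg`` or whose distance
    exceeds ``max_distance_factor`` times the template's median edge
    length are pruned (zero distance weight) for that iteration.
    """

    stiffness_schedule: tuple = (100.0, 51.8, 26.8, 13.9, 7.2, 3.7, 1.9, 1.0)
    landmark_weight_schedule: tuple | None = None  # default: linear 10 -> 0
    gamma: float = 1.0
    inner_tolerance_factor: float = 1e-4  # threshold = factor * p
    max_inner_iterations: int = 20
    max_normal_angle_deg: float = 90.0
    max_distance_factor: float = 10.0

    def __post_init__(self) -> None:
        s = np.asarray(self.stiffness_schedule, float)
        if s.size == 0 or np.any(np.diff(s) >= 0) and s.size > 1:
            raise ValueError("stiffness schedule must be nonempty and strictly decreasing")
        if self.landmark_weight_schedule is None:
            self.landmark_weight_schedule = tuple(np.linspace(10.0, 0.0, s.size))
        if len(self.landmark_weight_schedule) != s.size:
            raise ValueError("landmark weight schedule length must match stiffness schedule")

    @classmethod
    def fast(cls) -> "NICPConfig":
        """Reduced schedule for large batch runs."""
        return cls(
            stiffness_schedule=(50.0, 10.0, 2.0, 0.5),
            landmark_weight_schedule=(10.0, 5.0, 1.0, 0.0),
            max_inner_iterations=4,
        )


@dataclass
class MorphResult:
    """Output of nicp_affine: template topology, target geometry."""

    morphed: SurfaceMesh
    per_vertex_transforms: np.ndarray  # (p, 4, 3) stacked affines
    converged: bool
    distance_trace: list = field(default_factory=list)  # mean v2nn per stiffness level





def nicp_affine(
    template: SurfaceMesh,
    target: SurfaceMesh,
    template_lm_indices: np.ndarray | None = None,
    target_landmarks: LandmarkSet | np.ndarray | None = None,
    config: NICPConfig | None = None,
) -> MorphResult:
    """Morph the template onto the target with per-vertex affines.

    The template should already be similarity-aligned to the target
    (see :func:`procrustes_similarity`).  Returns the morphed mesh on
    the template's topology together with the per-vertex transforms and
    the mean vertex-to-surface distance after each stiffness level.
    """
    config = config or NICPConfig()
    p = template.n_vertices
    edges = template.edges
    n_e = len(edges)

    # node-arc incidence kron diag(G): rows 4e+c, cols 4i+c and 4j+c
    G = np.array([1.0, 1.0, 1.0, config.gamma])
    r = (4 * np.repeat(np.arange(n_e), 8) + np.tile(np.repeat(np.arange(4), 2), n_e))
    c = np.empty(8 * n_e, dtype=np.int64)
    vals = np.empty(8 * n_e)
    for k in range(4):
        c[2 * k::8] = 4 * edges[:, 0] + k
        c[2 * k + 1::8] = 4 * edges[:, 1] + k
        vals[2 * k::8] = G[k]
        vals[2 * k + 1::8] = -G[k]
    MG = sp.csr_matrix((vals, (r, c)), shape=(4 * n_e, 4 * p))
    MGtMG = (MG.T @ MG).tocsc()

    prox = SurfaceProximity(target.vertices, target.faces)
    target_face_normals = prox.face_normals

    lm_idx = None
    lm_pos = None
    if template_lm_indices is not None and target_landmarks is not None:
        lm_idx = np.asarray(template_lm_indices, dtype=np.int64)
        if isinstance(target_landmarks, LandmarkSet):
            lm_pos = target_landmarks.array()
        else:
            lm_pos = np.asarray(target_landmarks, float)
        if len(lm_idx) != len(lm_pos):
            raise ValueError("landmark index/position length mismatch")

    median_edge = float(np.median(np.linalg.norm(
        template.vertices[edges[:, 0]] - template.vertices[edges[:, 1]], axis=1)))
    max_dist = config.max_distance_factor * median_edge
    cos_max = np.cos(np.deg2rad(config.max_normal_angle_deg))

    # unknowns: X (4p x 3); initialize to identity affines
    X = np.zeros((4 * p, 3))
    X[0::4, 0] = X[1::4, 1] = X[2::4, 2] = 1.0

    hom = np.hstack([template.vertices, np.ones((p, 1))])  # (p, 4)
    base_rows = np.repeat(np.arange(p), 4)
    base_cols = (4 * np.arange(p)[:, None] + np.arange(4)).reshape(-1)

    def D_matrix(weights: np.ndarray) -> sp.csr_matrix:
        vals = (hom * weights[:, None]).reshape(-1)
        return sp.csr_matrix((vals, (base_rows, base_cols)), shape=(p, 4 * p))

    D1 = D_matrix(np.ones(p))

    converged = True
    trace: list[float] = []
    inner_tol = config.inner_tolerance_factor * p

    for alpha, beta in zip(config.stiffness_schedule, config.landmark_weight_schedule):
        level_converged = False
        for _ in range(config.max_inner_iterations):
            current = D1 @ X  # morphed vertices (p, 3)
            closest, dist, tri_id = prox.query(current)
            w = np.ones(p)
            w[dist > max_dist] = 0.0
            # normal compatibility: current template normals vs target face normals
            cur_tm = trimesh.Trimesh(current, template.faces, process=False)
            cur_normals = np.asarray(cur_tm.vertex_normals)
            cosang = np.einsum("ij,ij->i", cur_normals, target_face_normals[tri_id])
            w[cosang < cos_max] = 0.0

            Dw = D_matrix(w)
            A = MGtMG * (alpha**2) + (Dw.T @ Dw)
            rhs = Dw.T @ (w[:, None] * closest)
            if beta > 0 and lm_idx is not None:
                DL = sp.csr_matrix(
                    (hom[lm_idx].reshape(-1),
                     (np.repeat(np.arange(len(lm_idx)), 4),
                      (4 * lm_idx[:, None] + np.arange(4)).reshape(-1))),
                    shape=(len(lm_idx), 4 * p),
                )
                A = A + (beta**2) * (DL.T @ DL)
                rhs = rhs + (beta**2) * (DL.T @ lm_pos)
            try:
                solve = spla.factorized(A.tocsc())
            except RuntimeError as exc:
                raise RuntimeError(f"singular N-ICP system (disconnected template?): {exc}") from exc
            X_new = np.column_stack([solve(rhs[:, k]) for k in range(3)])
            change = float(np.linalg.norm(X_new - X))
            X = X_new
            if change < inner_tol:
                level_converged = True
                break
        if not level_converged:
            logger.warning("N-ICP-A did not converge at stiffness %.3g", alpha)
            converged = False
        morphed_now = D1 @ X
        _, dist_now, _ = prox.query(morphed_now)
        trace.append(float(dist_now.mean()))

    morphed = SurfaceMesh(D1 @ X, template.faces.copy())
    transforms = X.reshape(p, 4, 3)
    return MorphResult(morphed, transforms, converged, trace)
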