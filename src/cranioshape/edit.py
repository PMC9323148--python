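"""Shape-editing applications of the head model.

Two tools: (1) pathology change by attribute regression -- translating
a subject's coefficient vector by the difference of two class-mean
coefficient vectors (e.g. scaphocephaly -> control); (2) flexibility
modes of a partially fixed head -- directions in coefficient space
that maximally displace the free region (face, ears, neck) while
moving a fixed region (the cranium) minimally, obtained from a
constrained generalized eigenvalue problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .model import ShapeModelResults

__all__ = [
    "class_mean_coefficients",
    "remove_pathology",
    "FlexibilityBasis",
    "flexibility_modes",
    "sample_constrained",
]


def class_mean_coefficients(results: ShapeModelResults, shapes=None, labels=None) -> dict[str, np.ndarray]:
    """Per-class mean coefficient vectors in the model's frame.

    Defaults to the model's own (aligned) training shapes and labels;
    alternatively pass corresponded shapes (n, p, 3) and labels.
    """
    if shapes is None:
        if results.aligned_shapes is None or results.labels is None:
            raise ValueError("model carries no training shapes/labels; pass them explicitly")
        shapes = results.aligned_shapes
        labels = results.labels
    shapes = np.asarray(shapes, float)
    labels = np.asarray(labels)
    out: dict[str, np.ndarray] = {}
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        alphas = np.stack([results.project_mesh(shapes[i]) for i in idx])
        out[str(cls)] = alphas.mean(axis=0)
    return out


def remove_pathology(alpha, from_class: str, to_class: str, class_means: dict) -> np.ndarray:
    """Translate coefficients between class means:
    alpha_out = alpha + alpha_mu[to] - alpha_mu[from]."""
    for c in (from_class, to_class):
        if c not in class_means:
            raise ValueError(f"unknown class {c!r}; have {sorted(class_means)}")
    alpha = np.asarray(alpha, float)
    return alpha + np.asarray(class_means[to_class]) - np.asarray(class_means[from_class])


@dataclass
class FlexibilityBasis:
    """Coefficient-space directions ranked by free-to-fixed displacement
    ratio (generalized eigenvalues, descending)."""

    modes: np.ndarray        # (m, n_modes) columns = directions in alpha space
    eigenvalues: np.ndarray  # (n_modes,) free/fixed displacement ratios
    fixed_vertex_ids: np.ndarray
    epsilon: float


def _coordinate_rows(fixed_vertex_ids: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    fixed = np.zeros(p, bool)
    fixed[np.asarray(fixed_vertex_ids, np.int64)] = True
    coords_fixed = np.flatnonzero(np.repeat(fixed, 3))
    coords_free = np.flatnonzero(np.repeat(~fixed, 3))
    return coords_free, coords_fixed


def flexibility_modes(
    results: ShapeModelResults,
    fixed_vertex_ids,
    epsilon: float | None = None,
    n_modes: int | None = None,
) -> FlexibilityBasis:
    """Solve the constrained generalized eigenvalue problem.

    With S = V Lambda^{1/2} (displacement per unit coefficient), A the
    rows of S at free coordinates and B the rows at fixed coordinates,
    solve (A^T A) w = lambda (B^T B + eps I) w.  The leading
    eigenvectors are coefficient directions whose synthesized shapes
    move the free region much more than the fixed region.

    epsilon defaults to 1e-8 * trace(B^T B) / rank (Tikhonov floor;
    the pure ratio problem is singular when B^T B is rank-deficient).
    """
    fixed_vertex_ids = np.unique(np.asarray(fixed_vertex_ids, np.int64))
    p = results.n_vertices
    if fixed_vertex_ids.size == 0:
        raise ValueError("fixed vertex set is empty")
    if fixed_vertex_ids.size >= p:
        raise ValueError("fixed vertex set must be a strict subset of the vertices")
    S = results.components * np.sqrt(results.eigenvalues)[None, :]
    free_rows, fixed_rows = _coordinate_rows(fixed_vertex_ids, p)
    A = S[free_rows]
    B = S[fixed_rows]
    AtA = A.T @ A
    BtB = B.T @ B
    if epsilon is None:
        epsilon = 1e-8 * np.trace(BtB) / results.rank
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    lam, W = scipy.linalg.eigh(AtA, BtB + epsilon * np.eye(results.rank))
    lam, W = lam[::-1], W[:, ::-1]
    lam = np.clip(lam, 0.0, None)
    if n_modes is not None:
        lam, W = lam[:n_modes], W[:, :n_modes]
    return FlexibilityBasis(W, lam, fixed_vertex_ids, float(epsilon))


def sample_constrained(
    results: ShapeModelResults,
    basis: FlexibilityBasis,
    n: int,
    seed: int | None = None,
    base_alpha=None,
    n_modes: int = 3,
    scale: float = 1.0,
) -> np.ndarray:
    """Gaussian draws along the top flexibility modes around a base shape.

    Each mode direction is normalized so its synthesized displacement
    field has unit RMS over the free region; draws are i.i.d. standard
    normal times `scale` along each of the first `n_modes` modes.
    Returns (n, p, 3); n = 0 returns the base shape alone as (1, p, 3).
    """
    if basis.modes.shape[0] != results.rank:
        raise ValueError("basis does not match model rank")
    base_alpha = np.zeros(results.rank) if base_alpha is None else np.asarray(base_alpha, float)
    n_modes = min(n_modes, basis.modes.shape[1])
    p = results.n_vertices
    free_rows, _ = _coordinate_rows(basis.fixed_vertex_ids, p)
    S = results.components * np.sqrt(results.eigenvalues)[None, :]
    dirs = []
    for k in range(n_modes):
        w = basis.modes[:, k]
        disp = S[free_rows] @ w
        rms = np.sqrt(np.mean(disp**2))
        dirs.append(w / max(rms, 1e-300))
    dirs = np.stack(dirs, axis=1)  # (m, n_modes)
    if n == 0:
        return results.synthesize(base_alpha).reshape(1, -1, 3)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, n_modes)) * scale
    out = [results.synthesize(base_alpha + dirs @ zi).reshape(-1, 3) for zi in z]
    return np.stack(out)
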