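"""Morphing-quality and shape-model-quality metrics.

Morphing metrics: sparse landmark error, dense vertex-to-nearest-
neighbour surface distance, and per-class surface-normal deviation
(how consistently point identifiers land on similarly oriented surface
across a class, after removing rigid pose per class).

Model metrics: compactness (cumulative variance fraction),
generalization (leave-one-out reconstruction error, mm) and
specificity (mean distance of Gaussian samples to the nearest training
shape, mm) as functions of the number of components.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from .mesh import LandmarkSet, SurfaceMesh
from .model import PointDistributionModel, ShapeModelResults, generalized_procrustes_rigid, rigid_align

logger = logging.getLogger(__name__)

__all__ = [
    "landmark_error",
    "v2nn_distance",
    "surface_normal_deviation_per_class",
    "compactness",
    "generalization",
    "specificity",
    "model_metric_table",
]


def landmark_error(
    morphed: SurfaceMesh, template_lm_indices, target_lms: LandmarkSet | np.ndarray
) -> float:
    """Mean Euclidean distance (mm) between morphed template landmark
    vertices and the annotated target landmarks."""
    idx = np.asarray(template_lm_indices, np.int64)
    pos = target_lms.array() if isinstance(target_lms, LandmarkSet) else np.asarray(target_lms, float)
    if len(idx) != len(pos):
        raise ValueError("landmark count mismatch")
    return float(np.linalg.norm(morphed.vertices[idx] - pos, axis=1).mean())


def v2nn_distance(morphed: SurfaceMesh, target: SurfaceMesh) -> float:
    """Mean distance (mm) from morphed vertices to the nearest point on
    the target surface (point-to-triangle)."""
    from ._proximity import SurfaceProximity

    _, dist, _ = SurfaceProximity(target.vertices, target.faces).query(morphed.vertices)
    return float(dist.mean())


def surface_normal_deviation_per_class(
    morphed_set, labels, align: bool = True
) -> tuple[float, dict[str, float]]:
    """Mean pairwise per-vertex normal angle (degrees), per class.

    Classes are first rigidly GPA-aligned (pose removed); for every
    vertex the mean pairwise angle between corresponding vertex normals
    across the class members is computed, averaged over vertices, then
    combined across classes weighted by class size.  Returns
    (cumulative mean, per-class dict); classes of size 1 are skipped.
    """
    labels = np.asarray(labels)
    meshes = list(morphed_set)
    faces = meshes[0].faces
    per_class: dict[str, float] = {}
    weights: dict[str, int] = {}
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            warnings.warn(f"class {cls!r} has one member; excluded from normal deviation")
            continue
        shapes = np.stack([meshes[i].vertices for i in idx])
        if align:
            shapes, _ = generalized_procrustes_rigid(shapes)
        normals = np.stack(
            [SurfaceMesh(s, faces).vertex_normals() for s in shapes]
        )  # (k, p, 3)
        k = len(idx)
        angles = []
        for a in range(k):
            for b in range(a + 1, k):
                cosang = np.clip(np.einsum("ij,ij->i", normals[a], normals[b]), -1.0, 1.0)
                angles.append(np.degrees(np.arccos(cosang)))
        per_vertex = np.mean(angles, axis=0)  # mean pairwise angle per vertex
        per_class[str(cls)] = float(per_vertex.mean())
        weights[str(cls)] = idx.size
    if not per_class:
        raise ValueError("no class with >= 2 members")
    total = sum(weights.values())
    cumulative = sum(per_class[c] * weights[c] for c in per_class) / total
    return cumulative, per_class


# ---------------------------------------------------------------------------
# model metrics


def compactness(results: ShapeModelResults, m: int) -> float:
    """Fraction of total variance captured by the first m components."""
    return results.compactness(m)


def generalization(
    shapes,
    faces,
    m: int,
    mass=None,
    align_folds: bool = True,
    per_fold: bool = False,
):
    """Leave-one-out reconstruction error (mm) with m components.

    For each shape: a model is rebuilt from the remaining shapes, the
    left-out shape is rigidly aligned to the fold mean (skipped when
    ``align_folds`` is False), projected onto the first m components
    and synthesized; the error is the mean per-vertex Euclidean
    distance.  Returns the average over folds (or the per-fold array).
    """
    from .model import _as_shape_array

    X = _as_shape_array(shapes)
    n = len(X)
    if n < 3:
        raise ValueError("leave-one-out needs n >= 3")
    errs = []
    for i in range(n):
        rest = np.delete(X, i, axis=0)
        res = PointDistributionModel(rest, faces=faces, mass=mass, align=align_folds).fit()
        m_i = min(m, res.rank)
        if m_i < m:
            warnings.warn(f"fold {i}: rank {res.rank} < m={m}; clamped")
        aligned = res.align_to_model(X[i]) if align_folds else X[i]
        alpha = res.project(aligned.reshape(-1), n_components=m_i)
        rec = res.synthesize(alpha).reshape(-1, 3)
        errs.append(float(np.linalg.norm(aligned - rec, axis=1).mean()))
    errs = np.asarray(errs)
    return errs if per_fold else float(errs.mean())


def specificity(
    results: ShapeModelResults,
    training_shapes,
    n_samples: int,
    m: int,
    seed: int | None = None,
) -> float:
    """Mean distance (mm) of Gaussian model samples to the nearest
    training shape (per-vertex mean over corresponded vertices)."""
    from .model import _as_shape_array

    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    train = _as_shape_array(training_shapes)
    samples = results.sample(n_samples, seed=seed, n_components=m)
    out = []
    for s in samples:
        d = np.linalg.norm(train - s[None], axis=2).mean(axis=1)  # per training shape
        out.append(float(d.min()))
    return float(np.mean(out))


@dataclass
class ModelMetricTable:
    """Per-m model metrics (rows align with `n_components`)."""

    n_components: np.ndarray
    compactness: np.ndarray
    generalization: np.ndarray
    specificity: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "n_components": self.n_components,
                "compactness": self.compactness,
                "generalization_mm": self.generalization,
                "specificity_mm": self.specificity,
            }
        )


def model_metric_table(
    results: ShapeModelResults,
    shapes,
    faces,
    max_components: int | None = None,
    n_specificity_samples: int = 20,
    seed: int = 0,
) -> ModelMetricTable:
    """Compactness / generalization / specificity for m = 1..max."""
    m_max = results.rank if max_components is None else min(max_components, results.rank)
    ms = np.arange(1, m_max + 1)
    comp = np.array([results.compactness(m) for m in ms])
    gen = np.array([generalization(shapes, faces, m) for m in ms])
    spec = np.array([specificity(results, shapes, n_specificity_samples, m, seed=seed) for m in ms])
    return ModelMetricTable(ms, comp, gen, spec)
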