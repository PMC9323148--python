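"""Seeded generator of synthetic infant head scans with class-specific
deformities.

No patient data can be redistributed, so every stage of the pipeline
runs on synthetic heads: a subdivided icosphere scaled to infant head
proportions, with a smooth frontal face/nose protrusion, ten named
landmarks at analytically known positions, and smooth class-specific
deformation fields:

* ``sagittal`` (scaphocephaly): anteroposterior elongation with
  lateral narrowing (anisotropic scaling by sqrt(1+m) / 1/sqrt(1+m),
  so the length/width ratio grows by exactly (1+m));
* ``metopic`` (trigonocephaly): anterior wedge pulling the forehead
  toward the midline;
* ``coronal`` (anterior plagiocephaly): unilateral frontal flattening
  with a contralateral bulge (random side per scan);
* ``control``: small random left-right-symmetric smooth perturbation.

Landmarks ride every deformation field, so they stay anatomically
consistent.  All randomness is driven by a single integer seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import trimesh

from .mesh import (
    DEFAULT_LANDMARK_SCHEMA,
    LandmarkSet,
    Scan,
    SurfaceMesh,
    write_landmarks,
    write_mesh,
)

__all__ = [
    "CohortSpec",
    "HeadTemplate",
    "make_template",
    "generate_head",
    "generate_cohort",
    "default_cranial_mask",
]

# infant head proxy semi-axes (mm): x lateral, y anteroposterior, z vertical
SEMI_AXES = np.array([65.0, 80.0, 70.0])

# unit-sphere directions of the ten landmarks (left = +x, anterior = +y)
_LM_DIRECTIONS = {
    "nasion": (0.0, 1.0, 0.15),
    "sellion": (0.0, 1.0, 0.02),
    "opisthocranion": (0.0, -1.0, 0.0),
    "vertex": (0.0, 0.0, 1.0),
    "exocanthion_left": (0.5, 0.9, 0.12),
    "exocanthion_right": (-0.5, 0.9, 0.12),
    "tragion_left": (1.0, -0.1, -0.2),
    "tragion_right": (-1.0, -0.1, -0.2),
    "euryon_left": (1.0, 0.0, 0.1),
    "euryon_right": (-1.0, 0.0, 0.1),
}

# frontal protrusions: (unit direction, amplitude mm, angular width rad)
_FACE_BUMPS = (
    ((0.0, 0.94, -0.34), 10.0, 0.9),  # face/chin region
    ((0.0, 0.995, 0.10), 5.0, 0.35),  # nose
)

# per-subject facial variability: symmetric localized bumps (unit
# direction, angular width); amplitudes are drawn per scan.  All lie
# below the cranial region (an explicit vertical taper enforces it).
_FACE_VARIATION_BUMPS = (
    (((0.0, 0.995, 0.10),), 0.3),                           # nose size
    (((0.0, 0.97, -0.24),), 0.3),                           # mouth/philtrum
    (((0.0, 0.85, -0.53),), 0.5),                           # chin/jaw
    (((0.55, 0.72, -0.42), (-0.55, 0.72, -0.42)), 0.45),    # cheeks (paired)
    (((0.85, 0.35, -0.4), (-0.85, 0.35, -0.4)), 0.4),       # jaw sides (paired)
    (((0.98, -0.12, -0.17), (-0.98, -0.12, -0.17)), 0.35),  # ears (paired)
    (((0.6, -0.7, -0.38), (-0.6, -0.7, -0.38)), 0.45),      # mastoid/nape (paired)
    (((0.0, -0.55, -0.84),), 0.6),                          # neck/occiput base
)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


def _face_protrusion(u: np.ndarray) -> np.ndarray:
    """Radial displacement (mm) of the frontal face bumps at unit
    directions u; smooth cosine windows, symmetric in x."""
    disp = np.zeros_like(u)
    for d0, amp, width in _FACE_BUMPS:
        d0 = _unit(d0)
        ang = np.arccos(np.clip(u @ d0, -1.0, 1.0))
        w = np.where(ang < width, 0.5 * (1.0 + np.cos(np.pi * ang / width)), 0.0)
        disp += amp * w[:, None] * u
    return disp


def _smooth_pos(t: np.ndarray) -> np.ndarray:
    """max(0, t)^2 -- a C1 one-sided window."""
    return np.clip(t, 0.0, None) ** 2


def _below_cranium_taper(uz: np.ndarray) -> np.ndarray:
    """1 below uz = -0.15, 0 above uz = 0, cosine in between: keeps
    facial variability strictly out of the cranial region."""
    t = np.clip((uz + 0.15) / 0.15, 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * t))


def _face_variation_field(u: np.ndarray, amplitudes: np.ndarray) -> np.ndarray:
    """Radial displacement (mm) of the per-subject facial bumps.

    Paired bumps share one amplitude, keeping the field left-right
    symmetric (controls stay exactly symmetric)."""
    disp = np.zeros_like(u)
    taper = _below_cranium_taper(u[:, 2])
    for amp, (dirs, width) in zip(amplitudes, _FACE_VARIATION_BUMPS):
        for d0 in dirs:
            d0 = _unit(d0)
            ang = np.arccos(np.clip(u @ d0, -1.0, 1.0))
            w = np.where(ang < width, 0.5 * (1.0 + np.cos(np.pi * ang / width)), 0.0)
            disp += amp * (w * taper)[:, None] * u
    return disp


def _metopic_field(u: np.ndarray, pts: np.ndarray, magnitude: float) -> np.ndarray:
    """Anterior wedge: pull x toward the midline over the forehead."""
    w = _smooth_pos(u[:, 1]) * (0.25 + 0.75 * np.clip(u[:, 2], 0.0, None))
    disp = np.zeros_like(pts)
    disp[:, 0] = -magnitude * w * pts[:, 0]
    return disp


def _coronal_field(u: np.ndarray, pts: np.ndarray, magnitude: float, side: int) -> np.ndarray:
    """Unilateral frontal flattening (side = +1 left, -1 right) with a
    contralateral bulge; displacement along y."""
    h = _smooth_pos(u[:, 1])
    flat = _smooth_pos(side * u[:, 0])
    bulge = _smooth_pos(-side * u[:, 0])
    disp = np.zeros_like(pts)
    disp[:, 1] = magnitude * SEMI_AXES[1] * h * (-0.8 * flat + 0.4 * bulge)
    return disp


def _control_field(u: np.ndarray, pts: np.ndarray, magnitude: float, coeffs: np.ndarray) -> np.ndarray:
    """Small smooth symmetric perturbation: radial scaling by a random
    even-in-x polynomial field (exactly left-right symmetric)."""
    x2, y, z = u[:, 0] ** 2, u[:, 1], u[:, 2]
    basis = np.stack([x2, y, z, y * z, x2 * y, y**2 - z**2], axis=1)
    r = magnitude * (basis @ coeffs)
    return r[:, None] * pts


def _sagittal_scale(magnitude: float) -> np.ndarray:
    s = np.sqrt(1.0 + magnitude)
    return np.array([1.0 / s, s, 1.0])


@dataclass
class HeadTemplate:
    """Undeformed head proxy used as the morphing template."""

    mesh: SurfaceMesh
    landmarks: LandmarkSet
    landmark_vertex_indices: np.ndarray  # nearest template vertex per landmark

    @property
    def landmark_names(self) -> list[str]:
        return self.landmarks.names


def _base_head(subdivisions: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Unit icosphere + landmark unit directions -> base head (mm)."""
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    u = np.asarray(ico.vertices, float)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    faces = np.asarray(ico.faces, np.int64)
    lm_u = {k: _unit(v) for k, v in _LM_DIRECTIONS.items()}
    return u, faces, u * SEMI_AXES, lm_u


def make_template(subdivisions: int = 4) -> HeadTemplate:
    """Symmetric, undeformed head with face protrusion and landmarks."""
    u, faces, pts, lm_u = _base_head(subdivisions)
    pts = pts + _face_protrusion(u)
    lm_dirs = np.stack(list(lm_u.values()))
    lm_pts = lm_dirs * SEMI_AXES + _face_protrusion(lm_dirs)
    lms = LandmarkSet(dict(zip(lm_u.keys(), lm_pts)), dict(DEFAULT_LANDMARK_SCHEMA))
    from scipy.spatial import cKDTree

    _, idx = cKDTree(pts).query(lms.array())
    return HeadTemplate(SurfaceMesh(pts, faces), lms, np.asarray(idx, np.int64))


def generate_head(
    class_label: str,
    magnitude: float = 0.3,
    size: float = 1.0,
    noise: float = 0.5,
    seed: int | None = None,
    subdivisions: int = 4,
    coronal_side: int | None = None,
    age_days: int | None = None,
    face_variation: float = 2.0,
) -> Scan:
    """Generate one synthetic head scan of the given class.

    magnitude controls the deformity strength (dimensionless; the
    sagittal length/width ratio grows by exactly 1 + magnitude); size
    is a global scale factor; noise is the i.i.d. Gaussian vertex
    displacement sigma in mm (mesh only, landmarks stay exact);
    face_variation is the amplitude sigma (mm) of the per-subject
    symmetric facial bumps (nose, chin, cheeks, ears).
    """
    if class_label not in ("control", "coronal", "sagittal", "metopic"):
        raise ValueError(f"unknown class {class_label!r}")
    rng = np.random.default_rng(seed)
    u, faces, pts, lm_u = _base_head(subdivisions)
    lm_names = list(lm_u.keys())
    lm_dirs = np.stack([lm_u[k] for k in lm_names])
    lm_pts = lm_dirs * SEMI_AXES

    pts = pts + _face_protrusion(u)
    lm_pts = lm_pts + _face_protrusion(lm_dirs)

    if face_variation > 0:
        amps = rng.normal(0.0, face_variation, len(_FACE_VARIATION_BUMPS))
        pts = pts + _face_variation_field(u, amps)
        lm_pts = lm_pts + _face_variation_field(lm_dirs, amps)

    # class-specific deformation; landmarks ride the same field
    if class_label == "control":
        coeffs = rng.standard_normal(6)
        mag = 0.1 * magnitude  # controls get a mild symmetric perturbation
        pts = pts + _control_field(u, pts, mag, coeffs)
        lm_pts = lm_pts + _control_field(lm_dirs, lm_pts, mag, coeffs)
    elif class_label == "metopic":
        pts = pts + _metopic_field(u, pts, magnitude)
        lm_pts = lm_pts + _metopic_field(lm_dirs, lm_pts, magnitude)
    elif class_label == "coronal":
        side = int(coronal_side) if coronal_side is not None else (1 if rng.random() < 0.5 else -1)
        pts = pts + _coronal_field(u, pts, magnitude, side)
        lm_pts = lm_pts + _coronal_field(lm_dirs, lm_pts, magnitude, side)
    elif class_label == "sagittal":
        s = _sagittal_scale(magnitude)
        pts = pts * s
        lm_pts = lm_pts * s

    pts = pts * size
    lm_pts = lm_pts * size
    if noise > 0:
        pts = pts + rng.normal(0.0, noise, pts.shape)

    lms = LandmarkSet(dict(zip(lm_names, lm_pts)), dict(DEFAULT_LANDMARK_SCHEMA))
    if age_days is None:
        age_days = int(rng.integers(30, 540))
    return Scan(SurfaceMesh(pts, faces), lms, class_label, age_days=age_days)


# per-class deformity magnitude ranges (dimensionless, uniform draws)
DEFAULT_MAGNITUDES = {
    "control": (0.2, 0.4),   # scaled down 10x inside _control_field
    "coronal": (0.25, 0.45),
    "sagittal": (0.2, 0.4),
    "metopic": (0.3, 0.5),
}


@dataclass
class CohortSpec:
    """Conditions of a synthetic study cohort."""

    counts: dict = dc_field(default_factory=lambda: {c: 40 for c in DEFAULT_MAGNITUDES})
    noise: float = 0.5  # mm
    size_range: tuple = (0.9, 1.1)  # age-dependent global scale
    magnitudes: dict = dc_field(default_factory=lambda: dict(DEFAULT_MAGNITUDES))
    face_variation: float = 2.0  # mm
    subdivisions: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be nonnegative")
        if self.noise < 0:
            raise ValueError("noise must be nonnegative")
        for cls, (lo, hi) in self.magnitudes.items():
            if cls != "control" and lo <= 0:
                raise ValueError(f"magnitude range for {cls} must be positive")


def generate_cohort(spec: CohortSpec, out_dir: str | None = None) -> tuple[list[Scan], pd.DataFrame]:
    """Generate a cohort of scans (and optionally write a pipeline-ready
    directory of PLY meshes + landmark CSVs + a labels CSV)."""
    rng = np.random.default_rng(spec.seed)
    scans: list[Scan] = []
    rows = []
    for cls in sorted(spec.counts):
        lo, hi = spec.magnitudes[cls]
        for j in range(spec.counts[cls]):
            mag = float(rng.uniform(lo, hi))
            size = float(rng.uniform(*spec.size_range))
            child_seed = int(rng.integers(0, 2**31 - 1))
            scan = generate_head(
                cls, magnitude=mag, size=size, noise=spec.noise,
                seed=child_seed, subdivisions=spec.subdivisions,
                face_variation=spec.face_variation,
            )
            scans.append(scan)
            rows.append(
                {"scan_id": f"{cls}_{j:03d}", "label": cls, "magnitude": mag,
                 "size": size, "age_days": scan.age_days, "seed": child_seed}
            )
    table = pd.DataFrame(rows)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for row, scan in zip(rows, scans):
            write_mesh(scan.mesh, os.path.join(out_dir, row["scan_id"] + ".ply"))
            write_landmarks(scan.landmarks, os.path.join(out_dir, row["scan_id"] + "_landmarks.csv"))
        table.to_csv(os.path.join(out_dir, "labels.csv"), index=False)
    return scans, table


def default_cranial_mask(template: HeadTemplate, z_fraction: float = 0.15) -> np.ndarray:
    """Template vertex indices of the cranial region: everything above
    a horizontal plane at z = z_fraction * (max z), i.e. above the
    eye/ear level, removing the influence of the face."""
    z = template.mesh.vertices[:, 2]
    return np.flatnonzero(z > z_fraction * z.max())
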