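"""Weighted-PCA point distribution model of head shape.

The model follows the classical PDM construction: corresponded meshes
are rigidly aligned by generalized Procrustes analysis (rotation and
translation only -- scale is kept as an attribute of shape, since
deformity features covary with age and head size), vectorized into an
observation matrix ``X_obs`` of shape (3p, n), centred, and decomposed
by weighted PCA.  The weighting is an area mass matrix ``M3`` so that
surface regions contribute by area rather than vertex density.  The
decomposition goes through the n x n weighted Gram matrix

    G_W = X_zm^T M3 X_zm = U_G Lambda_G U_G^T,

from which the principal components ``V = X_zm U_G Lambda_G^{-1/2}``
(M3-orthonormal) and the covariance eigenvalues
``Lambda = Lambda_G / (n - 1)`` follow.  A shape is synthesized from
standardized coefficients ``alpha`` as ``x = mean + V Lambda^{1/2} alpha``.

Usage mirrors statsmodels: build a :class:`PointDistributionModel` from
data, call :meth:`~PointDistributionModel.fit`, and work with the
returned :class:`ShapeModelResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import scipy.sparse as sp

from .mesh import MassMatrix, SurfaceMesh, compute_mass_matrix, extract_cranial_submesh, stretch_mass_matrix

__all__ = [
    "PointDistributionModel",
    "ShapeModelResults",
    "generalized_procrustes_rigid",
    "center_observations",
    "build_wpca_basis",
    "rigid_align",
    "load_model",
]

MODEL_FORMAT_VERSION = "1"


def _as_shape_array(shapes) -> np.ndarray:
    """Normalize input to an (n, p, 3) array of corresponded shapes."""
    if isinstance(shapes, np.ndarray) and shapes.ndim == 3:
        return np.asarray(shapes, float)
    arrs = []
    faces = None
    for s in shapes:
        if isinstance(s, SurfaceMesh):
            if faces is None:
                faces = s.faces
            elif s.faces.shape != faces.shape or not np.array_equal(s.faces, faces):
                raise ValueError("meshes do not share template topology")
            arrs.append(s.vertices)
        else:
            arrs.append(np.asarray(s, float))
    return np.stack(arrs)


def rigid_align(points: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rigidly align (rotation + translation, no scaling) `points` onto
    `reference` in the least-squares sense (Kabsch)."""
    mu_p, mu_r = points.mean(0), reference.mean(0)
    P, R0 = points - mu_p, reference - mu_r
    U, _, Vt = np.linalg.svd(R0.T @ P)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    return P @ R.T + mu_r


def generalized_procrustes_rigid(
    shapes, tol: float = 1e-7, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Rigid generalized Procrustes alignment of corresponded shapes.

    Iteratively aligns every shape to the evolving mean (Euclidean
    Procrustes distance) until the relative mean-shape change falls
    below `tol`.  Scale is untouched.  Returns (aligned (n, p, 3),
    mean shape (p, 3)).
    """
    X = _as_shape_array(shapes).copy()
    if len(X) < 1:
        raise ValueError("need at least one shape")
    mean = X[0].copy()
    for _ in range(max_iter):
        X = np.stack([rigid_align(x, mean) for x in X])
        new_mean = X.mean(axis=0)
        change = np.linalg.norm(new_mean - mean) / max(np.linalg.norm(mean), 1e-300)
        mean = new_mean
        if change < tol:
            break
    return X, mean


def center_observations(X_obs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the row-mean shape from a (3p, n) observation matrix."""
    X_obs = np.asarray(X_obs, float)
    if X_obs.ndim != 2 or X_obs.shape[1] < 2:
        raise ValueError("observation matrix must be (3p, n) with n >= 2")
    mean = X_obs.mean(axis=1)
    return X_obs - mean[:, None], mean


def build_wpca_basis(
    X_zm: np.ndarray, M3, rank_cutoff: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted-PCA basis via the dual (Gram-matrix) eigenproblem.

    Parameters
    ----------
    X_zm : (3p, n) centred observation matrix.
    M3 : (3p, 3p) sparse/dense symmetric area weighting.
    rank_cutoff : eigenvalues of the Gram matrix below
        ``rank_cutoff * lambda_1`` (including any numerically negative
        ones) are treated as zero and dropped.

    Returns (V, lam): M3-orthonormal components (3p, m) and covariance
    eigenvalues lam = lam_G / (n - 1), descending.  Components carry a
    deterministic sign (largest-magnitude entry positive).
    """
    X_zm = np.asarray(X_zm, float)
    n = X_zm.shape[1]
    if n < 2:
        raise ValueError("need n >= 2 observations")
    if sp.issparse(M3):
        if M3.shape != (X_zm.shape[0], X_zm.shape[0]):
            raise ValueError("M3 has wrong shape")
        MX = M3 @ X_zm
    else:
        M3 = np.asarray(M3, float)
        if M3.shape != (X_zm.shape[0], X_zm.shape[0]):
            raise ValueError("M3 has wrong shape")
        MX = M3 @ X_zm
    G = X_zm.T @ MX
    G = 0.5 * (G + G.T)
    if not np.any(np.abs(G) > 0):
        raise ValueError("observations have zero weighted variance")
    lam_G, U = np.linalg.eigh(G)
    lam_G, U = lam_G[::-1], U[:, ::-1]
    keep = lam_G > rank_cutoff * lam_G[0]
    lam_G, U = lam_G[keep], U[:, keep]
    V = X_zm @ (U / np.sqrt(lam_G))
    # deterministic sign: largest-|entry| of each component positive
    flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(V.shape[1])])
    flip[flip == 0] = 1.0
    V *= flip
    return V, lam_G / (n - 1)


@dataclass
class PointDistributionModel:
    """Weighted-PCA shape model specification (fit with :meth:`fit`).

    Parameters
    ----------
    shapes : (n, p, 3) array or list of corresponded SurfaceMesh
    faces : (t, 3) template face array (taken from meshes if omitted)
    mass : MassMatrix, p x p sparse, or None (computed on the GPA mean)
    labels : optional class label per observation
    mirrored : optional boolean flags per observation
    align : run rigid GPA before decomposition (default True)
    """

    shapes: object
    faces: np.ndarray | None = None
    mass: object = None
    labels: np.ndarray | None = None
    mirrored: np.ndarray | None = None
    align: bool = True

    def __post_init__(self) -> None:
        if self.faces is None:
            first = self.shapes[0] if not isinstance(self.shapes, np.ndarray) else None
            if isinstance(first, SurfaceMesh):
                self.faces = first.faces
            else:
                raise ValueError("faces required unless shapes are SurfaceMesh objects")
        self.faces = np.asarray(self.faces, np.int64)
        self._X = _as_shape_array(self.shapes)
        n = len(self._X)
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != n:
                raise ValueError("labels length mismatch")
        if self.mirrored is not None:
            self.mirrored = np.asarray(self.mirrored, bool)

    def fit(self, rank_cutoff: float = 1e-10) -> "ShapeModelResults":
        X = self._X
        if self.align:
            X, mean_shape = generalized_procrustes_rigid(X)
        else:
            mean_shape = X.mean(axis=0)
        n, p, _ = X.shape
        mass = self.mass
        if mass is None:
            mass = compute_mass_matrix(SurfaceMesh(mean_shape, self.faces))
        if isinstance(mass, MassMatrix):
            M = mass.M
        else:
            M = sp.csr_matrix(mass)
        if M.shape != (p, p):
            raise ValueError(f"mass matrix is {M.shape}, expected {(p, p)}")
        M3 = stretch_mass_matrix(M)
        X_obs = X.reshape(n, 3 * p).T  # columns = vectorized shapes
        X_zm, mean = center_observations(X_obs)
        V, lam = build_wpca_basis(X_zm, M3, rank_cutoff=rank_cutoff)
        return ShapeModelResults(
            mean=mean,
            components=V,
            eigenvalues=lam,
            mass=MassMatrix(M),
            faces=self.faces,
            labels=None if self.labels is None else self.labels.copy(),
            mirrored=None if self.mirrored is None else self.mirrored.copy(),
            aligned_shapes=X,
        )


@dataclass
class ShapeModelResults:
    """Fitted weighted-PCA point distribution model.

    Attributes
    ----------
    mean : (3p,) mean shape, xyz-interleaved
    components : (3p, m) M3-orthonormal principal components
    eigenvalues : (m,) covariance eigenvalues, descending (mm^2)
    mass : MassMatrix on the template topology
    faces : template faces
    aligned_shapes : (n, p, 3) GPA-aligned training shapes
    """

    mean: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    mass: MassMatrix
    faces: np.ndarray
    labels: np.ndarray | None = None
    mirrored: np.ndarray | None = None
    aligned_shapes: np.ndarray | None = None
    _M3: object = field(default=None, repr=False)

    # -- basic properties ---------------------------------------------------
    @property
    def rank(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_vertices(self) -> int:
        return self.mean.size // 3

    @property
    def n_train(self) -> int:
        return 0 if self.aligned_shapes is None else len(self.aligned_shapes)

    @property
    def M3(self):
        if self._M3 is None:
            self._M3 = self.mass.M3
        return self._M3

    @property
    def mean_mesh(self) -> SurfaceMesh:
        return SurfaceMesh(self.mean.reshape(-1, 3), self.faces)

    # -- synthesis / analysis ----------------------------------------------
    def synthesize(self, alpha, as_mesh: bool = False):
        """Shape from standardized coefficients: mean + V diag(sqrt(lam)) alpha.

        Shorter coefficient vectors are zero-padded (truncated model)."""
        alpha = np.asarray(alpha, float).reshape(-1)
        if alpha.size > self.rank:
            raise ValueError(f"alpha has {alpha.size} entries; model rank is {self.rank}")
        m = alpha.size
        x = self.mean + self.components[:, :m] @ (np.sqrt(self.eigenvalues[:m]) * alpha)
        if as_mesh:
            return SurfaceMesh(x.reshape(-1, 3), self.faces)
        return x

    def project(self, x, n_components: int | None = None) -> np.ndarray:
        """Standardized coefficients of a shape (assumed aligned to the
        model frame): alpha = Lambda^{-1/2} V^T M3 (x - mean)."""
        x = np.asarray(x, float).reshape(-1)
        m = self.rank if n_components is None else int(n_components)
        if not 1 <= m <= self.rank:
            raise ValueError("n_components out of range")
        lam = self.eigenvalues[:m]
        if np.any(lam <= 0):
            raise ValueError("zero eigenvalue in requested component range")
        b = self.components[:, :m].T @ (self.M3 @ (x - self.mean))
        return b / np.sqrt(lam)

    def align_to_model(self, points: np.ndarray) -> np.ndarray:
        """Rigidly align a (p, 3) shape to the model mean (model frame)."""
        return rigid_align(np.asarray(points, float), self.mean.reshape(-1, 3))

    def project_mesh(self, points: np.ndarray, n_components: int | None = None) -> np.ndarray:
        """Align a corresponded (p, 3) shape to the model frame, then project."""
        return self.project(self.align_to_model(points).reshape(-1), n_components)

    def sample(self, n: int, seed: int | None = None, n_components: int | None = None) -> np.ndarray:
        """Draw n Gaussian instances; returns (n, p, 3). Reproducible per seed."""
        if n < 1:
            raise ValueError("n must be >= 1")
        m = self.rank if n_components is None else int(n_components)
        rng = np.random.default_rng(seed)
        alphas = rng.standard_normal((n, m))
        out = np.stack([self.synthesize(a) for a in alphas])
        return out.reshape(n, -1, 3)

    def compactness(self, m: int) -> float:
        """Cumulative variance fraction captured by the first m components."""
        if not 1 <= m <= self.rank:
            raise ValueError(f"m must be in [1, {self.rank}]")
        lam = self.eigenvalues
        return float(lam[:m].sum() / lam.sum())

    # -- reporting ----------------------------------------------------------
    def summary(self, n_show: int = 10) -> str:
        lam = self.eigenvalues
        lines = [
            "Weighted-PCA Point Distribution Model",
            "=" * 53,
            f"{'Vertices (p)':<30}{self.n_vertices:>23}",
            f"{'Training shapes (n)':<30}{self.n_train:>23}",
            f"{'Rank (m)':<30}{self.rank:>23}",
            f"{'Total variance (mm^4)':<30}{lam.sum():>23.4g}",
            f"{'Surface area of mean (mm^2)':<30}{self.mass.total_weight():>23.4g}",
            "-" * 53,
            f"{'mode':>6}{'eigenvalue':>16}{'var %':>10}{'cum %':>10}",
        ]
        cum = np.cumsum(lam) / lam.sum()
        for k in range(min(n_show, self.rank)):
            lines.append(f"{k + 1:>6}{lam[k]:>16.5g}{100 * lam[k] / lam.sum():>10.2f}{100 * cum[k]:>10.2f}")
        if self.labels is not None:
            vals, counts = np.unique(self.labels, return_counts=True)
            lines.append("-" * 53)
            lines.append("classes: " + ", ".join(f"{v}={c}" for v, c in zip(vals, counts)))
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        """Write the model to HDF5 (datasets mean/components/eigenvalues/
        faces + sparse mass matrix in COO form)."""
        Mcoo = self.mass.M.tocoo()
        with h5py.File(path, "w") as f:
            f.attrs["format_version"] = MODEL_FORMAT_VERSION
            f.attrs["generator"] = "cranioshape"
            f.create_dataset("mean", data=self.mean)
            f.create_dataset("components", data=self.components)
            f.create_dataset("eigenvalues", data=self.eigenvalues)
            f.create_dataset("faces", data=self.faces)
            f.create_dataset("mass_row", data=Mcoo.row)
            f.create_dataset("mass_col", data=Mcoo.col)
            f.create_dataset("mass_val", data=Mcoo.data)
            f.attrs["n_vertices"] = self.n_vertices
            if self.labels is not None:
                f.create_dataset("labels", data=np.asarray(self.labels, dtype="S"))
            if self.mirrored is not None:
                f.create_dataset("mirrored", data=self.mirrored)
            if self.aligned_shapes is not None:
                f.create_dataset("aligned_shapes", data=self.aligned_shapes)


def load_model(path) -> ShapeModelResults:
    with h5py.File(path, "r") as f:
        p = int(f.attrs["n_vertices"])
        M = sp.coo_matrix((f["mass_val"][:], (f["mass_row"][:], f["mass_col"][:])), shape=(p, p)).tocsr()
        return ShapeModelResults(
            mean=f["mean"][:],
            components=f["components"][:],
            eigenvalues=f["eigenvalues"][:],
            mass=MassMatrix(M),
            faces=f["faces"][:],
            labels=f["labels"][:].astype(str) if "labels" in f else None,
            mirrored=f["mirrored"][:].astype(bool) if "mirrored" in f else None,
            aligned_shapes=f["aligned_shapes"][:] if "aligned_shapes" in f else None,
        )


def fit_submodels(
    shapes,
    labels,
    faces: np.ndarray | None = None,
    cranial_mask: np.ndarray | None = None,
    mirrored: np.ndarray | None = None,
) -> dict[str, ShapeModelResults]:
    """Class-specific submodels plus an optional cranium-only model.

    Each submodel runs its own GPA and uses a mass matrix computed on
    its own mean (sub)mesh.  The cranial model (key ``"cranial"``) is
    built from the cranial submesh coordinates of *all* observations.
    """
    X = _as_shape_array(shapes)
    labels = np.asarray(labels)
    if faces is None:
        first = shapes[0]
        if not isinstance(first, SurfaceMesh):
            raise ValueError("faces required unless shapes are SurfaceMesh objects")
        faces = first.faces
    out: dict[str, ShapeModelResults] = {}
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has {idx.size} observation(s); need >= 2")
        out[str(cls)] = PointDistributionModel(
            X[idx], faces=faces, labels=labels[idx],
            mirrored=None if mirrored is None else mirrored[idx],
        ).fit()
    if cranial_mask is not None:
        submesh, idx_map = extract_cranial_submesh(SurfaceMesh(X[0], faces), cranial_mask)
        out["cranial"] = PointDistributionModel(
            X[:, idx_map, :], faces=submesh.faces, labels=labels, mirrored=mirrored
        ).fit()
    return out
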