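import numpy as np
import pytest
import scipy.sparse as sp

from cranioshape.mesh import MassMatrix, SurfaceMesh
from cranioshape.model import (
    PointDistributionModel,
    build_wpca_basis,
    center_observations,
    fit_submodels,
    generalized_procrustes_rigid,
    load_model,
)


def _random_rigid(rng):
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q, rng.normal(size=3) * 30


class TestGPA:
    def test_identical_copies_zero_variance(self, corresponded_shapes):
        X, _ = corresponded_shapes
        copies = np.stack([X[0]] * 5)
        aligned, mean = generalized_procrustes_rigid(copies)
        assert np.abs(aligned - mean[None]).max() < 1e-9

    def test_rigid_recoverable_set(self, corresponded_shapes):
        X, _ = corresponded_shapes
        rng = np.random.default_rng(0)
        copies = []
        for _ in range(6):
            R, t = _random_rigid(rng)
            copies.append(X[0] @ R.T + t)
        aligned, _ = generalized_procrustes_rigid(np.stack(copies))
        for i in range(1, 6):
            rmsd = np.sqrt(((aligned[i] - aligned[0]) ** 2).sum(axis=1).mean())
            assert rmsd < 1e-6

    def test_centroid_size_preserved(self, corresponded_shapes):
        """Rigid alignment must not rescale any shape."""
        X, _ = corresponded_shapes
        aligned, _ = generalized_procrustes_rigid(X)
        for before, after in zip(X, aligned):
            s0 = np.linalg.norm(before - before.mean(0))
            s1 = np.linalg.norm(after - after.mean(0))
            assert s1 == pytest.approx(s0, rel=1e-9)

    def test_topology_mismatch_error(self, corresponded_shapes):
        X, _ = corresponded_shapes
        meshes = [SurfaceMesh(X[0], np.array([[0, 1, 2]])), SurfaceMesh(X[1], np.array([[0, 2, 1]]))]
        with pytest.raises(ValueError, match="topology"):
            generalized_procrustes_rigid(meshes)


class TestCentering:
    def test_two_columns(self):
        a, b = np.array([1.0, 2, 3]), np.array([3.0, 2, 5])
        X = np.column_stack([a, b])
        Xzm, mean = center_observations(X)
        assert np.allclose(mean, (a + b) / 2)
        assert np.allclose(Xzm[:, 0], (a - b) / 2)
        assert np.allclose(Xzm[:, 1], (b - a) / 2)

    def test_idempotent_and_zero_row_means(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 7))
        Xzm, _ = center_observations(X)
        assert np.abs(Xzm.mean(axis=1)).max() < 1e-12
        Xzm2, mean2 = center_observations(Xzm)
        assert np.allclose(Xzm2, Xzm)
        assert np.abs(mean2).max() < 1e-12


class TestWPCA:
    def test_identity_weight_reduces_to_pca(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(36, 5))
        Xzm, _ = center_observations(X)
        V, lam = build_wpca_basis(Xzm, np.eye(36))
        U, s, _ = np.linalg.svd(Xzm, full_matrices=False)
        lam_oracle = (s**2) / 4
        assert np.abs(lam - lam_oracle[: len(lam)]).max() < 1e-8
        for k in range(len(lam)):
            assert abs(abs(V[:, k] @ U[:, k]) - 1) < 1e-8

    def test_centered_data_drops_zero_eigenvalue(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(36, 5))
        Xzm, _ = center_observations(X)
        G = Xzm.T @ Xzm
        ev = np.linalg.eigvalsh(G)
        assert ev[0] <= 1e-10 * ev[-1]  # smallest Gram eigenvalue ~ 0
        _, lam = build_wpca_basis(Xzm, np.eye(36))
        assert len(lam) == 4  # n - 1: zero mode omitted

    def test_gram_route_matches_direct_weighted_covariance(self):
        """5 shapes x 12 points, random positive diagonal weights: the
        n x n dual route equals the 36 x 36 primal eigenproblem."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(36, 5))
        Xzm, _ = center_observations(X)
        d = rng.uniform(0.5, 2.0, 36)
        V, lam = build_wpca_basis(Xzm, np.diag(d))
        C = Xzm @ Xzm.T / 4
        W = np.diag(np.sqrt(d))
        lam_oracle = np.linalg.eigvalsh(W @ C @ W)[::-1]
        assert np.abs(lam - lam_oracle[: len(lam)]).max() < 1e-8
        M3 = np.diag(d)
        assert np.abs(V.T @ M3 @ V - np.eye(len(lam))).max() < 1e-8

    def test_all_zero_data_is_error(self):
        with pytest.raises(ValueError):
            build_wpca_basis(np.zeros((6, 3)), np.eye(6))

    def test_wrong_mass_shape_is_error(self):
        with pytest.raises(ValueError):
            build_wpca_basis(np.random.default_rng(0).normal(size=(6, 3)), np.eye(5))


@pytest.fixture(scope="module")
def fitted(corresponded_shapes):
    X, faces = corresponded_shapes
    return PointDistributionModel(X, faces=faces).fit()


class TestResults:
    def test_zero_alpha_gives_mean(self, fitted):
        assert np.allclose(fitted.synthesize(np.zeros(fitted.rank)), fitted.mean)

    def test_project_mean_is_zero(self, fitted):
        assert np.abs(fitted.project(fitted.mean)).max() < 1e-8

    def test_linearity(self, fitted):
        rng = np.random.default_rng(5)
        a1, a2 = rng.normal(size=(2, fitted.rank))
        lhs = fitted.synthesize(a1 + a2) - fitted.mean
        rhs = (fitted.synthesize(a1) - fitted.mean) + (fitted.synthesize(a2) - fitted.mean)
        assert np.abs(lhs - rhs).max() < 1e-9

    def test_projection_left_inverse(self, fitted):
        rng = np.random.default_rng(6)
        alpha = rng.normal(size=fitted.rank)
        back = fitted.project(fitted.synthesize(alpha))
        assert np.abs(back - alpha).max() < 1e-6

    def test_training_shape_roundtrip(self, fitted):
        x = fitted.aligned_shapes[2].reshape(-1)
        rec = fitted.synthesize(fitted.project(x))
        assert np.abs(rec - x).max() / np.abs(x).max() < 1e-6

    def test_truncated_projection_is_optimal(self, fitted):
        """The m-term projection minimizes M3-weighted reconstruction
        error over all m-coefficient choices (checked vs perturbations)."""
        x = fitted.aligned_shapes[1].reshape(-1)
        m = 2
        alpha_opt = fitted.project(x, n_components=m)

        def werr(alpha):
            r = fitted.synthesize(alpha) - x
            return float(r @ (fitted.M3 @ r))

        e_opt = werr(alpha_opt)
        rng = np.random.default_rng(7)
        for _ in range(20):
            assert e_opt <= werr(alpha_opt + rng.normal(size=m) * 0.5) + 1e-12

    def test_alpha_too_long_is_error(self, fitted):
        with pytest.raises(ValueError):
            fitted.synthesize(np.zeros(fitted.rank + 1))

    def test_energy_conservation(self, fitted):
        """Sum of eigenvalues equals total M3-weighted variance."""
        X = fitted.aligned_shapes.reshape(fitted.n_train, -1).T
        Xzm, _ = center_observations(X)
        total = np.trace(Xzm.T @ (fitted.M3 @ Xzm)) / (fitted.n_train - 1)
        assert fitted.eigenvalues.sum() == pytest.approx(total, rel=1e-8)

    def test_reconstruction_error_monotone_in_m(self, fitted):
        x = fitted.aligned_shapes[0].reshape(-1)
        errs = []
        for m in range(1, fitted.rank + 1):
            alpha = fitted.project(x, n_components=m)
            errs.append(np.linalg.norm(fitted.synthesize(alpha) - x))
        assert all(e2 <= e1 + 1e-9 for e1, e2 in zip(errs, errs[1:]))

    def test_deterministic_build(self, corresponded_shapes):
        X, faces = corresponded_shapes
        r1 = PointDistributionModel(X, faces=faces).fit()
        r2 = PointDistributionModel(X, faces=faces).fit()
        assert np.array_equal(r1.components, r2.components)
        assert np.array_equal(r1.eigenvalues, r2.eigenvalues)

    def test_summary_smoke(self, fitted):
        s = fitted.summary()
        assert "Weighted-PCA" in s and "eigenvalue" in s


class TestSampling:
    def test_seed_determinism(self, fitted):
        s1 = fitted.sample(5, seed=42)
        s2 = fitted.sample(5, seed=42)
        assert np.array_equal(s1, s2)

    def test_sample_statistics(self, fitted):
        """Projected samples have ~zero mean and variance ~ lambda_k."""
        n = 10_000
        samples = fitted.sample(n, seed=0)
        alphas = np.stack([fitted.project(s.reshape(-1)) for s in samples])
        se = 1.0 / np.sqrt(n)
        assert np.abs(alphas.mean(axis=0)).max() < 3 * se * 1.5
        assert np.allclose(alphas.var(axis=0), 1.0, atol=0.1)


class TestSubmodels:
    def test_single_class_equals_full(self, corresponded_shapes):
        X, faces = corresponded_shapes
        labels = np.array(["control"] * len(X))
        subs = fit_submodels(X, labels, faces=faces)
        full = PointDistributionModel(X, faces=faces).fit()
        assert np.allclose(subs["control"].eigenvalues, full.eigenvalues)

    def test_two_disjoint_classes_means(self, corresponded_shapes):
        X, faces = corresponded_shapes
        labels = np.array(["a"] * 4 + ["b"] * 4)
        subs = fit_submodels(X, labels, faces=faces)
        for cls, idx in (("a", slice(0, 4)), ("b", slice(4, 8))):
            gpa_mean = generalized_procrustes_rigid(X[idx])[1]
            assert np.allclose(subs[cls].mean.reshape(-1, 3), gpa_mean, atol=1e-6)

    def test_small_class_error_names_class(self, corresponded_shapes):
        X, faces = corresponded_shapes
        labels = np.array(["a"] * 7 + ["rare"])
        with pytest.raises(ValueError, match="rare"):
            fit_submodels(X, labels, faces=faces)

    def test_cranial_model_dimension(self, corresponded_shapes, template2):
        X, faces = corresponded_shapes
        labels = np.array(["a"] * 4 + ["b"] * 4)
        mask = np.flatnonzero(template2.mesh.vertices[:, 2] > 0)
        subs = fit_submodels(X, labels, faces=faces, cranial_mask=mask)
        assert subs["cranial"].mean.size == 3 * len(mask)


def test_hdf5_roundtrip(tmp_path, fitted):
    path = tmp_path / "model.h5"
    fitted.save(path)
    back = load_model(path)
    assert np.array_equal(back.mean, fitted.mean)
    assert np.array_equal(back.components, fitted.components)
    assert np.array_equal(back.eigenvalues, fitted.eigenvalues)
    assert np.array_equal(back.faces, fitted.faces)
    assert (back.mass.M != fitted.mass.M).nnz == 0
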