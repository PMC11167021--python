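"""PCA reduction, mixture fitting, assignment, projection, sub-splitting."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import multivariate_normal
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

from phageselect import (
    assign_clusters,
    fit_gmm,
    project_2d,
    reduce_pca,
    subsplit_cluster,
)


def two_blobs(n=200, sep=12.0, d=5, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n // 2, d))
    b = rng.normal(sep, 1.0, size=(n - n // 2, d))
    X = np.vstack([a, b])
    labels = np.repeat([0, 1], [n // 2, n - n // 2])
    return X, labels


class TestReducePCA:
    def test_low_rank_data_reconstructs_exactly(self):
        rng = np.random.default_rng(1)
        basis = rng.normal(size=(4, 30))
        X = rng.normal(size=(100, 4)) @ basis  # exact rank 4
        reduced, red = reduce_pca(X, target_dim=4, standardize=False)
        recon = reduced @ red.basis.T * red.scale + red.mean
        assert np.allclose(recon, X, atol=1e-8)

    def test_full_dimension_is_distance_preserving_rotation(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 6))
        reduced, red = reduce_pca(X, target_dim=6, standardize=False)
        assert np.allclose(red.basis.T @ red.basis, np.eye(6), atol=1e-8)
        d_orig = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        d_red = np.linalg.norm(reduced[:, None] - reduced[None, :], axis=2)
        assert np.allclose(d_orig, d_red, atol=1e-8)

    def test_explained_variance_matches_eigendecomposition(self):
        """Direct covariance eigenvalues are the independent oracle for the
        per-component explained variance (non-increasing by construction)."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 10)) * np.arange(1, 11)
        _, red = reduce_pca(X, target_dim=8, standardize=False)
        ev = red.explained_variance
        assert (np.diff(ev) <= 1e-10).all()
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
        assert np.allclose(ev, eigvals[:8], rtol=1e-8)

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 7))
        _, r1 = reduce_pca(X, target_dim=5)
        _, r2 = reduce_pca(X.copy(), target_dim=5)
        assert np.array_equal(r1.basis, r2.basis)
        for j in range(r1.basis.shape[1]):
            i = np.argmax(np.abs(r1.basis[:, j]))
            assert r1.basis[i, j] > 0

    def test_requires_more_samples_than_components(self):
        with pytest.raises(ValueError):
            reduce_pca(np.zeros((10, 30)), target_dim=20)


class TestFitGMM:
    def test_separated_blobs_recovered_with_full_purity(self):
        X, truth = two_blobs()
        model = fit_gmm(X, 2, seed=0)
        labels, _ = assign_clusters(model, X)
        purity = max(
            (labels == truth).mean(), (labels == 1 - truth).mean()
        )
        assert purity == 1.0

    def test_single_component_mean_is_data_mean(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 3))
        model = fit_gmm(X, 1, seed=0)
        assert np.allclose(model.means[0], X.mean(axis=0), atol=1e-8)
        assert model.weights[0] == pytest.approx(1.0)

    def test_log_likelihood_trace_monotone(self):
        X, _ = two_blobs(sep=2.0, seed=6)
        model = fit_gmm(X, 4, seed=1)
        diffs = np.diff(model.log_likelihoods)
        assert (diffs >= -1e-9).all()

    def test_weights_and_covariances_valid(self):
        X, _ = two_blobs(seed=7)
        model = fit_gmm(X, 3, seed=2)
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert (model.covariances > 0).all()

    def test_more_components_than_points_rejected(self):
        with pytest.raises(ValueError):
            fit_gmm(np.zeros((5, 2)), 6)

    def test_comparable_fit_to_reference_mixture_implementation(self):
        """Final average log-likelihood on separable data matches an
        independent EM implementation (scikit-learn) closely."""
        X, _ = two_blobs(n=400, sep=6.0, seed=8)
        model = fit_gmm(X, 2, seed=3)
        ref = GaussianMixture(
            n_components=2, covariance_type="diag", random_state=3, n_init=3
        ).fit(X)
        assert model.log_likelihoods[-1] == pytest.approx(
            ref.score(X), abs=0.01
        )


class TestAssignClusters:
    def test_component_mean_assigned_to_own_cluster(self):
        X, _ = two_blobs(seed=9)
        model = fit_gmm(X, 2, seed=0)
        labels, _ = assign_clusters(model, model.means)
        assert list(labels) == [0, 1]

    def test_responsibilities_row_normalize(self):
        X, _ = two_blobs(sep=1.5, seed=10)
        model = fit_gmm(X, 3, seed=1)
        _, resp = assign_clusters(model, X)
        assert np.allclose(resp.sum(axis=1), 1.0, atol=1e-9)

    def test_agreement_with_direct_density_oracle(self):
        """Responsibilities equal weighted Gaussian densities normalized
        per row, evaluated directly with scipy on 10 points."""
        X, _ = two_blobs(sep=3.0, seed=11)
        model = fit_gmm(X, 3, seed=2)
        pts = X[:10]
        dens = np.column_stack(
            [
                model.weights[k]
                * multivariate_normal.pdf(
                    pts, mean=model.means[k], cov=np.diag(model.covariances[k])
                )
                for k in range(3)
            ]
        )
        expected = dens / dens.sum(axis=1, keepdims=True)
        _, resp = assign_clusters(model, pts)
        assert np.allclose(resp, expected, atol=1e-8)


class TestProject2D:
    def test_same_seed_identical_coordinates(self):
        X, _ = two_blobs(n=60, seed=12)
        a = project_2d(X, seed=4)
        b = project_2d(X, seed=4)
        assert np.array_equal(a, b)
        assert a.shape == (60, 2)

    def test_three_collinear_points_project(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        coords = project_2d(X, seed=0)
        assert coords.shape == (3, 2)

    def test_separated_clusters_stay_separated(self):
        X, truth = two_blobs(n=120, sep=15.0, seed=13)
        coords = project_2d(X, seed=5)
        assert silhouette_score(coords, truth) > 0


class TestSubsplit:
    def test_bimodal_cluster_splits_with_full_purity(self):
        X, truth = two_blobs(n=120, sep=10.0, seed=14)
        parent = fit_gmm(X, 1, seed=0)
        labels, _ = assign_clusters(parent, X)
        new_labels, sub = subsplit_cluster(parent, X, labels, 0, k2=2, seed=1)
        assert set(new_labels) == {"0-1", "0-2"}
        side_a = new_labels[truth == 0]
        assert len(set(side_a)) == 1
        assert len(set(new_labels[truth == 1])) == 1
        assert sub is not None

    def test_k2_of_one_is_identity_relabeling(self):
        X, _ = two_blobs(n=40, seed=15)
        model = fit_gmm(X, 2, seed=0)
        labels, _ = assign_clusters(model, X)
        new_labels, sub = subsplit_cluster(model, X, labels, 0, k2=1)
        assert sub is None
        assert list(new_labels) == [str(x) for x in labels]

    def test_too_few_members_rejected(self):
        X, _ = two_blobs(n=20, seed=16)
        model = fit_gmm(X, 1, seed=0)
        labels, _ = assign_clusters(model, X)
        with pytest.raises(ValueError):
            subsplit_cluster(model, X, labels, 0, k2=15)
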