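"""Dimensionality reduction, Gaussian-mixture clustering, 2-D projection.

The clustering stage mirrors the embedding-space analysis of selection
pools: embeddings are reduced to 20 principal components and clustered
with a diagonal-covariance Gaussian mixture (20 components for the
pooled global analysis, 10 per sample), with a stochastic
neighbor-embedding projection for visualization only.

The EM fit is implemented here (k-means seeded initialization, fixed
iteration cap, log-likelihood tolerance) so that the per-iteration
log-likelihood trace is available and asserted non-decreasing on every
fit — the defining EM guarantee.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

DEFAULT_REDUCED_DIM = 20
GLOBAL_K = 20
PER_SAMPLE_K = 10


@dataclass(frozen=True)
class PCAReduction:
    """A fitted (optionally standardized) PCA basis d -> k.

    ``basis`` columns are orthonormal principal axes with a fixed sign
    convention (largest-magnitude loading positive), so the reduction is
    deterministic.
    """

    mean: np.ndarray  # (d,)
    scale: np.ndarray  # (d,) column std (ones if not standardized)
    basis: np.ndarray  # (d, k) orthonormal columns
    explained_variance: np.ndarray  # (k,)

    @property
    def target_dim(self) -> int:
        return int(self.basis.shape[1])

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        matrix = np.asarray(matrix, float)
        return ((matrix - self.mean) / self.scale) @ self.basis


def reduce_pca(
    matrix: np.ndarray,
    target_dim: int = DEFAULT_REDUCED_DIM,
    standardize: bool = False,
) -> tuple[np.ndarray, PCAReduction]:
    """Project onto the top ``target_dim`` principal axes.

    Columns are centered before the eigendecomposition (the embedder is
    responsible for feature-scale balance; ``standardize=True`` optionally
    z-scores columns instead). Component signs follow the convention that
    the largest-|loading| entry of each axis is positive.
    """
    X = np.asarray(matrix, dtype=float)
    n, d = X.shape
    if n <= target_dim:
        raise ValueError(f"need more samples ({n}) than target_dim ({target_dim})")
    target_dim = min(target_dim, d)
    mean = X.mean(axis=0)
    if standardize:
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0  # constant columns carry no signal
    else:
        scale = np.ones(d)
    Z = (X - mean) / scale
    pca = PCA(n_components=target_dim, svd_solver="full")
    pca.fit(Z)
    basis = pca.components_.T.copy()  # (d, k)
    for j in range(basis.shape[1]):
        i = int(np.argmax(np.abs(basis[:, j])))
        if basis[i, j] < 0:
            basis[:, j] = -basis[:, j]
    red = PCAReduction(
        mean=mean,
        scale=scale,
        basis=basis,
        explained_variance=pca.explained_variance_.copy(),
    )
    return red.transform(X), red


@dataclass
class ClusterModel:
    """A fitted diagonal-covariance Gaussian mixture in reduced space."""

    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, d)
    covariances: np.ndarray  # (K, d) diagonal entries
    seed: int | None
    log_likelihoods: list[float] = field(default_factory=list)
    converged: bool = False
    pca: PCAReduction | None = None

    @property
    def n_components(self) -> int:
        return int(self.weights.shape[0])

    def validate(self) -> None:
        assert abs(self.weights.sum() - 1.0) < 1e-9, "weights must sum to 1"
        assert (self.covariances > 0).all(), "covariances must be positive"
        ll = np.array(self.log_likelihoods)
        assert (np.diff(ll) >= -1e-9).all(), "EM log-likelihood decreased"


def _log_gaussian_diag(
    X: np.ndarray, means: np.ndarray, covs: np.ndarray
) -> np.ndarray:
    """(n, K) log N(x_i; mu_k, diag(cov_k))."""
    n, d = X.shape
    log_det = np.sum(np.log(covs), axis=1)  # (K,)
    # squared Mahalanobis distance under diagonal covariance
    quad = (
        np.sum((X**2)[:, None, :] / covs[None, :, :], axis=2)
        - 2.0 * (X / 1.0) @ (means / covs).T
        + np.sum(means**2 / covs, axis=1)[None, :]
    )
    return -0.5 * (d * np.log(2.0 * np.pi) + log_det[None, :] + quad)


def fit_gmm(
    X: np.ndarray,
    n_components: int,
    seed: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-5,
    reg_covar: float = 1e-6,
    pca: PCAReduction | None = None,
) -> ClusterModel:
    """Expectation-maximization fit of a diagonal-covariance mixture.

    Initialization is k-means (seeded); iteration stops at ``max_iter`` or
    when the mean log-likelihood improves by less than ``tol``. The
    recorded log-likelihood trace is checked non-decreasing (EM guarantee)
    before returning.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if n_components > n:
        raise ValueError(f"n_components ({n_components}) > n samples ({n})")
    if n < 10 * n_components:
        warnings.warn(
            f"fitting {n_components} components with only {n} points",
            stacklevel=2,
        )
    km = KMeans(n_clusters=n_components, random_state=seed, n_init=10)
    labels = km.fit_predict(X)
    resp = np.zeros((n, n_components))
    resp[np.arange(n), labels] = 1.0

    lls: list[float] = []
    converged = False
    weights = means = covs = None
    for _ in range(max_iter):
        # M step
        nk = resp.sum(axis=0) + 10 * np.finfo(float).eps
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        covs = (resp.T @ (X**2)) / nk[:, None] - means**2 + reg_covar
        # E step
        log_prob = _log_gaussian_diag(X, means, covs) + np.log(weights)[None, :]
        log_norm = logsumexp(log_prob, axis=1)
        resp = np.exp(log_prob - log_norm[:, None])
        ll = float(log_norm.mean())
        lls.append(ll)
        if len(lls) > 1 and abs(lls[-1] - lls[-2]) < tol:
            converged = True
            break
    model = ClusterModel(
        weights=weights,
        means=means,
        covariances=covs,
        seed=seed,
        log_likelihoods=lls,
        converged=converged,
        pca=pca,
    )
    model.validate()
    return model


def assign_clusters(
    model: ClusterModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels and posterior responsibilities for points in reduced space.

    Responsibilities are the normalized weighted Gaussian densities; the
    hard label is the argmax, ties broken toward the lowest cluster id.
    """
    X = np.asarray(X, dtype=float)
    log_prob = (
        _log_gaussian_diag(X, model.means, model.covariances)
        + np.log(model.weights)[None, :]
    )
    log_norm = logsumexp(log_prob, axis=1)
    resp = np.exp(log_prob - log_norm[:, None])
    labels = np.argmax(resp, axis=1)  # argmax returns first (lowest id) on ties
    return labels, resp


def project_2d(
    X: np.ndarray, seed: int | None = None, perplexity: float = 30.0
) -> np.ndarray:
    """t-SNE projection to 2-D, for visualization output only.

    Absolute coordinates carry no meaning and per-dataset projections of
    the same peptide are never compared numerically; statistics always use
    the reduced space, not these coordinates. Perplexity is capped below
    the sample count so small inputs still project.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points to project")
    eff_perplexity = min(perplexity, max(0.5, (n - 1) / 3.0))
    tsne = TSNE(
        n_components=2,
        perplexity=eff_perplexity,
        random_state=seed,
        init="pca" if X.shape[1] > 1 else "random",
    )
    return tsne.fit_transform(X)


def subsplit_cluster(
    model: ClusterModel,
    X: np.ndarray,
    labels: np.ndarray,
    cluster_id: int,
    k2: int = 2,
    seed: int | None = None,
) -> tuple[np.ndarray, ClusterModel | None]:
    """Refit a mixture within one cluster and suffix its members' labels.

    Returns string labels for all points — unchanged ids elsewhere, and
    e.g. ``"4-1"``/``"4-2"`` inside the split cluster — plus the
    sub-model (None when ``k2 == 1``, which is an identity relabeling).
    """
    labels = np.asarray(labels)
    out = labels.astype(str).astype(object)
    members = np.flatnonzero(labels == cluster_id)
    if k2 == 1:
        return out.astype(str), None
    if len(members) < 2 * k2:
        raise ValueError(
            f"cluster {cluster_id} has {len(members)} members; need >= {2 * k2}"
        )
    sub = fit_gmm(X[members], n_components=k2, seed=seed)
    sub_labels, _ = assign_clusters(sub, X[members])
    for i, sl in zip(members, sub_labels):
        out[i] = f"{cluster_id}-{sl + 1}"
    return out.astype(str), sub
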