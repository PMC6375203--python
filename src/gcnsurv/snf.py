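"""Similarity Network Fusion (SNF) of per-platform patient networks.

Each platform's eigengene features give a patient × patient affinity via
a locally scaled exponential kernel; SNF then cross-diffuses the two
networks: each view's full (row-stochastic) similarity is repeatedly
propagated through the other view's K-nearest-neighbor kernel,

    W̃⁽¹⁾ ← S⁽¹⁾ · W̃⁽²⁾ · S⁽¹⁾ᵀ,   W̃⁽²⁾ ← S⁽²⁾ · W̃⁽¹⁾ · S⁽²⁾ᵀ,

with symmetrization and row re-normalization after every round, and the
fused network is the average of the two states after t rounds.

The full normalization used here puts 1/2 on the diagonal and spreads
the remaining 1/2 over each row's off-diagonal entries; the KNN kernel
normalizes each row's K nearest neighbors to sum 1/2 and zeroes the
rest.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances

__all__ = ["affinity_kernel", "snf_full_normalize", "snf_knn_kernel",
           "snf_fuse", "spectral_cluster", "SimilarityNetworkFusion"]

logger = logging.getLogger(__name__)


def _clamp_K(K: int, n: int) -> int:
    if K >= n:
        warnings.warn(f"K={K} ≥ n_samples={n}; clamping to {n - 1}",
                      stacklevel=3)
        return n - 1
    return K


def affinity_kernel(features, K: int = 30, mu: float = 0.8) -> pd.DataFrame:
    """Locally scaled exponential kernel over per-sample feature vectors.

    W(i,j) = exp(−d²(i,j) / (mu·ε_ij)) with Euclidean distance d and
    ε_ij = (mean distance of i to its K nearest neighbors + the same for
    j + d(i,j)) / 3. Diagonal is 1.

    ``features`` is a samples × features DataFrame (or array).
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if isinstance(features, pd.DataFrame):
        ids = list(features.index)
        X = features.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        ids = list(range(X.shape[0]))
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    K = _clamp_K(K, n)
    D = pairwise_distances(X, metric="euclidean")
    # mean distance to the K nearest other samples
    sortd = np.sort(D, axis=1)  # column 0 is the zero self-distance
    mean_knn = sortd[:, 1:K + 1].mean(axis=1)
    eps = (mean_knn[:, None] + mean_knn[None, :] + D) / 3.0
    eps[eps <= 0] = np.finfo(float).tiny
    W = np.exp(-(D**2) / (mu * eps))
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 1.0)
    return pd.DataFrame(W, index=ids, columns=ids)


def snf_full_normalize(W) -> pd.DataFrame:
    """Full row normalization: 1/2 on the diagonal, off-diagonal entries
    scaled to W_ij / (2 Σ_{k≠i} W_ik); every row sums to exactly 1."""
    A, ids = _as_array(W)
    off = A.copy()
    np.fill_diagonal(off, 0.0)
    rs = off.sum(axis=1)
    if (rs <= 0).any():
        bad = [ids[i] for i in np.flatnonzero(rs <= 0)]
        raise ValueError(f"zero off-diagonal row sum for samples: {bad[:5]}")
    P = off / (2.0 * rs[:, None])
    np.fill_diagonal(P, 0.5)
    return pd.DataFrame(P, index=ids, columns=ids)


def snf_knn_kernel(W, K: int) -> pd.DataFrame:
    """Sparse local kernel: each row keeps its K most similar other
    samples, normalized to sum 1/2; everything else (including the
    diagonal) is zero. Ties at the K-th neighbor break toward the
    smaller sample id."""
    A, ids = _as_array(W)
    n = A.shape[0]
    K = _clamp_K(K, n)
    S = np.zeros_like(A)
    id_rank = np.argsort(np.argsort(np.asarray(ids, dtype=str)))
    for i in range(n):
        cand = [j for j in range(n) if j != i]
        cand.sort(key=lambda j: (-A[i, j], id_rank[j]))
        nbrs = cand[:K]
        total = A[i, nbrs].sum()
        if total <= 0:
            warnings.warn(f"row {ids[i]} has zero similarity to its neighbors",
                          stacklevel=2)
            continue
        S[i, nbrs] = A[i, nbrs] / (2.0 * total)
    return pd.DataFrame(S, index=ids, columns=ids)


def snf_fuse(raw_matrices, K: int = 30, t: int = 20) -> pd.DataFrame:
    """Fuse two raw affinity matrices by t rounds of cross-diffusion.

    Both matrices must share an identical sample-id set (same order).
    Returns the fused patient network (symmetric, nonnegative).
    """
    if len(raw_matrices) != 2:
        raise ValueError("exactly two views are fused")
    if t < 1:
        raise ValueError("iteration count t must be ≥ 1")
    (A1, ids1), (A2, ids2) = (_as_array(m) for m in raw_matrices)
    if list(ids1) != list(ids2):
        raise ValueError("views must share identical sample ids")
    P1 = snf_full_normalize(pd.DataFrame(A1, index=ids1, columns=ids1)).to_numpy()
    P2 = snf_full_normalize(pd.DataFrame(A2, index=ids1, columns=ids1)).to_numpy()
    S1 = snf_knn_kernel(pd.DataFrame(A1, index=ids1, columns=ids1), K).to_numpy()
    S2 = snf_knn_kernel(pd.DataFrame(A2, index=ids1, columns=ids1), K).to_numpy()

    def renorm(M):
        M = (M + M.T) / 2.0
        return snf_full_normalize(
            pd.DataFrame(M, index=ids1, columns=ids1)).to_numpy()

    for _ in range(t):
        N1 = S1 @ P2 @ S1.T
        N2 = S2 @ P1 @ S2.T
        P1, P2 = renorm(N1), renorm(N2)
    fused = (P1 + P2) / 2.0
    fused = (fused + fused.T) / 2.0
    return pd.DataFrame(fused, index=ids1, columns=ids1)


def spectral_cluster(W, n_clusters: int, seed: int = 0,
                     n_init: int = 50) -> np.ndarray:
    """Normalized-Laplacian spectral clustering of a patient network.

    Embeds samples with the top eigenvectors of D^{-1/2} W D^{-1/2}
    (rows normalized to unit length) and runs seeded k-means.
    """
    A, ids = _as_array(W)
    n = A.shape[0]
    if not 2 <= n_clusters <= n:
        raise ValueError("n_clusters must be in [2, n_samples]")
    if (A < -1e-12).any():
        raise ValueError("affinity matrix must be nonnegative")
    n_comp, _ = connected_components((A > 0).astype(int), directed=False)
    if n_comp > n_clusters:
        warnings.warn(f"graph has {n_comp} components > {n_clusters} clusters",
                      stacklevel=2)
    d = A.sum(axis=1)
    d[d <= 0] = 1.0
    Dinv = 1.0 / np.sqrt(d)
    M = Dinv[:, None] * A * Dinv[None, :]
    M = (M + M.T) / 2.0
    vals, vecs = np.linalg.eigh(M)
    emb = vecs[:, -n_clusters:]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    emb = emb / norms
    km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed)
    return km.fit_predict(emb)


class SimilarityNetworkFusion(BaseEstimator):
    """Estimator wrapper: build per-view kernels, fuse, cluster.

    ``fit`` takes a list of two samples × features DataFrames over the
    same samples; ``fit_predict`` additionally returns spectral cluster
    labels of the fused network.
    """

    def __init__(self, K=30, mu=0.8, t=20, n_clusters=3, random_state=0):
        self.K = K
        self.mu = mu
        self.t = t
        self.n_clusters = n_clusters
        self.random_state = random_state

    def fit(self, X, y=None):
        views = list(X)
        if len(views) != 2:
            raise ValueError("exactly two views required")
        kernels = [affinity_kernel(v, K=self.K, mu=self.mu) for v in views]
        self.kernels_ = kernels
        self.fused_ = snf_fuse(kernels, K=self.K, t=self.t)
        return self

    def fit_predict(self, X, y=None):
        self.fit(X)
        self.labels_ = spectral_cluster(self.fused_, self.n_clusters,
                                        seed=self.random_state)
        return self.labels_


def _as_array(W):
    if isinstance(W, pd.DataFrame):
        return W.to_numpy(dtype=float), list(W.index)
    A = np.asarray(W, dtype=float)
    return A, list(range(A.shape[0]))
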