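"""Local-maximum Quasi-Clique Merging (lmQCM) module mining.

A greedy miner for dense, possibly overlapping subgraphs of a weighted
gene co-expression network. Seeds are edges that are local maxima of
the weight function and at least ``gamma``; each seed grows by adding
the vertex with the largest total weight to the current members while
the subgraph density stays above an adaptive bound
``gamma * (1 - 1/(2*alpha*(k + t)))`` evaluated at the enlarged size
``k``; candidates are merged when their overlap relative to the smaller
module reaches ``beta``.

Parameter names follow the module-mining literature: the seed threshold
is called gamma here (some descriptions call the same quantity lambda),
alpha and t shape the adaptive density bound, beta the merge ratio.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .network import spearman_weight_matrix, normalize_weights, weighted_density

__all__ = ["GeneModule", "lmqcm_mine", "LmQCM", "density_bound"]

logger = logging.getLogger(__name__)


@dataclass
class GeneModule:
    """An ordered set of gene symbols mined from one platform."""

    label: str
    genes: list[str] = field(default_factory=list)
    platform: str | None = None

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"module {self.label} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_set(self) -> frozenset:
        return frozenset(self.genes)


def density_bound(size: int, gamma: float, alpha: float, t: float) -> float:
    """Adaptive density acceptance bound at module size ``size``."""
    return gamma * (1.0 - 1.0 / (2.0 * alpha * (size + t)))


def _seed_edges(A: np.ndarray, gamma: float):
    """Edges with weight ≥ gamma that are local maxima.

    An edge (i, j) is a local maximum when its weight is ≥ the weight of
    every edge incident to i or j. Returned sorted by descending weight,
    ties broken by vertex index pair.
    """
    n = A.shape[0]
    rowmax = A.max(axis=1) if n else np.array([])
    seeds = []
    for i in range(n):
        for j in range(i + 1, n):
            w = A[i, j]
            if w >= gamma and w >= rowmax[i] and w >= rowmax[j]:
                seeds.append((w, i, j))
    seeds.sort(key=lambda s: (-s[0], s[1], s[2]))
    return seeds


def _grow(A: np.ndarray, seed: tuple[int, int], gamma: float, alpha: float,
          t: float, order: np.ndarray) -> list[int]:
    """Greedy expansion of one seed edge.

    ``order`` maps vertex position → tie-break rank (lexicographic gene
    label), making the result invariant to input gene order.
    """
    n = A.shape[0]
    i, j = seed
    members = [i, j]
    in_set = np.zeros(n, dtype=bool)
    in_set[[i, j]] = True
    gain = A[:, i] + A[:, j]
    edge_sum = A[i, j]
    while True:
        k_new = len(members) + 1
        masked = np.where(in_set, -np.inf, gain)
        best = masked.max()
        if not np.isfinite(best):
            break
        ties = np.flatnonzero(masked == best)
        v = ties[np.argmin(order[ties])]
        new_density = 2.0 * (edge_sum + gain[v]) / (k_new * (k_new - 1))
        if new_density < density_bound(k_new, gamma, alpha, t):
            break
        members.append(int(v))
        in_set[v] = True
        edge_sum += gain[v]
        gain = gain + A[:, v]
    return members


def _merge(candidates: list[frozenset], beta: float, key) -> list[frozenset]:
    """Merge overlapping candidates to a fixed point.

    Modules are kept sorted by size descending (ties by the lexicographic
    gene tuple); any pair with |A∩B| / min(|A|,|B|) ≥ beta is replaced by
    its union, and scanning restarts.
    """
    mods = sorted(set(candidates), key=key)
    merged = True
    while merged:
        merged = False
        for a in range(len(mods)):
            for b in range(a + 1, len(mods)):
                inter = len(mods[a] & mods[b])
                if inter / min(len(mods[a]), len(mods[b])) >= beta:
                    union = mods[a] | mods[b]
                    del mods[b], mods[a]
                    mods.append(union)
                    mods.sort(key=key)
                    merged = True
                    break
            if merged:
                break
    return mods


def lmqcm_mine(
    W: pd.DataFrame,
    gamma: float = 0.80,
    t: float = 1.0,
    alpha: float = 1.0,
    beta: float = 0.4,
    min_module_size: int = 10,
    platform: str | None = None,
    prefix: str | None = None,
) -> list[GeneModule]:
    """Mine co-expressed gene modules from a weight matrix.

    Parameters
    ----------
    W : DataFrame, genes × genes
        Symmetric nonnegative edge weights with zero diagonal, e.g. from
        :func:`~gcnsurv.network.spearman_weight_matrix`. The seed
        threshold ``gamma`` applies to this matrix as passed.
    gamma, t, alpha, beta : floats
        Seed edge-weight threshold, density-bound offset, density-bound
        scale and merge-overlap ratio.
    min_module_size : int
        Grown candidates smaller than this are discarded before merging.
    platform, prefix : str, optional
        Platform tag stored on each module and the label prefix
        (default: first letter of the platform, upper-cased, else "M").

    Returns
    -------
    list of GeneModule, labelled by final size rank (1 = largest).
    """
    if not 0 < gamma <= 1:
        raise ValueError("gamma must be in (0, 1]")
    if not 0 < beta <= 1:
        raise ValueError("beta must be in (0, 1]")
    if t < 0 or alpha <= 0:
        raise ValueError("t must be ≥ 0 and alpha > 0")
    A = W.to_numpy(dtype=float)
    genes = W.index.to_numpy()
    order = np.argsort(np.argsort(genes.astype(str)))

    seeds = _seed_edges(A, gamma)
    if not seeds:
        logger.info("no edge reaches gamma=%.3f; returning no modules", gamma)
        return []
    candidates: list[frozenset] = []
    for _, i, j in seeds:
        grown = _grow(A, (i, j), gamma, alpha, t, order)
        if len(grown) >= min_module_size:
            candidates.append(frozenset(grown))
    if not candidates:
        return []

    def sort_key(s):
        return (-len(s), tuple(sorted(genes[list(s)].astype(str))))

    merged = _merge(candidates, beta, sort_key)
    merged.sort(key=sort_key)
    if prefix is None:
        prefix = platform[0].upper() if platform else "M"
    modules = []
    for rank, mod in enumerate(merged, start=1):
        mod_genes = sorted(genes[sorted(mod)].astype(str))
        modules.append(GeneModule(f"{prefix}{rank}", mod_genes, platform))
    return modules


class LmQCM(BaseEstimator):
    """Quasi-clique module miner with a scikit-learn estimator surface.

    ``fit`` consumes a samples × genes table (sklearn orientation) or a
    genes × samples DataFrame when ``genes_as_rows=True``, builds the
    absolute-Spearman network and mines modules.

    Attributes
    ----------
    modules_ : list of GeneModule
    weight_matrix_ : DataFrame
        The matrix actually mined (raw |Spearman|, or the spectrally
        normalized version when ``spectral_norm=True``).
    premerge_densities_ : dict
        Weighted density of every grown candidate, keyed by the sorted
        gene tuple; all satisfy the adaptive bound at their size.
    """

    def __init__(self, gamma=0.80, t=1.0, alpha=1.0, beta=0.4,
                 min_module_size=10, spectral_norm=False,
                 platform=None, prefix=None, genes_as_rows=False):
        self.gamma = gamma
        self.t = t
        self.alpha = alpha
        self.beta = beta
        self.min_module_size = min_module_size
        self.spectral_norm = spectral_norm
        self.platform = platform
        self.prefix = prefix
        self.genes_as_rows = genes_as_rows

    def fit(self, X, y=None):
        expr = self._as_gene_frame(X)
        W = spearman_weight_matrix(expr)
        if self.spectral_norm:
            W = normalize_weights(W)
        self.weight_matrix_ = W
        self.modules_ = lmqcm_mine(
            W, gamma=self.gamma, t=self.t, alpha=self.alpha, beta=self.beta,
            min_module_size=self.min_module_size, platform=self.platform,
            prefix=self.prefix,
        )
        A = W.to_numpy()
        seeds = _seed_edges(A, self.gamma)
        order = np.argsort(np.argsort(W.index.to_numpy().astype(str)))
        self.premerge_densities_ = {}
        for _, i, j in seeds:
            grown = _grow(A, (i, j), self.gamma, self.alpha, self.t, order)
            if len(grown) >= self.min_module_size:
                key = tuple(sorted(W.index.to_numpy()[grown].astype(str)))
                self.premerge_densities_[key] = weighted_density(A, grown)
        return self

    def fit_predict(self, X, y=None):
        self.fit(X)
        return self.modules_

    def _as_gene_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X if self.genes_as_rows else X.T
        X = np.asarray(X, dtype=float)
        cols = [f"g{i}" for i in range(X.shape[1])]
        rows = [f"s{i}" for i in range(X.shape[0])]
        df = pd.DataFrame(X, index=rows, columns=cols)
        return df if self.genes_as_rows else df.T
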