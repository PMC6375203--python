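"""Cross-platform module comparison: uniqueness, coherence, stability.

Uniqueness: a module mined on one platform is *unique* when it has no
meaningful counterpart on the other platform — Jaccard index below a
threshold (default 0.05) AND one-sided Fisher/hypergeometric overlap
p-value above a threshold (default 0.05) against *every* module of the
other platform.

Coherence: the Correlation Index of a module of K genes with absolute
Spearman matrix W (unit diagonal) is

    C = ||W − I_{K×K}||_F² / K²

with an empirical p-value from size-matched random gene sets drawn from
the whole dataset: p = #(C* > C) / n_perm (strict inequality).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .lmqcm import GeneModule
from .network import spearman_weight_matrix

__all__ = ["jaccard_index", "overlap_fisher_p", "unique_modules",
           "UniquenessResult", "correlation_index", "correlation_index_p",
           "CoherenceResult", "module_stability", "StabilityResult"]

logger = logging.getLogger(__name__)


def jaccard_index(A, B) -> float:
    """|A∩B| / |A∪B| for two gene sets."""
    A, B = set(A), set(B)
    if not A and not B:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(A & B) / len(A | B)


def overlap_fisher_p(A, B, universe) -> float:
    """One-sided (enrichment) exact p-value for the overlap of two gene sets.

    Hypergeometric tail probability of observing at least |A∩B| shared
    genes when |A| genes are drawn from a universe of size |universe|
    containing |B| marked genes.
    """
    A, B, universe = set(A), set(B), set(universe)
    if not A <= universe or not B <= universe:
        raise ValueError("module genes must be contained in the universe")
    k = len(A & B)
    return float(hypergeom.sf(k - 1, len(universe), len(B), len(A)))


@dataclass
class UniquenessResult:
    """Per-module uniqueness call against every module of the other platform."""

    module_label: str
    platform: str | None
    best_jaccard: float
    best_fisher_p: float
    partner_label: str | None
    unique: bool


def _uniqueness_one_side(mods, others, universe, jaccard_threshold,
                         fisher_threshold):
    out = []
    for m in mods:
        best_j, best_p, partner, unique = 0.0, 1.0, None, True
        for o in others:
            j = jaccard_index(m.genes, o.genes)
            p = overlap_fisher_p(m.genes, o.genes, universe)
            if j > best_j or (j == best_j and partner is None):
                best_j, best_p, partner = j, p, o.label
            if not (j < jaccard_threshold and p > fisher_threshold):
                unique = False
        out.append(UniquenessResult(m.label, m.platform, best_j, best_p,
                                    partner, unique))
    return out


def unique_modules(mods1, mods2, universe, jaccard_threshold=0.05,
                   fisher_threshold=0.05):
    """Uniqueness calls for both module lists against each other.

    Returns a pair of UniquenessResult lists (one per platform, in input
    order). A module is unique iff versus EVERY module of the other
    platform its Jaccard is below ``jaccard_threshold`` and its Fisher
    overlap p is above ``fisher_threshold``; the recorded partner is the
    worst case (largest Jaccard).
    """
    universe = set(universe)
    for m in list(mods1) + list(mods2):
        extra = set(m.genes) - universe
        if extra:
            raise ValueError(f"module {m.label} has genes outside universe: "
                             f"{sorted(extra)[:5]}")
    if not mods2:
        warnings.warn("empty opposing module list: all modules trivially unique",
                      stacklevel=2)
    if not mods1:
        warnings.warn("empty module list on platform 1", stacklevel=2)
    res1 = _uniqueness_one_side(mods1, mods2, universe, jaccard_threshold,
                                fisher_threshold)
    res2 = _uniqueness_one_side(mods2, mods1, universe, jaccard_threshold,
                                fisher_threshold)
    return res1, res2


def uniqueness_frame(results) -> pd.DataFrame:
    """Tabulate UniquenessResult lists as one DataFrame."""
    rows = []
    for r in results:
        rows.append({"module": r.module_label, "platform": r.platform,
                     "best_jaccard": r.best_jaccard,
                     "best_fisher_p": r.best_fisher_p,
                     "partner": r.partner_label, "unique": r.unique})
    return pd.DataFrame(rows)


def correlation_index(W_sub) -> float:
    """Correlation Index C = ||W − I||_F² / K² of a module weight submatrix.

    ``W_sub`` is the K × K absolute-correlation matrix of the module's
    genes with unit diagonal.
    """
    W = np.asarray(W_sub, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W_sub must be square")
    K = W.shape[0]
    diff = W - np.eye(K)
    return float((diff**2).sum()) / (K * K)


@dataclass
class CoherenceResult:
    C: float
    p: float
    K: int
    n_perm: int


def _abs_spearman_unit_diag(expr: pd.DataFrame) -> pd.DataFrame:
    W = spearman_weight_matrix(expr)
    A = W.to_numpy()
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=W.index, columns=W.columns)


def correlation_index_p(expr: pd.DataFrame, module, n_perm: int = 1000,
                        seed: int | None = None,
                        weight_matrix: pd.DataFrame | None = None) -> CoherenceResult:
    """Correlation Index of a module with a permutation p-value.

    The null distribution draws ``n_perm`` gene sets of the module's
    size uniformly without replacement from all genes of ``expr`` and
    recomputes C each time; p = #(C* > C) / n_perm (ties do not count).
    ``weight_matrix`` may carry a precomputed absolute-Spearman matrix
    (unit diagonal) over the same genes to avoid recomputation.
    """
    genes = module.genes if isinstance(module, GeneModule) else list(module)
    K = len(genes)
    W = weight_matrix if weight_matrix is not None else _abs_spearman_unit_diag(expr)
    if W.shape[0] < K:
        raise ValueError("fewer genes available than the module size")
    idx = W.index.get_indexer(genes)
    if (idx < 0).any():
        raise KeyError("module genes absent from expression matrix")
    A = W.to_numpy()
    C = correlation_index(A[np.ix_(idx, idx)])
    rng = np.random.default_rng(seed)
    n_genes = A.shape[0]
    exceed = 0
    for _ in range(n_perm):
        pick = rng.choice(n_genes, size=K, replace=False)
        if correlation_index(A[np.ix_(pick, pick)]) > C:
            exceed += 1
    return CoherenceResult(C=C, p=exceed / n_perm, K=K, n_perm=n_perm)


@dataclass
class StabilityResult:
    C_train: float
    C_test: float
    random_C_test: np.ndarray


def module_stability(expr_train: pd.DataFrame, expr_test: pd.DataFrame,
                     module, n_random: int = 1000,
                     seed: int | None = None) -> StabilityResult:
    """Coherence of a module on held-out samples versus random gene sets.

    Computes the Correlation Index of the module on the training and
    test sample splits, plus the distribution of C over ``n_random``
    size-matched random gene sets evaluated on the test split. A stable
    co-expressed module keeps a test-set C in the upper tail of the
    random distribution.
    """
    genes = module.genes if isinstance(module, GeneModule) else list(module)
    W_tr = _abs_spearman_unit_diag(expr_train)
    W_te = _abs_spearman_unit_diag(expr_test)
    idx_tr = W_tr.index.get_indexer(genes)
    idx_te = W_te.index.get_indexer(genes)
    if (idx_tr < 0).any() or (idx_te < 0).any():
        raise KeyError("module genes must be present in both splits")
    A_te = W_te.to_numpy()
    C_train = correlation_index(W_tr.to_numpy()[np.ix_(idx_tr, idx_tr)])
    C_test = correlation_index(A_te[np.ix_(idx_te, idx_te)])
    rng = np.random.default_rng(seed)
    K, n_genes = len(genes), A_te.shape[0]
    rand = np.empty(n_random)
    for r in range(n_random):
        pick = rng.choice(n_genes, size=K, replace=False)
        rand[r] = correlation_index(A_te[np.ix_(pick, pick)])
    return StabilityResult(C_train=C_train, C_test=C_test, random_C_test=rand)
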