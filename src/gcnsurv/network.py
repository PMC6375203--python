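"""Weighted gene co-expression networks from expression matrices.

The network layer turns a genes × samples expression table into a
symmetric edge-weight matrix of absolute Spearman rank correlations
(robust to the large non-linear dynamic range of RNA-seq), optionally
rescaled by the symmetric degree normalization used in spectral
clustering, W_ij / sqrt(d_i d_j).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["spearman_weight_matrix", "normalize_weights", "weighted_density"]


def spearman_weight_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Absolute Spearman correlation between every pair of gene profiles.

    Parameters
    ----------
    expr : DataFrame, genes × samples
        Expression values; index = gene symbols (unique), columns =
        sample ids (unique). Needs at least 3 samples for non-degenerate
        ranks.

    Returns
    -------
    DataFrame, genes × genes
        Symmetric matrix of |Spearman rho| with the diagonal forced to 0
        (self-edges are excluded from mining). ``attrs["normalized"]``
        is set to False. Constant genes (zero rank variance) get all
        their correlations set to 0, with a warning.
    """
    _validate_expression(expr)
    values = expr.to_numpy(dtype=float)
    ranks = rankdata(values, axis=1)
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            "constant gene profile(s) set to zero correlation: "
            + ", ".join(map(str, expr.index[constant][:10])),
            stacklevel=2,
        )
        # give constant rows unit variance after centering to avoid nan;
        # their correlations are zeroed below
        ranks[constant] += np.random.default_rng(0).standard_normal(ranks.shape[1]) * 0
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((centered**2).sum(axis=1))
    denom[denom == 0] = 1.0
    corr = (centered / denom[:, None]) @ (centered / denom[:, None]).T
    W = np.abs(corr)
    W[constant, :] = 0.0
    W[:, constant] = 0.0
    np.clip(W, 0.0, 1.0, out=W)
    np.fill_diagonal(W, 0.0)
    out = pd.DataFrame(W, index=expr.index, columns=expr.index)
    out.attrs["normalized"] = False
    return out


def normalize_weights(W: pd.DataFrame) -> pd.DataFrame:
    """Symmetric degree normalization W_ij / sqrt(d_i d_j), d_i = Σ_k W_ik.

    The rescaling borrowed from spectral clustering; it damps weights of
    highly connected (hub) genes. Isolated genes (zero degree) keep a
    zero row/column, with a warning.
    """
    if W.attrs.get("normalized", False):
        raise ValueError("weight matrix is already normalized")
    A = W.to_numpy(dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("weight matrix must be square and symmetric")
    d = A.sum(axis=1)
    isolated = d == 0
    if isolated.any():
        warnings.warn(
            f"{int(isolated.sum())} isolated gene(s) with zero degree", stacklevel=2
        )
    scale = np.where(isolated, 1.0, d)
    out = A / np.sqrt(np.outer(scale, scale))
    out[isolated, :] = 0.0
    out[:, isolated] = 0.0
    res = pd.DataFrame(out, index=W.index, columns=W.columns)
    res.attrs["normalized"] = True
    return res


def weighted_density(W, members) -> float:
    """Mean edge weight of the subgraph induced by ``members``.

    2 Σ_{i<j} W_ij / (k (k−1)) for a member set of size k ≥ 2.
    ``W`` may be a DataFrame (members = gene labels or positions) or a
    plain array (members = positions).
    """
    if isinstance(W, pd.DataFrame):
        A = W.to_numpy(dtype=float)
        members = list(members)
        if members and not isinstance(members[0], (int, np.integer)):
            idx = W.index.get_indexer(members)
            if (idx < 0).any():
                missing = [m for m, i in zip(members, idx) if i < 0]
                raise KeyError(f"genes not in weight matrix: {missing}")
            members = idx
    else:
        A = np.asarray(W, dtype=float)
        members = list(members)
    k = len(members)
    if k < 2:
        raise ValueError("weighted density needs at least 2 members")
    sub = A[np.ix_(members, members)]
    return float(sub.sum() - np.trace(sub)) / (k * (k - 1))


def _validate_expression(expr: pd.DataFrame) -> None:
    if not isinstance(expr, pd.DataFrame):
        raise TypeError("expression must be a pandas DataFrame (genes × samples)")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for rank correlation")
    if expr.index.duplicated().any():
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene symbols: {dups}")
    if expr.columns.duplicated().any():
        raise ValueError("duplicate sample ids")
    if expr.isna().any().any():
        raise ValueError("expression matrix contains missing values")
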