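"""Eigengene summarization: one per-sample feature per gene module.

The eigengene of a module is the first principal-component score of the
z-scored module submatrix across samples, rescaled to unit variance.
Its sign is fixed so that it correlates non-negatively with the mean
z-scored profile of the module genes, making the summary deterministic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .lmqcm import GeneModule

__all__ = ["zscore_genes", "summarize_module", "eigengene_matrix",
           "EigengeneTransformer"]


def zscore_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Standardize every gene row to mean 0, sample (n−1) SD 1.

    Zero-variance genes become all-zero rows, with a warning.
    """
    if expr.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    values = expr.to_numpy(dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance gene(s) z-scored to zeros",
            stacklevel=2)
    sd[sd == 0] = 1.0
    out = (values - mu) / sd
    out[flat, :] = 0.0
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def summarize_module(expr: pd.DataFrame, module) -> pd.Series:
    """First-PC eigengene of one module, unit variance, sign-aligned.

    ``module`` is a GeneModule or any iterable of gene symbols, all of
    which must be rows of ``expr``.
    """
    genes = module.genes if isinstance(module, GeneModule) else list(module)
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"module genes absent from expression matrix: {missing}")
    Z = zscore_genes(expr.loc[genes]).to_numpy()
    # first right singular vector of the K × n z-scored block = PC1 scores
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    score = vt[0]
    if s[0] == 0:  # all-constant module
        warnings.warn("degenerate (constant) module; zero eigengene", stacklevel=2)
        return pd.Series(np.zeros(expr.shape[1]), index=expr.columns)
    sd = score.std(ddof=1)
    if sd > 0:
        score = score / sd
    mean_profile = Z.mean(axis=0)
    if score @ mean_profile < 0:
        score = -score
    return pd.Series(score, index=expr.columns)


def eigengene_matrix(expr: pd.DataFrame, modules) -> pd.DataFrame:
    """Stack eigengenes of several modules into a modules × samples table."""
    modules = list(modules)
    if not modules:
        raise ValueError("no modules to summarize")
    rows, labels = [], []
    for i, m in enumerate(modules):
        rows.append(summarize_module(expr, m))
        labels.append(m.label if isinstance(m, GeneModule) else f"M{i+1}")
    return pd.DataFrame(rows, index=labels)


class EigengeneTransformer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer mapping samples × genes to samples × eigengenes.

    Parameters
    ----------
    modules : list of GeneModule
        Modules to summarize; set at construction so the transformer
        composes with sklearn pipelines.

    Notes
    -----
    ``fit`` learns the per-gene standardization and the PC1 loadings on
    the training samples; ``transform`` projects new samples onto those
    loadings. ``fit_transform`` on the same data reproduces
    :func:`eigengene_matrix` transposed.
    """

    def __init__(self, modules=None):
        self.modules = modules

    def fit(self, X, y=None):
        expr = self._gene_frame(X)
        if not self.modules:
            raise ValueError("modules must be provided")
        self.module_labels_ = [m.label for m in self.modules]
        self.gene_stats_ = {}
        self.loadings_ = {}
        self.signs_ = {}
        self.scales_ = {}
        for m in self.modules:
            missing = [g for g in m.genes if g not in expr.index]
            if missing:
                raise KeyError(f"module {m.label}: genes missing: {missing}")
            sub = expr.loc[m.genes].to_numpy(dtype=float)
            mu = sub.mean(axis=1)
            sd = sub.std(axis=1, ddof=1)
            sd[sd == 0] = 1.0
            Z = (sub - mu[:, None]) / sd[:, None]
            u, s, vt = np.linalg.svd(Z, full_matrices=False)
            load = u[:, 0]
            score = vt[0] * s[0]
            sign = 1.0 if score @ Z.mean(axis=0) >= 0 else -1.0
            score = score * sign
            scale = score.std(ddof=1)
            self.gene_stats_[m.label] = (mu, sd)
            self.loadings_[m.label] = load
            self.signs_[m.label] = sign
            self.scales_[m.label] = scale if scale > 0 else 1.0
        return self

    def transform(self, X):
        expr = self._gene_frame(X)
        cols = {}
        for m in self.modules:
            mu, sd = self.gene_stats_[m.label]
            Z = (expr.loc[m.genes].to_numpy(dtype=float) - mu[:, None]) / sd[:, None]
            score = self.signs_[m.label] * (self.loadings_[m.label] @ Z)
            cols[m.label] = score / self.scales_[m.label]
        return pd.DataFrame(cols, index=expr.columns)

    @staticmethod
    def _gene_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X.T  # sklearn orientation: samples × genes
        raise TypeError("X must be a DataFrame with gene-symbol columns")
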