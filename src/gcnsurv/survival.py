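"""Survival modelling: cross-validated lasso-Cox selection, risk-index
stratification, Kaplan–Meier curves and the log-rank test.

The selector fits an L1-penalized Cox proportional-hazards model over a
decreasing penalty path, picks the penalty by k-fold cross-validated
partial-likelihood deviance (Verweij & van Houwelingen), and exposes the
sparse coefficient vector, the per-sample risk index (linear predictor)
and the training-median risk threshold used for low/high dichotomization.
An outer leave-one-out loop yields honest per-sample risk groups and
per-fold selected feature sets, aggregated by consensus frequency.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold, StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

__all__ = ["CoxnetSelector", "RiskModel", "lasso_cox_fit",
           "loocv_risk_indices", "LoocvResult", "consensus_selection",
           "median_split", "km_estimate", "KMCurve", "logrank_test",
           "LogrankResult", "cox_partial_loglik"]

logger = logging.getLogger(__name__)


def cox_partial_loglik(X, time, event, beta) -> float:
    """Breslow partial log-likelihood of a Cox model at coefficients ``beta``."""
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    lp = X @ np.asarray(beta, dtype=float)
    order = np.argsort(-time, kind="stable")  # decreasing time
    lp_o, t_o, e_o = lp[order], time[order], event[order]
    log_cum = np.logaddexp.accumulate(lp_o)  # log Σ_{t_j ≥ t_i} exp(lp_j)
    ll = 0.0
    i = 0
    n = len(t_o)
    while i < n:
        j = i
        while j < n and t_o[j] == t_o[i]:
            j += 1
        # risk set for this time = everyone with index < j (t ≥ t_i)
        log_risk = log_cum[j - 1]
        for k in range(i, j):
            if e_o[k]:
                ll += lp_o[k] - log_risk
        i = j
    return float(ll)


@dataclass
class RiskModel:
    """Fitted sparse Cox risk model."""

    feature_labels: list
    coefficients: np.ndarray
    regularization: float
    training_median_risk: float
    selected_features: list

    def risk_index(self, X: pd.DataFrame) -> pd.Series:
        lp = X[self.feature_labels].to_numpy(dtype=float) @ self.coefficients
        return pd.Series(lp, index=X.index)


class CoxnetSelector(BaseEstimator):
    """L1 Cox proportional-hazards feature selector (sklearn estimator).

    Parameters
    ----------
    inner_folds : int
        Folds of the penalty-selection cross-validation (reduced with a
        warning when there are fewer samples).
    penalty_rule : {"min", "1se"}
        Pick the deviance-minimizing penalty or the largest penalty
        within one standard error of the minimum.
    n_alphas, alpha_min_ratio : path shape passed to the coordinate
        descent solver.
    random_state : seed for the CV fold shuffle.

    Attributes (after ``fit``)
    --------------------------
    coef_ : Series per feature; alpha_ : chosen penalty;
    alphas_ : path; cv_deviance_ : mean CV deviance per path point;
    selected_features_ : labels with nonzero coefficient;
    training_median_risk_ : median linear predictor on the fit samples.
    """

    def __init__(self, inner_folds=10, penalty_rule="min", n_alphas=50,
                 alpha_min_ratio=0.05, tol=1e-7, max_iter=100000,
                 random_state=None):
        self.inner_folds = inner_folds
        self.penalty_rule = penalty_rule
        self.n_alphas = n_alphas
        self.alpha_min_ratio = alpha_min_ratio
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        X = self._as_frame(X)
        time, event = _unpack_y(y, X.index)
        if event.sum() < 2:
            raise ValueError("need at least 2 observed events to fit a Cox model")
        if X.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        Xv = X.to_numpy(dtype=float)
        y_struct = Surv.from_arrays(event=event.astype(bool), time=time)

        path = self._coxnet()
        path.fit(Xv, y_struct)
        alphas = np.asarray(path.alphas_)

        n = len(X)
        folds = min(self.inner_folds, int(event.sum()), n)
        if folds < self.inner_folds:
            warnings.warn(f"reducing CV folds to {folds}", stacklevel=2)
        if folds < 2:
            # no CV possible: keep the middle of the path
            chosen = alphas[len(alphas) // 2]
            dev_mean = dev_se = np.full(len(alphas), np.nan)
        else:
            dev = np.full((folds, len(alphas)), np.nan)
            splitter = StratifiedKFold(folds, shuffle=True,
                                       random_state=self.random_state)
            try:
                splits = list(splitter.split(Xv, event))
            except ValueError:
                splits = list(KFold(folds, shuffle=True,
                                    random_state=self.random_state).split(Xv))
            ll_full_cache = {}
            for f, (tr, _te) in enumerate(splits):
                m = self._coxnet(alphas=alphas)
                try:
                    m.fit(Xv[tr], y_struct[tr])
                except Exception as exc:  # pragma: no cover - solver edge
                    logger.warning("fold %d failed: %s", f, exc)
                    continue
                fold_alphas = np.asarray(m.alphas_)
                coefs = m.coef_  # (p, n_alphas_fit)
                for a_idx, a in enumerate(alphas):
                    hit = np.flatnonzero(np.isclose(fold_alphas, a))
                    if hit.size == 0:
                        continue
                    beta = coefs[:, hit[0]]
                    key = beta.tobytes()
                    if key not in ll_full_cache:
                        ll_full_cache[key] = cox_partial_loglik(
                            Xv, time, event, beta)
                    ll_train = cox_partial_loglik(Xv[tr], time[tr], event[tr],
                                                  beta)
                    dev[f, a_idx] = -2.0 * (ll_full_cache[key] - ll_train)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                dev_mean = np.nanmean(dev, axis=0)
                dev_se = np.nanstd(dev, axis=0, ddof=1) / np.sqrt(
                    np.maximum(1, (~np.isnan(dev)).sum(axis=0)))
            if np.all(np.isnan(dev_mean)):
                chosen = alphas[len(alphas) // 2]
            else:
                best = int(np.nanargmin(dev_mean))
                if self.penalty_rule == "1se":
                    limit = dev_mean[best] + dev_se[best]
                    ok = np.flatnonzero(dev_mean <= limit)
                    # alphas are in decreasing order: smallest index = strongest
                    chosen = alphas[ok.min()] if ok.size else alphas[best]
                else:
                    chosen = alphas[best]

        final = self._coxnet(alphas=[chosen])
        final.fit(Xv, y_struct)
        coef = final.coef_[:, 0]
        self.feature_names_in_ = list(X.columns)
        self.coef_ = pd.Series(coef, index=X.columns)
        self.alpha_ = float(chosen)
        self.alphas_ = alphas
        self.cv_deviance_ = dev_mean
        self.cv_deviance_se_ = dev_se
        self.selected_features_ = list(X.columns[np.abs(coef) > 0])
        lp = Xv @ coef
        self.training_median_risk_ = float(np.median(lp))
        return self

    def predict(self, X):
        """Per-sample risk index (Cox linear predictor)."""
        X = self._as_frame(X)
        lp = X[self.feature_names_in_].to_numpy(dtype=float) @ \
            self.coef_.to_numpy()
        return pd.Series(lp, index=X.index)

    def risk_model_(self) -> RiskModel:
        return RiskModel(self.feature_names_in_, self.coef_.to_numpy(),
                         self.alpha_, self.training_median_risk_,
                         list(self.selected_features_))

    def _coxnet(self, alphas=None):
        kw = dict(l1_ratio=1.0, tol=self.tol, max_iter=self.max_iter,
                  fit_baseline_model=False)
        if alphas is None:
            kw.update(n_alphas=self.n_alphas,
                      alpha_min_ratio=self.alpha_min_ratio)
        else:
            kw.update(alphas=list(alphas))
        return CoxnetSurvivalAnalysis(**kw)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])


def _unpack_y(y, index=None):
    """Accept a clinical DataFrame (time/event), a (time, event) tuple or a
    sksurv structured array."""
    if isinstance(y, pd.DataFrame):
        df = y.set_index("sample_id") if "sample_id" in y.columns else y
        if index is not None and set(index) <= set(df.index):
            df = df.loc[list(index)]
        time = df["time"].to_numpy(dtype=float)
        event = df["event"].to_numpy(dtype=int)
    elif isinstance(y, tuple) and len(y) == 2:
        time = np.asarray(y[0], dtype=float)
        event = np.asarray(y[1], dtype=int)
    else:
        arr = np.asarray(y)
        if arr.dtype.names:
            names = arr.dtype.names
            event = arr[names[0]].astype(int)
            time = arr[names[1]].astype(float)
        else:
            raise TypeError("cannot interpret survival outcome y")
    if (time <= 0).any():
        raise ValueError("survival times must be positive")
    if not np.isin(event, [0, 1]).all():
        raise ValueError("event indicator must be 0 or 1")
    return time, event


def lasso_cox_fit(features, survival, inner_folds=10, penalty_rule="min",
                  seed=None) -> RiskModel:
    """Fit the cross-validated lasso-Cox model on all provided samples.

    ``features`` is an eigengene matrix (modules × samples DataFrame) or
    a samples × features table; ``survival`` a clinical DataFrame with
    sample_id/time/event.
    """
    X = _features_as_samples(features, survival)
    sel = CoxnetSelector(inner_folds=inner_folds, penalty_rule=penalty_rule,
                         random_state=seed)
    sel.fit(X, survival)
    return sel.risk_model_()


def _features_as_samples(features, survival=None) -> pd.DataFrame:
    X = features
    if survival is not None and "sample_id" in getattr(survival, "columns", []):
        ids = list(survival["sample_id"])
        if set(ids) == set(X.columns):  # modules × samples orientation
            X = X.T
        X = X.loc[ids]
    elif isinstance(X, pd.DataFrame) and X.shape[0] < X.shape[1]:
        X = X.T
    return X


@dataclass
class LoocvResult:
    risk_index: pd.Series
    group: pd.Series  # "low" / "high" vs each training fit's median
    fold_selected: list = field(default_factory=list)


def loocv_risk_indices(features, survival, inner_folds=10, penalty_rule="min",
                       seed=None, outer="loo") -> LoocvResult:
    """Outer held-out risk indices with per-fold selected feature sets.

    ``outer`` is "loo" (one fit per sample) or an integer k for k-fold
    outer splitting; each held-out sample's risk index comes from a
    model that never saw it, and its low/high group compares that index
    to the training fit's median risk.
    """
    X = _features_as_samples(features, survival)
    time, event = _unpack_y(survival, X.index)
    n = len(X)
    if outer == "loo":
        splits = [(np.delete(np.arange(n), i), np.array([i]))
                  for i in range(n)]
    else:
        k = int(outer)
        splits = list(KFold(k, shuffle=True, random_state=seed).split(X))
    risk = pd.Series(np.nan, index=X.index, dtype=float)
    group = pd.Series("", index=X.index, dtype=object)
    fold_selected = []
    for tr, te in splits:
        sel = CoxnetSelector(inner_folds=inner_folds,
                             penalty_rule=penalty_rule, random_state=seed)
        sel.fit(X.iloc[tr], (time[tr], event[tr]))
        fold_selected.append(set(sel.selected_features_))
        lp = sel.predict(X.iloc[te])
        risk.iloc[te] = lp.to_numpy()
        thr = sel.training_median_risk_
        group.iloc[te] = np.where(lp.to_numpy() <= thr, "low", "high")
    return LoocvResult(risk_index=risk, group=group,
                       fold_selected=fold_selected)


def consensus_selection(per_fold_sets, frequency_threshold=0.5):
    """Features selected in at least ``frequency_threshold`` of the folds."""
    per_fold_sets = list(per_fold_sets)
    if not per_fold_sets:
        raise ValueError("no fold selections provided")
    counts = {}
    for s in per_fold_sets:
        for f in s:
            counts[f] = counts.get(f, 0) + 1
    k = len(per_fold_sets)
    return {f for f, c in counts.items() if c / k >= frequency_threshold}


def median_split(risks, threshold) -> pd.Series:
    """Dichotomize risk indices at a threshold: ≤ threshold → "low"."""
    risks = pd.Series(risks)
    if not np.isfinite(risks.to_numpy(dtype=float)).all():
        raise ValueError("risk indices must be finite")
    labels = np.where(risks.to_numpy(dtype=float) <= threshold, "low", "high")
    if len(set(labels)) == 1:
        warnings.warn("degenerate split: all samples in one risk group",
                      stacklevel=2)
    return pd.Series(labels, index=risks.index)


@dataclass
class KMCurve:
    """Kaplan–Meier product-limit estimate as a right-continuous step function."""

    times: np.ndarray
    survival: np.ndarray

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return float(out) if out.ndim == 0 else out


def km_estimate(time, event=None) -> KMCurve:
    """Kaplan–Meier estimator; accepts (time, event) arrays or a clinical frame."""
    if event is None:
        time, event = _unpack_y(time)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValueError("no survival records")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    sf = kmf.survival_function_
    return KMCurve(times=sf.index.to_numpy(dtype=float),
                   survival=sf.iloc[:, 0].to_numpy(dtype=float))


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float
    log_p: float  # natural log of the p-value; exact even when p underflows


def logrank_test(time, event, groups) -> LogrankResult:
    """g-sample log-rank test (chi-square with g−1 degrees of freedom)."""
    from scipy.stats import chi2

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("log-rank test needs at least 2 non-empty groups")
    if event.sum() < 1:
        raise ValueError("log-rank test needs at least 1 observed event")
    res = multivariate_logrank_test(time, groups, event)
    stat, df = float(res.test_statistic), len(levels) - 1
    return LogrankResult(statistic=stat, df=df, p_value=float(res.p_value),
                         log_p=float(chi2.logsf(stat, df)))
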