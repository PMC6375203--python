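import numpy as np
import pandas as pd
import pytest

from gcnsurv.eigengene import eigengene_matrix
from gcnsurv.lmqcm import GeneModule
from gcnsurv.survival import (CoxnetSelector, consensus_selection,
                              cox_partial_loglik, km_estimate, lasso_cox_fit,
                              logrank_test, loocv_risk_indices, median_split)
from gcnsurv.synthetic import CohortConfig, ModuleSpec, generate_cohort


def eigengenes_with_truth(n_modules, informative, n=300, seed=0):
    """Cohort with n_modules planted modules, the named ones driving hazard."""
    cfg = CohortConfig(
        n_samples=n, n_genes_per_platform=n_modules * 20 + 20,
        shared_modules=tuple(ModuleSpec(20, 0.8) for _ in range(n_modules)),
        unique_modules_platform1=(), unique_modules_platform2=(),
        hazard_coefficients={m: 1.0 for m in informative}, seed=seed)
    cohort = generate_cohort(cfg)
    mods = [GeneModule(lab, genes) for lab, genes in
            cohort.truth_modules1.items()]
    eig = eigengene_matrix(cohort.expr1, mods)
    return eig.T, cohort.clinical


class TestKaplanMeier:
    def test_hand_product_limit_all_events(self):
        c = km_estimate(np.array([5.0, 8.0, 12.0]), np.array([1, 1, 1]))
        assert np.allclose(c([5, 8, 12]), [2 / 3, 1 / 3, 0.0])
        assert c(4.9) == 1.0

    def test_hand_product_limit_with_censoring(self):
        c = km_estimate(np.array([5.0, 8.0, 12.0]), np.array([1, 0, 1]))
        assert np.allclose(c([5, 11, 12]), [2 / 3, 2 / 3, 0.0])

    def test_all_censored_curve_stays_at_one(self):
        c = km_estimate(np.array([5.0, 8.0]), np.array([0, 0]))
        assert np.all(c([0, 5, 8, 100]) == 1.0)

    def test_curve_monotone_from_one(self):
        rng = np.random.default_rng(2)
        c = km_estimate(rng.exponential(10, 100),
                        rng.integers(0, 2, 100))
        assert c.survival[0] <= 1.0
        assert np.all(np.diff(c.survival) <= 1e-12)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1.0, 2, 3, 1, 2, 3])
        e = np.ones(6, int)
        g = np.array(list("AAABBB"))
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_enumerated_observed_minus_expected(self):
        # group A dies at 1,2,3; group B at 10,11,12 — enumerate the O−E
        # table and hypergeometric variances independently
        t = np.array([1.0, 2, 3, 10, 11, 12])
        e = np.ones(6, int)
        g = np.array(list("AAABBB"))
        # (time, total at risk, group-A at risk, deaths); O_A = 3 since the
        # events at t = 1, 2, 3 are all in group A
        at_risk = [(1.0, 6, 3, 1), (2.0, 5, 2, 1), (3.0, 4, 1, 1),
                   (10.0, 3, 0, 1), (11.0, 2, 0, 1), (12.0, 1, 0, 1)]
        E_A = sum(d * nA / n for _, n, nA, d in at_risk)
        V = sum(d * (nA / n) * (1 - nA / n) * (n - d) / max(n - 1, 1)
                for _, n, nA, d in at_risk)
        stat_expected = (3 - E_A) ** 2 / V
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(stat_expected, rel=1e-10)
        assert res.df == 1

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(5, 60)
        e = rng.integers(0, 2, 60)
        e[0] = 1
        g = rng.integers(0, 2, 60)
        a = logrank_test(t, e, g)
        b = logrank_test(t, e, 1 - g)
        assert a.statistic == pytest.approx(b.statistic)
        assert 0 <= a.p_value <= 1

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(np.array([1.0, 2.0]), np.array([1, 1]),
                         np.array([0, 0]))


class TestMedianSplit:
    def test_threshold_split_and_tie_rule(self):
        out = median_split(pd.Series([1.0, 2, 3, 4]), 2.5)
        assert list(out) == ["low", "low", "high", "high"]
        assert median_split(pd.Series([2.5]), 2.5).iloc[0] == "low"

    def test_degenerate_constant_risks_warn(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = median_split(pd.Series([1.0, 1.0]), 1.0)
        assert set(out) == {"low"}


class TestConsensus:
    def test_counting_rules(self):
        sets = [{"a", "b"}] * 6 + [{"b"}] * 4
        assert consensus_selection(sets, 0.5) == {"a", "b"}
        assert consensus_selection(sets, 0.7) == {"b"}
        assert consensus_selection([set(), set()]) == set()


class TestCoxnetSelector:
    def test_informative_feature_selected_with_correct_sign(self):
        X, clinical = eigengenes_with_truth(4, ["S1"], n=300, seed=1)
        sel = CoxnetSelector(penalty_rule="1se", random_state=0)
        sel.fit(X, clinical)
        assert "S1" in sel.selected_features_
        # eigengene sign convention may flip the factor; require the risk
        # index itself to point the right way
        risk = sel.predict(X)
        hi = risk > risk.median()
        assert clinical.loc[hi.to_numpy(), "time"].median() < \
            clinical.loc[~hi.to_numpy(), "time"].median()

    def test_duplicate_feature_leaves_risk_index_unchanged(self):
        X, clinical = eigengenes_with_truth(3, ["S1"], n=200, seed=5)
        sel = CoxnetSelector(random_state=0)
        sel.fit(X, clinical)
        X2 = X.copy()
        X2["S1_copy"] = X["S1"]
        sel2 = CoxnetSelector(random_state=0)
        sel2.fit(X2, clinical)
        # refit at the first model's penalty for a like-for-like comparison
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv
        y = Surv.from_arrays(event=clinical["event"].astype(bool),
                             time=clinical["time"])
        a = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[sel.alpha_],
                                   tol=1e-9, max_iter=200000).fit(X, y)
        b = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[sel.alpha_],
                                   tol=1e-9, max_iter=200000).fit(X2, y)
        lp_a = X.to_numpy() @ a.coef_[:, 0]
        lp_b = X2.to_numpy() @ b.coef_[:, 0]
        assert np.allclose(lp_a, lp_b, atol=1e-6)

    def test_risk_ordering_invariant_to_feature_shift(self):
        X, clinical = eigengenes_with_truth(3, ["S1"], n=200, seed=6)
        sel = CoxnetSelector(random_state=0).fit(X, clinical)
        shifted = X + 5.0
        r1 = sel.predict(X).rank()
        r2 = sel.predict(shifted).rank()
        assert (r1 == r2).all()

    def test_no_events_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).standard_normal((10, 2)))
        clinical = pd.DataFrame({"sample_id": X.index.astype(str),
                                 "time": np.arange(1.0, 11),
                                 "event": np.zeros(10, int)})
        with pytest.raises(ValueError, match="event"):
            CoxnetSelector().fit(X, (clinical["time"], clinical["event"]))

    def test_partial_loglik_matches_lifelines(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"t": rng.exponential(5, 40) + 0.1,
                           "e": rng.integers(0, 2, 40),
                           "x": rng.standard_normal(40)})
        df.loc[0, "e"] = 1
        cph = CoxPHFitter().fit(df, "t", "e", formula="x")
        mine = cox_partial_loglik(df[["x"]].to_numpy(), df["t"], df["e"],
                                  [cph.params_["x"]])
        assert mine == pytest.approx(cph.log_likelihood_, rel=1e-8)


class TestLoocv:
    def test_toy_cohort_fold_accounting(self):
        X = pd.DataFrame({"f1": [0.1, 0.5, 0.9, 0.3],
                          "f2": [1.0, 0.2, 0.4, 0.8]}, index=list("abcd"))
        clinical = pd.DataFrame({"sample_id": list("abcd"),
                                 "time": [3.0, 5, 2, 8],
                                 "event": [1, 1, 1, 1]})
        res = loocv_risk_indices(X, clinical, seed=0)
        assert len(res.fold_selected) == 4
        assert res.risk_index.notna().all()
        assert set(res.group) <= {"low", "high"}

    def test_reproducible_given_seed(self):
        X, clinical = eigengenes_with_truth(3, ["S1"], n=40, seed=9)
        a = loocv_risk_indices(X, clinical, seed=1, outer=4)
        b = loocv_risk_indices(X, clinical, seed=1, outer=4)
        assert a.risk_index.equals(b.risk_index)
        assert a.fold_selected == b.fold_selected

    def test_informative_features_dominate_fold_selections(self):
        X, clinical = eigengenes_with_truth(9, ["S1", "S2"], n=300, seed=11)
        res = loocv_risk_indices(X, clinical, penalty_rule="1se", seed=0,
                                 outer=10)
        k = len(res.fold_selected)
        freq = {f: sum(f in s for s in res.fold_selected) / k
                for f in X.columns}
        assert freq["S1"] >= 0.8 and freq["S2"] >= 0.8
        assert all(v <= 0.3 for f, v in freq.items()
                   if f not in ("S1", "S2"))


class TestPowerOfSelection:
    def test_selected_eigengenes_sharpen_median_split_logrank(self):
        # risk index restricted to informative features beats one diluted
        # by noise eigengenes (geometric mean over replicates)
        logs_sel, logs_all = [], []
        for rep in range(8):
            X, clinical = eigengenes_with_truth(8, ["S1"], n=200,
                                                seed=100 + rep)
            model = lasso_cox_fit(X, clinical, penalty_rule="1se", seed=rep)
            risk_sel = model.risk_index(X)
            # the unweighted composite a joint analysis of every eigengene
            # (signal and noise alike) would stratify on
            sign = np.sign(model.coefficients.sum()) or 1.0
            risk_all = X @ np.full(X.shape[1], sign)
            for risk, out in ((risk_sel, logs_sel), (risk_all, logs_all)):
                groups = median_split(risk, risk.median())
                res = logrank_test(clinical["time"], clinical["event"],
                                   groups.to_numpy())
                out.append(res.log_p)
        assert np.mean(logs_sel) < np.mean(logs_all)
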