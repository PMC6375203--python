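"""Quasi-clique miner: hand-checked graphs, brute-force oracle, invariants."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gcnsurv.lmqcm import (GeneModule, LmQCM, _seed_edges, density_bound,
                           lmqcm_mine)
from gcnsurv.network import spearman_weight_matrix, weighted_density
from gcnsurv.synthetic import (CohortConfig, ModuleSpec, generate_cohort,
                               truth_overlap)


# ---------------------------------------------------------------- oracle
def brute_force_mine(W: pd.DataFrame, gamma, alpha, t, beta, min_size):
    """Naive independent simulation of the seed/growth/merge rules."""
    genes = list(W.index)
    A = W.to_numpy()
    n = len(genes)

    def density(members):
        s = 0.0
        for i, j in itertools.combinations(members, 2):
            s += A[i, j]
        k = len(members)
        return 2 * s / (k * (k - 1))

    # seed edges: weight >= gamma and >= every incident edge
    seeds = []
    for i in range(n):
        for j in range(i + 1, n):
            w = A[i, j]
            if w < gamma:
                continue
            incident = [A[i, k] for k in range(n) if k != i] + \
                       [A[j, k] for k in range(n) if k != j]
            if all(w >= x for x in incident):
                seeds.append((w, i, j))
    seeds.sort(key=lambda s: (-s[0], s[1], s[2]))

    grown = []
    for _, i, j in seeds:
        members = [i, j]
        while True:
            outside = [v for v in range(n) if v not in members]
            if not outside:
                break
            gains = {v: sum(A[v, m] for m in members) for v in outside}
            best_gain = max(gains.values())
            best = sorted(v for v in outside if gains[v] == best_gain)
            v = min(best, key=lambda v: genes[v])
            new = members + [v]
            if density(new) < gamma * (1 - 1 / (2 * alpha * (len(new) + t))):
                break
            members = new
        if len(members) >= min_size:
            grown.append(frozenset(members))

    def key(s):
        return (-len(s), tuple(sorted(genes[v] for v in s)))

    mods = sorted(set(grown), key=key)
    changed = True
    while changed:
        changed = False
        for a in range(len(mods)):
            for b in range(a + 1, len(mods)):
                inter = len(mods[a] & mods[b])
                if inter / min(len(mods[a]), len(mods[b])) >= beta:
                    u = mods[a] | mods[b]
                    del mods[b], mods[a]
                    mods.append(u)
                    mods.sort(key=key)
                    changed = True
                    break
            if changed:
                break
    return sorted((frozenset(genes[v] for v in m) for m in mods),
                  key=lambda s: (-len(s), tuple(sorted(s))))


def mined_sets(mods):
    return sorted((m.gene_set for m in mods),
                  key=lambda s: (-len(s), tuple(sorted(s))))


def random_weight_frame(rng, n):
    A = rng.uniform(0, 1, (n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0)
    genes = [f"g{i}" for i in range(n)]
    return pd.DataFrame(A, index=genes, columns=genes)


def clique_frame(cliques, n, base=0.10, high=0.95):
    genes = [f"g{i}" for i in range(n)]
    A = np.full((n, n), base)
    for cl in cliques:
        for i in cl:
            for j in cl:
                A[i, j] = high
    np.fill_diagonal(A, 0.0)
    return pd.DataFrame(A, index=genes, columns=genes)


# ----------------------------------------------------------------- tests
class TestHandGraphs:
    def test_single_tight_triangle(self, toy_weight_frame):
        mods = lmqcm_mine(toy_weight_frame, gamma=0.8, t=1, alpha=1, beta=0.4,
                          min_module_size=3)
        assert len(mods) == 1
        assert mods[0].gene_set == frozenset("abc")

    def test_disjoint_cliques_stay_separate(self):
        W = clique_frame([range(0, 4), range(4, 8)], 10)
        mods = lmqcm_mine(W, gamma=0.8, t=1, alpha=1, beta=0.4,
                          min_module_size=3)
        sets = mined_sets(mods)
        assert frozenset(f"g{i}" for i in range(4)) in sets
        assert frozenset(f"g{i}" for i in range(4, 8)) in sets
        # zero overlap ratio < beta → no merge
        assert len(sets) == 2

    def test_overlapping_cliques_merge(self):
        # two 4-cliques sharing 2 genes → overlap ratio ≥ 2/4 ≥ beta → merged
        W = clique_frame([{0, 1, 2, 3}, {2, 3, 4, 5}], 8)
        mods = lmqcm_mine(W, gamma=0.8, t=1, alpha=1, beta=0.4,
                          min_module_size=3)
        assert len(mods) == 1
        assert mods[0].gene_set >= frozenset(f"g{i}" for i in range(6))

    def test_no_seed_above_gamma_yields_empty(self):
        W = clique_frame([], 6, base=0.3)
        assert lmqcm_mine(W, gamma=0.8) == []

    def test_labels_ranked_by_size(self):
        W = clique_frame([range(0, 5), range(5, 8)], 12)
        mods = lmqcm_mine(W, gamma=0.8, beta=0.4, min_module_size=3,
                          platform="rnaseq")
        assert [m.label for m in mods] == ["R1", "R2"]
        assert len(mods[0]) >= len(mods[1])
        assert all(m.platform == "rnaseq" for m in mods)


class TestOracleEquivalence:
    @pytest.mark.parametrize("gamma", [0.5, 0.8])
    def test_random_small_graphs_match_brute_force(self, gamma):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(4, 9))
            W = random_weight_frame(rng, n)
            ours = mined_sets(lmqcm_mine(W, gamma=gamma, t=1, alpha=1,
                                         beta=0.4, min_module_size=2))
            oracle = brute_force_mine(W, gamma, 1, 1, 0.4, 2)
            assert ours == oracle


class TestInvariants:
    def test_premerge_candidates_respect_density_bound(self, planted_cohort):
        miner = LmQCM(min_module_size=5, genes_as_rows=True)
        miner.fit(planted_cohort.expr1)
        assert miner.premerge_densities_
        for genes, dens in miner.premerge_densities_.items():
            assert dens >= density_bound(len(genes), miner.gamma, miner.alpha,
                                         miner.t) - 1e-12

    def test_gene_order_permutation_invariance(self):
        rng = np.random.default_rng(5)
        W = random_weight_frame(rng, 8)
        perm = list(rng.permutation(W.index))
        a = mined_sets(lmqcm_mine(W, gamma=0.6, min_module_size=2))
        b = mined_sets(lmqcm_mine(W.loc[perm, perm], gamma=0.6,
                                  min_module_size=2))
        assert a == b

    def test_raising_gamma_never_adds_seeds(self):
        rng = np.random.default_rng(9)
        A = random_weight_frame(rng, 10).to_numpy()
        counts = [len(_seed_edges(A, g)) for g in (0.2, 0.5, 0.8, 0.95)]
        assert counts == sorted(counts, reverse=True)

    def test_duplicate_genes_in_module_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GeneModule("M1", ["a", "a", "b"])


class TestPlantedRecovery:
    def test_planted_modules_recovered(self, planted_cohort):
        W = spearman_weight_matrix(planted_cohort.expr1)
        mods = lmqcm_mine(W, gamma=0.8, t=1, alpha=1, beta=0.4,
                          min_module_size=10)
        ov = truth_overlap(planted_cohort.truth_modules1, mods)
        assert (ov.max(axis=1) >= 0.8).all()
        # background contributes no module: every mined module matches truth
        assert (ov.max(axis=0) >= 0.8).all()

    def test_estimator_surface(self, planted_cohort):
        miner = LmQCM(platform="microarray", genes_as_rows=True)
        out = miner.fit_predict(planted_cohort.expr1)
        assert out is miner.modules_
        assert miner.get_params()["gamma"] == 0.8
        labels = [m.label for m in out]
        assert labels == [f"M{i+1}" for i in range(len(out))]
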