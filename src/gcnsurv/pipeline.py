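"""End-to-end orchestration of the integrative survival workflow.

Stages: (optional) simulate a paired cohort → mine co-expression modules
per platform → summarize eigengenes → cross-platform uniqueness and
coherence → cross-validated lasso-Cox eigengene selection per platform →
assemble the fusion feature set (selected ∩ unique, with configurable
de-duplication of selected-but-shared pairs) → spectral clustering per
platform on all vs selected eigengenes → SNF fusion and clustering →
log-rank survival test for every clustering. Everything is a pure
function of (inputs, config, seed).
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .compare import (correlation_index_p, unique_modules, uniqueness_frame)
from .eigengene import eigengene_matrix
from .lmqcm import LmQCM
from .network import spearman_weight_matrix, normalize_weights
from .snf import affinity_kernel, snf_fuse, spectral_cluster
from .survival import (consensus_selection, lasso_cox_fit, logrank_test,
                       loocv_risk_indices, median_split)
from .synthetic import CohortConfig, generate_cohort

__all__ = ["PipelineConfig", "ResultsBundle", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Either ``simulate`` (a CohortConfig) or the three input paths must
    be provided.
    """

    expression1: str | None = None
    expression2: str | None = None
    clinical: str | None = None
    simulate: CohortConfig | None = None
    platform1: str = "microarray"
    platform2: str = "rnaseq"
    # module mining
    gamma: float = 0.80
    t: float = 1.0
    alpha: float = 1.0
    beta: float = 0.4
    min_module_size: int = 10
    spectral_norm: bool = False
    # uniqueness / coherence
    jaccard_threshold: float = 0.05
    fisher_threshold: float = 0.05
    n_perm: int = 1000
    # lasso-Cox
    inner_folds: int = 10
    penalty_rule: str = "1se"
    selection_mode: str = "consensus"  # "consensus" (outer-CV) or "full"
    outer: object = "loo"
    consensus_threshold: float = 0.5
    # SNF / clustering
    snf_K: int = 30
    snf_mu: float = 0.8
    snf_t: int = 20
    clusters_platform: int = 2
    clusters_fused: int = 3
    dedup_shared: str = "higher_C"  # or "keep_both" / "drop_both"
    cohort_filter: str = "all"  # or "high_risk" (requires a group column)
    seed: int = 0
    out_dir: str | None = None


@dataclass
class ResultsBundle:
    modules1: list = field(default_factory=list)
    modules2: list = field(default_factory=list)
    eigengenes1: pd.DataFrame | None = None
    eigengenes2: pd.DataFrame | None = None
    uniqueness: pd.DataFrame | None = None
    coherence: pd.DataFrame | None = None
    selected1: list = field(default_factory=list)
    selected2: list = field(default_factory=list)
    fusion_features1: list = field(default_factory=list)
    fusion_features2: list = field(default_factory=list)
    risk_index1: pd.Series | None = None
    risk_index2: pd.Series | None = None
    cluster_labels: dict = field(default_factory=dict)
    survival_tests: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    stages_completed: list = field(default_factory=list)


def _mine_platform(expr, cfg: PipelineConfig, platform, prefix):
    miner = LmQCM(gamma=cfg.gamma, t=cfg.t, alpha=cfg.alpha, beta=cfg.beta,
                  min_module_size=cfg.min_module_size,
                  spectral_norm=cfg.spectral_norm, platform=platform,
                  prefix=prefix, genes_as_rows=True)
    miner.fit(expr)
    return miner.modules_


def _cluster_and_test(features: pd.DataFrame, clinical: pd.DataFrame,
                      n_clusters, K, mu, seed, name, bundle):
    """Spectral-cluster samples on a feature table and log-rank the groups."""
    if features.shape[1] == 0:
        logger.warning("%s: no features; skipping clustering", name)
        return
    W = affinity_kernel(features, K=K, mu=mu)
    labels = spectral_cluster(W, n_clusters, seed=seed)
    bundle.cluster_labels[name] = pd.Series(labels, index=features.index)
    try:
        res = logrank_test(clinical["time"], clinical["event"], labels)
        bundle.survival_tests[name] = {
            "statistic": res.statistic, "df": res.df, "p_value": res.p_value,
            "log_p": res.log_p}
    except ValueError as exc:
        logger.warning("%s: log-rank not possible (%s)", name, exc)


def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    bundle = ResultsBundle()
    t0 = _time.time()

    def done(stage):
        bundle.stages_completed.append(stage)
        logger.info("stage %-12s %.1fs", stage, _time.time() - t0)

    # ---- inputs -----------------------------------------------------
    if config.simulate is not None:
        cohort = generate_cohort(config.simulate)
        expr1, expr2, clinical = cohort.expr1, cohort.expr2, cohort.clinical
        bundle.provenance["simulated"] = True
    else:
        if not (config.expression1 and config.expression2 and config.clinical):
            raise ValueError("provide either a simulation block or all three "
                             "input paths")
        expr1 = gio.read_expression(config.expression1)
        expr2 = gio.read_expression(config.expression2)
        clinical = gio.read_clinical(config.clinical)
        gio.check_sample_alignment(expr1, clinical)
        gio.check_sample_alignment(expr2, clinical)
    if config.cohort_filter == "high_risk":
        if "group" not in clinical.columns:
            raise ValueError("cohort_filter=high_risk needs a 'group' column")
        clinical = clinical[clinical["group"] == "high_risk"].reset_index(drop=True)
        expr1 = expr1[clinical["sample_id"]]
        expr2 = expr2[clinical["sample_id"]]
    clinical = clinical.reset_index(drop=True)
    ids = list(clinical["sample_id"])
    expr1 = expr1[ids]
    expr2 = expr2[ids]
    bundle.provenance.update(config=_config_dict(config),
                             n_samples=len(ids),
                             n_genes=[expr1.shape[0], expr2.shape[0]])
    done("input")

    # ---- mining -----------------------------------------------------
    p1, p2 = config.platform1, config.platform2
    bundle.modules1 = _mine_platform(expr1, config, p1, p1[0].upper())
    bundle.modules2 = _mine_platform(expr2, config, p2, p2[0].upper())
    done("mine")
    if not bundle.modules1 or not bundle.modules2:
        logger.warning("no modules on at least one platform; stopping after "
                       "mining")
        return bundle

    # ---- eigengenes -------------------------------------------------
    bundle.eigengenes1 = eigengene_matrix(expr1, bundle.modules1)
    bundle.eigengenes2 = eigengene_matrix(expr2, bundle.modules2)
    done("eigengenes")

    # ---- uniqueness + coherence ------------------------------------
    universe = sorted(set(expr1.index) & set(expr2.index))
    res1, res2 = unique_modules(bundle.modules1, bundle.modules2, universe,
                                config.jaccard_threshold,
                                config.fisher_threshold)
    bundle.uniqueness = uniqueness_frame(res1 + res2)
    rng = np.random.default_rng(config.seed)
    coh_rows = []
    for expr, mods in ((expr1, bundle.modules1), (expr2, bundle.modules2)):
        W = spearman_weight_matrix(expr)
        A = W.to_numpy()
        np.fill_diagonal(A, 1.0)
        Wd = pd.DataFrame(A, index=W.index, columns=W.columns)
        for m in mods:
            c = correlation_index_p(expr, m, n_perm=config.n_perm,
                                    seed=int(rng.integers(2**31)),
                                    weight_matrix=Wd)
            coh_rows.append({"module": m.label, "platform": m.platform,
                             "K": c.K, "C": c.C, "p": c.p})
    bundle.coherence = pd.DataFrame(coh_rows)
    done("compare")

    # ---- lasso-Cox selection per platform --------------------------
    def select(eig: pd.DataFrame, tag):
        X = eig.T.loc[ids]
        if config.selection_mode == "consensus":
            loo = loocv_risk_indices(X, clinical,
                                     inner_folds=config.inner_folds,
                                     penalty_rule=config.penalty_rule,
                                     seed=config.seed, outer=config.outer)
            selected = sorted(consensus_selection(
                loo.fold_selected, config.consensus_threshold))
            risk = loo.risk_index
        else:
            model = lasso_cox_fit(X, clinical,
                                  inner_folds=config.inner_folds,
                                  penalty_rule=config.penalty_rule,
                                  seed=config.seed)
            selected = sorted(model.selected_features)
            risk = model.risk_index(X)
        logger.info("%s: selected %d / %d eigengenes", tag, len(selected),
                    eig.shape[0])
        return selected, risk

    bundle.selected1, bundle.risk_index1 = select(bundle.eigengenes1, p1)
    bundle.selected2, bundle.risk_index2 = select(bundle.eigengenes2, p2)
    done("select")

    # ---- fusion feature set ----------------------------------------
    uniq = {row["module"]: row["unique"]
            for _, row in bundle.uniqueness.iterrows()}
    coh = {row["module"]: row["C"] for _, row in bundle.coherence.iterrows()}
    fus1 = list(bundle.selected1)
    fus2 = list(bundle.selected2)
    if config.dedup_shared != "keep_both":
        mod1 = {m.label: m for m in bundle.modules1}
        mod2 = {m.label: m for m in bundle.modules2}
        drop1, drop2 = set(), set()
        for a in bundle.selected1:
            for b in bundle.selected2:
                if uniq.get(a, True) and uniq.get(b, True):
                    continue
                from .compare import jaccard_index
                j = jaccard_index(mod1[a].genes, mod2[b].genes)
                if j >= config.jaccard_threshold:
                    # a selected-but-shared cross-platform pair
                    if config.dedup_shared == "drop_both":
                        drop1.add(a)
                        drop2.add(b)
                    elif coh.get(a, 0.0) >= coh.get(b, 0.0):
                        drop2.add(b)
                    else:
                        drop1.add(a)
        fus1 = [m for m in fus1 if m not in drop1]
        fus2 = [m for m in fus2 if m not in drop2]
    bundle.fusion_features1 = fus1
    bundle.fusion_features2 = fus2
    done("fusion-set")

    # ---- clustering + survival tests -------------------------------
    eig1s = bundle.eigengenes1.T.loc[ids]
    eig2s = bundle.eigengenes2.T.loc[ids]
    clus_args = dict(K=config.snf_K, mu=config.snf_mu, seed=config.seed)
    _cluster_and_test(eig1s, clinical, config.clusters_platform,
                      name=f"{p1}_all", bundle=bundle, **clus_args)
    _cluster_and_test(eig2s, clinical, config.clusters_platform,
                      name=f"{p2}_all", bundle=bundle, **clus_args)
    _cluster_and_test(eig1s[bundle.selected1], clinical,
                      config.clusters_platform, name=f"{p1}_selected",
                      bundle=bundle, **clus_args)
    _cluster_and_test(eig2s[bundle.selected2], clinical,
                      config.clusters_platform, name=f"{p2}_selected",
                      bundle=bundle, **clus_args)
    if fus1 and fus2:
        W1 = affinity_kernel(eig1s[fus1], K=config.snf_K, mu=config.snf_mu)
        W2 = affinity_kernel(eig2s[fus2], K=config.snf_K, mu=config.snf_mu)
        fused = snf_fuse([W1, W2], K=config.snf_K, t=config.snf_t)
        labels = spectral_cluster(fused, config.clusters_fused,
                                  seed=config.seed)
        bundle.cluster_labels["fused"] = pd.Series(labels, index=ids)
        try:
            res = logrank_test(clinical["time"], clinical["event"], labels)
            bundle.survival_tests["fused"] = {
                "statistic": res.statistic, "df": res.df,
                "p_value": res.p_value, "log_p": res.log_p}
        except ValueError as exc:
            logger.warning("fused: log-rank not possible (%s)", exc)
        bundle.provenance["fused_matrix"] = fused
    else:
        logger.warning("empty fusion feature set on a platform; SNF skipped")
    done("integrate")

    if config.out_dir:
        _write_bundle(bundle, clinical, config)
    return bundle


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    if d.get("simulate") is not None:
        sim = d["simulate"]
        for key in ("shared_modules", "unique_modules_platform1",
                    "unique_modules_platform2"):
            sim[key] = [list(x) if isinstance(x, (tuple, list)) else
                        [x.size, x.correlation] for x in
                        getattr(config.simulate, key)]
        d["simulate"] = sim
    return d


def _write_bundle(bundle: ResultsBundle, clinical: pd.DataFrame,
                  config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gio.write_modules_gmt(bundle.modules1, out / "modules_platform1.gmt")
    gio.write_modules_gmt(bundle.modules2, out / "modules_platform2.gmt")
    if bundle.eigengenes1 is not None:
        gio.write_matrix_tsv(bundle.eigengenes1, out / "eigengenes_platform1.tsv",
                             index_name="module")
        gio.write_matrix_tsv(bundle.eigengenes2, out / "eigengenes_platform2.tsv",
                             index_name="module")
    if bundle.uniqueness is not None:
        bundle.uniqueness.to_csv(out / "uniqueness.tsv", sep="\t", index=False)
    if bundle.coherence is not None:
        bundle.coherence.to_csv(out / "coherence.tsv", sep="\t", index=False)
    if bundle.risk_index1 is not None:
        pd.DataFrame({"sample_id": bundle.risk_index1.index,
                      "risk_platform1": bundle.risk_index1.to_numpy(),
                      "risk_platform2": bundle.risk_index2.to_numpy()}
                     ).to_csv(out / "risk_indices.tsv", sep="\t", index=False)
    labels = pd.DataFrame({"sample_id": clinical["sample_id"]})
    for name, ser in bundle.cluster_labels.items():
        labels[name] = ser.to_numpy()
    labels.to_csv(out / "cluster_labels.tsv", sep="\t", index=False)
    fused = bundle.provenance.get("fused_matrix")
    if fused is not None:
        gio.write_matrix_tsv(fused, out / "fused_network.tsv",
                             index_name="sample_id")
    report = {
        "selected": {"platform1": bundle.selected1,
                     "platform2": bundle.selected2},
        "fusion_features": {"platform1": bundle.fusion_features1,
                            "platform2": bundle.fusion_features2},
        "survival_tests": bundle.survival_tests,
        "stages_completed": bundle.stages_completed,
        "provenance": {k: v for k, v in bundle.provenance.items()
                       if k != "fused_matrix"},
    }
    gio.write_report(report, out / "report.json")
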