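# gcnsurv

Integrative survival analysis for tumor cohorts profiled on **two
transcriptomic platforms** (e.g. microarray and RNA-seq of the same
patients). The package mines co-expressed gene modules on each platform,
summarizes them into per-patient *eigengenes*, identifies which modules are
platform-unique, selects survival-associated eigengenes with a
cross-validated lasso-Cox model, and fuses per-platform patient-similarity
networks with Similarity Network Fusion (SNF) to stratify patients into
prognostic subgroups. It ships a synthetic-cohort generator with planted
module and hazard structure, so every stage can be validated against known
ground truth.

Intended users: computational biologists studying multi-platform bulk
transcriptomics of clinically annotated cohorts (the motivating application
is high-risk neuroblastoma survival prognosis), and methodologists who need
a tested reference implementation of the lmQCM → eigengene → lasso-Cox →
SNF workflow.

## Methods at a glance

- **Co-expression network**: edge weights `w_ij = |Spearman ρ(g_i, g_j)|`
  across patients; an optional spectral-style rescaling
  `w_ij / sqrt(d_i d_j)` is available.
- **lmQCM module mining**: greedy quasi-clique expansion seeded at locally
  maximal edges with weight ≥ γ (default 0.80); a vertex joins while the
  subgraph density stays above the adaptive bound
  `γ·(1 − 1/(2α(k + t)))` (α = 1, t = 1); candidates merge when
  `|A∩B|/min(|A|,|B|) ≥ β` (β = 0.4). Modules may overlap.
- **Eigengene**: first principal-component score of the z-scored module
  submatrix, unit variance, sign aligned with the module mean profile.
- **Module uniqueness**: a module is unique to its platform when, against
  *every* module of the other platform, Jaccard < 0.05 and the one-sided
  hypergeometric (Fisher) overlap p > 0.05.
- **Coherence (Correlation Index)**: `C = ‖W − I_K‖_F² / K²` on the
  module's absolute-Spearman matrix, with an empirical p-value from
  size-matched random gene sets, `p = #(C* > C)/n_perm`.
- **Survival selection**: L1-penalized Cox proportional hazards over a
  penalty path, penalty chosen by k-fold cross-validated partial-likelihood
  deviance (min or one-standard-error rule); optional leave-one-out outer
  loop with consensus feature selection; patients are dichotomized at the
  training-median risk index and compared by Kaplan–Meier / log-rank.
- **Integration**: per-platform patient networks from a locally scaled
  exponential kernel (K = 30 neighbors, μ = 0.8), fused by t = 20 rounds of
  SNF cross-diffusion `W̃⁽¹⁾ ← S⁽¹⁾ W̃⁽²⁾ S⁽¹⁾ᵀ`, then spectral clustering
  on the fused network.

See `docs/methods.md` for assumptions, parameter choices and limitations.

## Worked example

```python
from gcnsurv import CohortConfig, PipelineConfig, run_pipeline

config = PipelineConfig(
    simulate=CohortConfig(seed=42),   # 200 patients, 500 genes/platform,
                                      # 2 shared + 1 unique module each side,
                                      # hazard on the unique factors
    selection_mode="full",            # single cross-validated lasso-Cox fit
    clusters_fused=4,
    seed=42,
)
bundle = run_pipeline(config)

print([m.label for m in bundle.modules1], [m.label for m in bundle.modules2])
print(bundle.selected1, bundle.selected2)
for name, test in bundle.survival_tests.items():
    print(f"log-rank {name:22s} chi2={test['statistic']:.2f} "
          f"p={test['p_value']:.3g}")
```

Output:

```
['M1', 'M2', 'M3'] ['R1', 'R2', 'R3']
['M3'] ['R3']
log-rank microarray_all         chi2=1.16 p=0.282
log-rank rnaseq_all             chi2=5.28 p=0.0216
log-rank microarray_selected    chi2=49.89 p=1.63e-12
log-rank rnaseq_selected        chi2=30.24 p=3.82e-08
log-rank fused                  chi2=128.70 p=1.03e-27
```

Both platforms recover the two shared planted modules (M1/R1, M2/R2 —
flagged non-unique, cross-platform Jaccard 1.0) and their own unique module
(M3, R3 — Jaccard 0 against the other platform). The lasso-Cox step selects
exactly the hazard-driving unique eigengenes. Clustering patients on *all*
eigengenes dilutes the survival signal (p ≈ 0.28 and 0.02); clustering on
the selected eigengene sharpens it by several orders of magnitude; and SNF
fusion of the two platform-unique signals, each invisible to the other
platform, gives the strongest stratification (p ≈ 1e-27) — the integration
benefit the workflow is built around.

The same stages are exposed as a CLI
(`gcnsurv simulate | mine | eigengenes | compare | select | km | fuse | run`);
`gcnsurv run --config pipeline.yaml` executes the full workflow from a YAML
file.

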