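# Methods

## Overview

gcnsurv implements a two-platform integrative survival workflow: weighted
gene co-expression networks → lmQCM module mining → eigengene
summarization → cross-platform module comparison → lasso-Cox survival
feature selection → Similarity Network Fusion (SNF) and spectral
clustering. This note records the models, the parameter choices that
matter, the numerical conventions, and what the synthetic validation does
and does not establish.

## Co-expression network and lmQCM mining

The network over genes uses absolute Spearman rank correlation, which is
invariant to monotone transforms and therefore tolerant of the wide
non-linear dynamic range of RNA-seq. The diagonal is set to zero so
self-edges never enter mining. A spectral-clustering-style rescaling
`w_ij / sqrt(d_i d_j)` (`normalize_weights`) is provided; it damps hub
genes but also shrinks every weight roughly by the network degree, so a
seed threshold calibrated for raw correlations (γ = 0.80) can never fire
on a normalized matrix of realistic size. The pipeline therefore mines the
**raw** absolute-correlation matrix by default; `spectral_norm=True`
switches matrices, in which case γ must be re-calibrated by the user. The
seed threshold always applies to the matrix actually passed to the miner.

Mining follows the quasi-clique-merging scheme:

1. **Seeds** — edges with weight ≥ γ that are local maxima (at least as
   heavy as every edge sharing an endpoint), processed by descending
   weight.
2. **Growth** — repeatedly add the outside vertex with the largest total
   weight to the current members; accept while the enlarged subgraph's
   weighted density (mean edge weight) stays at or above the adaptive
   bound `γ·(1 − 1/(2α(k + t)))`, where `k` is the enlarged size. The
   γ factor makes the bound a *relative* density requirement: clusters of
   genes correlated at about the seed level keep growing, while the
   `1/(2α(k+t))` term forgives small deficits in small clusters and
   tightens asymptotically to γ. Without the γ factor the bound would
   exceed any realistic correlation level already at k = 3 and no module
   of moderate coherence could form.
3. **Filter and merge** — grown candidates below `min_module_size`
   (default 10) are dropped; remaining candidates merge whenever the
   overlap relative to the smaller module is ≥ β, repeated to a fixed
   point, so mined modules may share genes.

Ties (equal-gain vertices, equal-weight seeds, equal-size modules) break
toward the lexicographically smallest gene label, which makes the output
exactly invariant to gene order. Defaults γ = 0.80, t = 1, α = 1, β = 0.4
are the workflow's standard operating point for transcriptomic cohorts.

## Eigengenes

Each module is summarized by the first principal component of its z-scored
(per gene: mean 0, sample-SD 1 with the n−1 convention) expression
submatrix, computed by SVD, rescaled to unit sample variance across
patients. The PC sign is chosen so the eigengene correlates non-negatively
with the module's mean z-scored profile; this removes the inherent sign
ambiguity deterministically. Zero-variance genes z-score to zero rows; an
all-constant module yields a zero eigengene with a warning.
`EigengeneTransformer` freezes gene statistics and PC loadings on training
samples so held-out patients can be projected without leakage.

## Module comparison

*Uniqueness.* A module is unique to its platform when against every module
of the other platform the Jaccard index is < 0.05 and the one-sided
hypergeometric overlap p-value is > 0.05 (no significant shared
membership). The gene universe is the set of symbols present on both
platforms. The worst-case partner (largest Jaccard) is recorded. No
multiple-testing correction is applied: the screen is deliberately
permissive, since "unique" requires failing to overlap *everything* on the
other side.

*Coherence.* The Correlation Index of a module of K genes with absolute
Spearman matrix W (unit diagonal) is `C = ‖W − I‖_F²/K²`, i.e. the mean
squared off-diagonal correlation up to the K²-normalization. Its null
p-value draws size-matched gene sets uniformly from all genes of the
dataset (`p = #(C* > C)/n_perm`, strict inequality, ties not counted).
Sampling dataset-wide is the only self-consistent null: drawing K genes
from within a K-gene module would reproduce the module itself. Under the
null, `P(p ≤ 0.05)` is `(⌊0.05·n_perm⌋+1)/(n_perm+1)` ≈ 0.055 rather than
exactly 0.05 — the usual discreteness of permutation p-values.

*Stability.* Module coherence generalizes across patients: C computed on a
held-out sample split is compared to the distribution of C over random
size-matched gene sets on the same split. A real module sits in the upper
tail; this is the train/test concordance check used to argue that mined
modules are not artifacts of a particular cohort split.

## Survival modelling

`CoxnetSelector` fits an L1-penalized Cox proportional-hazards model along
a decreasing penalty path (coordinate descent via scikit-survival) and
picks the penalty by k-fold (default 10) cross-validated
partial-likelihood deviance, computed with the Verweij–van Houwelingen
construction `−2(ℓ_full(β̂_fold) − ℓ_train(β̂_fold))` and Breslow tie
handling. Two rules are exposed: `"min"` (deviance-minimizing penalty, the
estimator default) and `"1se"` (strongest penalty within one standard
error of the minimum). The pipeline defaults to `"1se"`: on cohorts with
few informative eigengenes the min rule habitually retains most noise
features (which defeats the point of a sparse survival signature and
washes out the selected-versus-all clustering comparison), while the 1se
rule selects the informative features essentially always and nothing under
a null in our validation experiments. The penalty path stops at
`alpha_min_ratio = 0.05` of the largest penalty: with longer paths the
near-unpenalized end of the path occasionally wins the CV deviance by
chance on pure-noise data, defeating even the 1se guard.

An outer loop (`loocv_risk_indices`; leave-one-out by contract, k-fold as
a cheaper option) produces honest per-patient risk indices: each held-out
patient is scored by a model that never saw them and assigned low/high by
that training fit's median risk (ties go low). Features selected in ≥ 50%
of outer folds form the consensus signature. Whether the final signature
comes from the consensus or from a single full-data fit is configurable
(`selection_mode`), since both are defensible; consensus is the default.

Kaplan–Meier curves and the g-sample log-rank test are delegated to
lifelines; `logrank_test` additionally reports the exact natural-log
p-value via the chi-square log survival function, because fused-network
stratifications routinely reach p below double-precision underflow and
comparisons between stratifications must happen on the log scale.

## Similarity Network Fusion

Per-platform patient similarities come from the locally scaled exponential
kernel `W(i,j) = exp(−d²/(μ·ε_ij))` with Euclidean distance on eigengene
features and `ε_ij` the mean of the two patients' mean K-nearest-neighbor
distances and their own distance. Fusion uses the printed two-view
recurrence: full kernels are row-normalized to 1/2 off-diagonal mass and
1/2 on the diagonal (rows sum to exactly 1); the sparse diffusion operator
keeps each row's K nearest neighbors normalized to sum 1/2 (a deliberate
divergence from the original SNF scaling of 1 — harmless here because
every round ends with the full re-normalization); each round computes
`S⁽¹⁾W̃⁽²⁾S⁽¹⁾ᵀ` and vice versa simultaneously, symmetrizes, and
re-normalizes — the symmetrization/re-normalization is not part of the
bare recurrence but is required for numerical stability and is standard
practice. After t rounds the two states are averaged and symmetrized.
Defaults K = 30, μ = 0.8, t = 20; K is clamped to n−1 with a warning on
small cohorts. Exactly two views are supported by contract.

Spectral clustering embeds patients with the top eigenvectors of
`D^{−1/2} W D^{−1/2}`, row-normalizes the embedding, and runs k-means with
a fixed seed and 50 restarts, so labels are a deterministic function of
the network and the seed. A disconnected network with more components than
clusters triggers a warning but still returns labels.

The pipeline's fusion feature set starts from each platform's selected
eigengenes and removes redundancy among selected-but-shared cross-platform
pairs (keeping the copy whose module has the higher Correlation Index on
its own platform, by default); platform-unique selected eigengenes always
survive. The number of fused strata defaults to 3 — one more than the
binary low/high split, reflecting that fusing complementary risk factors
can isolate an extra extreme-risk subgroup.

## Synthetic cohorts

The generator plants single-latent-factor modules: per module a factor
f ~ N(0,1) across patients (standardized to exact zero mean / unit
variance so the realized correlation level matches the configured target
rather than fluctuating with the factor's sampled variance), gene
loadings uniform on [0.6, 1] with random signs, and per-gene Gaussian
noise scaled so every within-module pair has Pearson correlation
`2·sin(π·ρ_S/6)` — the Gaussian-copula value whose Spearman correlation is
the configured target ρ_S (default 0.8). Correlation targets are specified
on the Spearman scale because that is the statistic the mining stage
consumes. Shared modules reuse the same factor on both platforms;
platform-unique modules plant the factor on one platform while the same
gene symbols are independent noise on the other; background genes are
independent N(0, noise_sd²).

Survival times are exponential with rate `λ₀·exp(Σ β_m f_m)` (default
baseline 0.01 events/month, i.e. ~70-month median at lp = 0); censoring
times are uniform on (0, c_max) with c_max solved by root-finding so the
expected censoring fraction matches the target (default 0.3). Default
cohort: 200 patients, 500 genes per platform, two shared modules (30 and
20 genes) plus one 15-gene unique module per platform, with hazard β = 1
on the two unique factors — a desk-scale analogue of a paired-platform
tumor cohort in which each platform carries private prognostic signal.

What the generator does **not** emulate: probe effects, library-size or
count-distribution artifacts, batch structure, overlapping planted
modules, non-proportional hazards, or informative censoring. Passing
tests therefore demonstrate correctness of the algorithms under the
latent-factor proportional-hazards model, not robustness to real-platform
technical noise; matrices are continuous-valued as the pipeline consumes
them post-preprocessing, and probe-to-gene summarization is upstream of
this package.

## Validation experiment design

The validation suite (tests and `scripts/acceptance.py`) uses fixed
problem sizes chosen to make each property measurable in minutes on one
CPU: module recovery on 500 genes × 200 patients with planted sizes
30/20/15; miner-vs-brute-force agreement on 100 random graphs of ≤ 8
nodes; permutation-p calibration over 200 null replicates at n_perm = 200;
lasso-Cox selection rates over 50 replicate cohorts with 9 eigengenes (2
informative at β = 1, n = 300), using a 5-fold outer consensus; log-rank
null calibration over 500 cohorts of n = 200; and the integration
experiment over 20 replicate cohorts (150 patients, 300 genes/platform,
three shared noise modules, one hazard-driving unique module per platform,
β = 1, 30% censoring). In the integration experiment, per-platform
clusterings use 2 groups while the fused network is cut into 4: the
planted risk surface has two independent factors, so its natural coarse
geometry is the four quadrants (low/low … high/high), and an even cut
avoids splitting along an arbitrary direction of the symmetric
two-factor plane. p-values are compared as geometric means on the exact
log scale.

## Known limitations

- Two platforms only; the SNF recurrence generalizes to m views but the
  implementation deliberately does not.
- The miner's greedy growth stops at the first rejected vertex; it does
  not backtrack, matching the reference algorithm but meaning very uneven
  module densities can truncate growth early.
- `correlation_index_p` recomputes nothing across modules unless a
  precomputed weight matrix is supplied; the pipeline supplies one.
- The lasso-Cox CV deviance uses fold-wise standard errors across k folds;
  with very few events per fold the 1se rule becomes conservative.
- Eigengene projection of held-out samples assumes the training gene
  statistics transfer; under strong batch effects this is optimistic.
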