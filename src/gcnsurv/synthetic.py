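"""Synthetic paired-platform cohorts with planted modules and survival.

The generator emulates a tumor cohort profiled on two transcriptomic
platforms that share a gene-symbol universe: co-expressed modules are
planted as single-latent-factor blocks (gene = loading × factor +
noise), some modules share their factor across both platforms, some are
platform-unique (the same gene symbols are independent noise on the
other platform), and survival times follow an exponential
proportional-hazards model whose linear predictor is a weighted sum of
selected module factors, with independent uniform right censoring
calibrated to a target censoring fraction.

Within-module correlation targets are specified on the Spearman scale
(the statistic the mining stage consumes); for the Gaussian factor
model the corresponding Pearson correlation is 2·sin(π·ρ_S/6).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .lmqcm import GeneModule

__all__ = ["ModuleSpec", "CohortConfig", "SyntheticCohort", "generate_cohort",
           "truth_overlap"]


@dataclass(frozen=True)
class ModuleSpec:
    """Size and within-module Spearman correlation target of one planted module."""

    size: int
    correlation: float = 0.8

    def __post_init__(self):
        if self.size < 2:
            raise ValueError("module size must be ≥ 2")
        if not 0 < self.correlation <= 1:
            raise ValueError("correlation target must be in (0, 1]")


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a desk-scale analogue of a paired-platform tumor
    cohort: 200 patients, 500 genes per platform, two shared modules and
    one unique module per platform at Spearman 0.8, a single unique
    module per platform driving hazard, exponential baseline hazard of
    0.01 events/month and 30% censoring.
    """

    n_samples: int = 200
    n_genes_per_platform: int = 500
    shared_modules: tuple = (ModuleSpec(30), ModuleSpec(20))
    unique_modules_platform1: tuple = (ModuleSpec(15),)
    unique_modules_platform2: tuple = (ModuleSpec(15),)
    hazard_coefficients: dict = field(
        default_factory=lambda: {"U1_1": 1.0, "U2_1": 1.0})
    baseline_hazard: float = 0.01
    censoring_rate_target: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    def module_labels(self):
        shared = [f"S{i+1}" for i in range(len(self.shared_modules))]
        u1 = [f"U1_{i+1}" for i in range(len(self.unique_modules_platform1))]
        u2 = [f"U2_{i+1}" for i in range(len(self.unique_modules_platform2))]
        return shared, u1, u2

    def validate(self) -> None:
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples")
        if self.baseline_hazard <= 0 or self.noise_sd <= 0:
            raise ValueError("baseline_hazard and noise_sd must be positive")
        if not 0 <= self.censoring_rate_target < 1:
            raise ValueError("censoring_rate_target must be in [0, 1)")
        shared, u1, u2 = self.module_labels()
        size1 = sum(m.size for m in self.shared_modules) + \
            sum(m.size for m in self.unique_modules_platform1) + \
            sum(m.size for m in self.unique_modules_platform2)
        if size1 > self.n_genes_per_platform:
            raise ValueError(
                f"planted module sizes ({size1}) exceed genes per platform "
                f"({self.n_genes_per_platform})")
        known = set(shared + u1 + u2)
        unknown = set(self.hazard_coefficients) - known
        if unknown:
            raise ValueError(f"hazard coefficients for unknown modules: {sorted(unknown)}")


@dataclass
class SyntheticCohort:
    """Generated cohort plus the planted ground truth."""

    expr1: pd.DataFrame  # genes × samples, platform 1
    expr2: pd.DataFrame  # genes × samples, platform 2
    clinical: pd.DataFrame  # columns: sample_id, time, event
    truth_modules1: dict  # module label → gene list planted on platform 1
    truth_modules2: dict
    factors: pd.DataFrame  # module label × samples latent factors
    hazard_coefficients: dict
    config: CohortConfig = None

    @property
    def sample_ids(self):
        return list(self.clinical["sample_id"])


def _planted_block(rng, spec: ModuleSpec, factor: np.ndarray) -> np.ndarray:
    """Gene block following gene = a·f + σ·ε with exact pairwise Pearson
    correlation 2 sin(π ρ_S / 6); loadings U[0.6, 1] with random signs."""
    size, n = spec.size, factor.size
    rho_p = min(1.0, 2.0 * np.sin(np.pi * spec.correlation / 6.0))
    loadings = rng.uniform(0.6, 1.0, size) * rng.choice([-1.0, 1.0], size)
    if rho_p >= 1.0:
        noise_scale = np.zeros(size)
    else:
        noise_scale = np.abs(loadings) * np.sqrt((1.0 - rho_p) / rho_p)
    eps = rng.standard_normal((size, n))
    return loadings[:, None] * factor[None, :] + noise_scale[:, None] * eps


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a paired-platform cohort; fully reproducible from the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    p = config.n_genes_per_platform
    samples = [f"P{i+1:04d}" for i in range(n)]
    genes = [f"G{i+1:05d}" for i in range(p)]

    shared_lab, u1_lab, u2_lab = config.module_labels()
    all_specs = (list(zip(shared_lab, config.shared_modules)) +
                 list(zip(u1_lab, config.unique_modules_platform1)) +
                 list(zip(u2_lab, config.unique_modules_platform2)))
    # factors are standardized to exact zero mean / unit variance so the
    # realized within-module correlation matches the configured target
    factors = {}
    for lab, _ in all_specs:
        f = rng.standard_normal(n)
        factors[lab] = (f - f.mean()) / f.std()

    # assign disjoint gene blocks to modules, in declaration order
    cursor = 0
    assignment: dict[str, list[str]] = {}
    for lab, spec in all_specs:
        assignment[lab] = genes[cursor:cursor + spec.size]
        cursor += spec.size

    gene_pos = {g: i for i, g in enumerate(genes)}

    def build_platform(planted_labels):
        X = rng.normal(0.0, config.noise_sd, (p, n))
        for lab, spec in all_specs:
            if lab in planted_labels:
                idx = [gene_pos[g] for g in assignment[lab]]
                X[idx, :] = _planted_block(rng, spec, factors[lab])
        return pd.DataFrame(X, index=genes, columns=samples)

    expr1 = build_platform(set(shared_lab) | set(u1_lab))
    expr2 = build_platform(set(shared_lab) | set(u2_lab))

    lp = np.zeros(n)
    for lab, beta in config.hazard_coefficients.items():
        lp += beta * factors[lab]
    rate = config.baseline_hazard * np.exp(lp)
    T = rng.exponential(1.0 / rate)

    q = config.censoring_rate_target
    if q <= 0:
        time, event = T, np.ones(n, dtype=int)
    else:
        # censored iff C < T with C ~ U(0, c_max); expected fraction is
        # mean_i min(T_i / c_max, 1) — solve for c_max, then draw C
        def frac(c_max):
            return float(np.mean(np.minimum(T / c_max, 1.0))) - q

        hi = float(T.max()) / max(q, 1e-9) + 1.0
        c_max = brentq(frac, 1e-12, hi)
        C = rng.uniform(0.0, c_max, n)
        event = (T <= C).astype(int)
        time = np.minimum(T, C)
    time = np.maximum(time, 1e-9)

    clinical = pd.DataFrame({"sample_id": samples, "time": time, "event": event})
    truth1 = {lab: assignment[lab] for lab in shared_lab + u1_lab}
    truth2 = {lab: assignment[lab] for lab in shared_lab + u2_lab}
    fac = pd.DataFrame({lab: factors[lab] for lab, _ in all_specs},
                       index=samples).T
    return SyntheticCohort(expr1, expr2, clinical, truth1, truth2, fac,
                           dict(config.hazard_coefficients), config)


def truth_overlap(truth_modules, found_modules) -> pd.DataFrame:
    """Jaccard ratio between every planted set and every mined module.

    ``truth_modules`` is a mapping label → gene collection (or a list of
    gene collections); ``found_modules`` a list of
    :class:`~gcnsurv.lmqcm.GeneModule` or gene collections. Entry (i, j)
    is |truth_i ∩ found_j| / |truth_i ∪ found_j|.
    """
    if not isinstance(truth_modules, dict):
        truth_modules = {f"T{i+1}": m for i, m in enumerate(truth_modules)}
    truth_sets = {k: set(v) for k, v in truth_modules.items()}
    found = {}
    for i, m in enumerate(found_modules):
        if isinstance(m, GeneModule):
            found[m.label] = set(m.genes)
        else:
            found[f"F{i+1}"] = set(m)
    for name, s in list(truth_sets.items()) + list(found.items()):
        if not s:
            raise ValueError(f"empty module {name!r}: Jaccard undefined")
    out = pd.DataFrame(index=list(truth_sets), columns=list(found), dtype=float)
    for ti, ts in truth_sets.items():
        for fi, fs in found.items():
            out.loc[ti, fi] = len(ts & fs) / len(ts | fs)
    return out
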