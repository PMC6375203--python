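import numpy as np
import pandas as pd
import pytest

from gcnsurv.synthetic import CohortConfig, ModuleSpec, generate_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """Small paired cohort: 2 shared + 1 unique-per-platform modules, with
    hazard driven by the platform-unique factors."""
    cfg = CohortConfig(
        n_samples=120, n_genes_per_platform=200,
        shared_modules=(ModuleSpec(20, 0.8), ModuleSpec(15, 0.8)),
        unique_modules_platform1=(ModuleSpec(12, 0.8),),
        unique_modules_platform2=(ModuleSpec(12, 0.8),),
        hazard_coefficients={"U1_1": 1.0, "U2_1": 1.0},
        censoring_rate_target=0.3, seed=7)
    return generate_cohort(cfg)


@pytest.fixture()
def toy_weight_frame():
    """6-gene graph: {a,b,c} pairwise 0.95, every other edge 0.10."""
    genes = list("abcdef")
    A = np.full((6, 6), 0.10)
    for i in range(3):
        for j in range(3):
            A[i, j] = 0.95
    np.fill_diagonal(A, 0.0)
    return pd.DataFrame(A, index=genes, columns=genes)
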