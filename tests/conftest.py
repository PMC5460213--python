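import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from zpage import ExpressionMatrix, SimConfig, simulate_cohort


def make_matrix(values, gene_symbols=None, sample_ids=None, groups=None,
                species="mouse") -> ExpressionMatrix:
    """Build a small ExpressionMatrix from a 2-D array of raw intensities."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_symbols = gene_symbols or [f"G{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samples)]
    groups = groups or ["young"] * n_samples
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_symbols, columns=sample_ids),
        species=species,
        age_groups=dict(zip(sample_ids, groups)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def random_matrix(rng) -> ExpressionMatrix:
    """200 genes x 10 samples of log-normal intensities, balanced age groups."""
    values = np.exp(rng.normal(5.0, 1.0, size=(200, 10)))
    groups = ["young"] * 4 + ["middle"] * 3 + ["old"] * 3
    return make_matrix(values, groups=groups)


@pytest.fixture
def null_cohort():
    """Four-species cohort with no planted effects (scaled-down universe)."""
    cfg = SimConfig(seed=7, n_genes=400, n_sets=20, set_size_range=(10, 20))
    matrices, truth = simulate_cohort(cfg)
    return cfg, matrices, truth
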