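import numpy as np
import pandas as pd
import pytest

from rifnet.core_io import ExpressionStudy


def make_study(values, gene_ids=None, n_s=None, seed=None):
    """Build an ExpressionStudy from a 2-D array; first n_s columns are treated."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if n_s is None:
        n_s = n_samples // 2
    if gene_ids is None:
        gene_ids = [f"g{i:03d}" for i in range(n_genes)]
    sample_ids = [f"S{i}" for i in range(n_s)] + [f"C{i}" for i in range(n_samples - n_s)]
    condition_of = {s: ("S" if s.startswith("S") else "C") for s in sample_ids}
    return ExpressionStudy(pd.DataFrame(values, index=gene_ids, columns=sample_ids), condition_of)


def random_study(rng, n_genes=20, n_s=5, n_c=5, mean_range=(6, 12), sd=1.0):
    mu = rng.uniform(*mean_range, size=n_genes)
    vals = mu[:, None] + sd * rng.standard_normal((n_genes, n_s + n_c))
    return make_study(vals, n_s=n_s)


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


@pytest.fixture
def small_study(rng):
    return random_study(rng, n_genes=12, n_s=5, n_c=5)
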