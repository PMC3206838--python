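import numpy as np
import pandas as pd
import pytest

from irstab import ExpressionStudy, BinaryContrast


def make_study(expr, study_id="t", phenotypes=None, gene_prefix="g", sample_prefix="s"):
    expr = np.asarray(expr, dtype=float)
    gene_ids = [f"{gene_prefix}{i:04d}" for i in range(expr.shape[0])]
    sample_ids = [f"{sample_prefix}{k:04d}" for k in range(expr.shape[1])]
    return ExpressionStudy(study_id, expr, gene_ids, sample_ids, phenotypes)


def make_contrast(study, labels, name="group1_vs_2"):
    return BinaryContrast(name, tuple(study.sample_ids),
                          tuple(int(y) for y in labels))


def noise_study(n_genes=200, n_samples=30, seed=0, loc=8.0, scale=1.0, **kw):
    rng = np.random.default_rng(seed)
    return make_study(rng.normal(loc, scale, (n_genes, n_samples)), **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_study(rng):
    """50 genes x 20 samples of correlated data (3 latent factors + noise)."""
    L = rng.normal(size=(50, 3))
    F = rng.normal(size=(3, 20)) * 2.0
    return make_study(L @ F + rng.normal(size=(50, 20)) + 8.0)


@pytest.fixture
def balanced_labels():
    return np.array([1, 2] * 10)
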