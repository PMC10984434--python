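import numpy as np
import pandas as pd
import pytest

from csfnet.containers import ExpressionMatrix
from csfnet.simulate import SimConfig, generate_cohorts


def make_matrix(x: np.ndarray, scale_tag: str = "residual",
                prefix: str = "P") -> ExpressionMatrix:
    """Wrap a plain array as an ExpressionMatrix with generated registries."""
    n, p = x.shape
    df = pd.DataFrame(x, index=[f"S{i:03d}" for i in range(n)],
                      columns=[f"{prefix}{j:04d}" for j in range(p)])
    return ExpressionMatrix(df, scale_tag)


def planted_blocks(rng: np.random.Generator, n_samples: int,
                   block_sizes: list[int], n_background: int = 0,
                   factor_sd: float = 1.0, noise_sd: float = 0.5):
    """Rank-1 correlated blocks plus background noise; returns (matrix, labels)."""
    p = sum(block_sizes) + n_background
    x = noise_sd * rng.standard_normal((n_samples, p))
    labels = np.zeros(p, dtype=int)
    pos = 0
    for m, size in enumerate(block_sizes, start=1):
        f = factor_sd * rng.standard_normal(n_samples)
        x[:, pos:pos + size] += f[:, None]
        labels[pos:pos + size] = m
        pos += size
    em = make_matrix(x)
    return em, pd.Series(labels, index=em.protein_ids, name="module")


@pytest.fixture(scope="session")
def small_cohorts():
    """One modest two-cohort dataset shared by read-only tests."""
    cfg = SimConfig(n_proteins=300, n_samples_discovery=110,
                    n_samples_replication=120, n_buffer_wells=10,
                    module_sizes=(60, 50, 40), module_cors=(0.6, 0.6, 0.6),
                    preserved_flags=(True, True, False), n_junk_proteins=30,
                    seed=7)
    return cfg, generate_cohorts(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
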