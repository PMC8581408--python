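import numpy as np
import pandas as pd
import pytest

from fusreg import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 300-gene desk dataset shared by read-only tests."""
    cfg = SimConfig(n_genes=300, seed=42)
    counts, samples, truth = simulate_dataset(cfg)
    return counts, samples, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_fit_table(genes, padj, coef):
    """Hand-built minimal FitTable for pooling tests."""
    df = pd.DataFrame(
        {
            "gene": genes,
            "padj": padj,
            "coef": coef,
            "pvalue": padj,
            "significant": [p < 0.05 if not np.isnan(p) else False for p in padj],
        }
    ).set_index("gene", drop=False)
    return df
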