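import numpy as np
import pandas as pd
import pytest

from autoscore.io import GeneSet, GeneSetCollection


@pytest.fixture
def four_gene_matrix() -> pd.DataFrame:
    """The 4-gene worked example: one sample with expression 4 > 3 > 2 > 1."""
    return pd.DataFrame(
        {"s1": [4.0, 3.0, 2.0, 1.0]}, index=["g1", "g2", "g3", "g4"]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_matrix(rng, n_genes=50, n_samples=10) -> pd.DataFrame:
    genes = [f"g{i:03d}" for i in range(n_genes)]
    samples = [f"s{i:02d}" for i in range(n_samples)]
    return pd.DataFrame(rng.normal(size=(n_genes, n_samples)), index=genes, columns=samples)


def random_set(rng, matrix, size, name="set") -> GeneSet:
    genes = tuple(rng.choice(matrix.index, size=size, replace=False))
    return GeneSet(name, "", genes)
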