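import numpy as np
import pandas as pd
import pytest

from plastiscore.data_io import ExpressionMatrix, GeneSet
from plastiscore.synthetic_data import SyntheticConfig, generate_bulk_dataset


def make_matrix(values, genes=None, samples=None, metadata=None) -> ExpressionMatrix:
    """Build an ExpressionMatrix from a 2-D array with default ids."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples),
        metadata=dict({"log_scale": True} if metadata is None else metadata),
    )


def random_matrix(rng, n_genes=50, n_samples=10, loc=8.0, scale=2.0) -> ExpressionMatrix:
    return make_matrix(rng.normal(loc, scale, size=(n_genes, n_samples)))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231107)


@pytest.fixture(scope="session")
def bulk_dataset():
    """A planted epithelial/hybrid/mesenchymal cohort shared across tests."""
    config = SyntheticConfig(seed=42, n_samples=90)
    return generate_bulk_dataset(config)


@pytest.fixture
def small_set():
    return GeneSet(name="SMALL", genes=frozenset({"G1", "G2", "G3"}))
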