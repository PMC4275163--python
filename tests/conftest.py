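import numpy as np
import pytest

from hirrecur.io_preprocess import ExpressionMatrix
from hirrecur.synthetic_data import SyntheticConfig, generate_paired_datasets


def make_matrix(values, feature_ids=None, symbols=None, sample_ids=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    if feature_ids is None:
        feature_ids = [f"F{i}" for i in range(n_feat)]
    if symbols is None:
        symbols = [f"G{i}" for i in range(n_feat)]
    if sample_ids is None:
        sample_ids = [f"S{j}" for j in range(n_samp)]
    return ExpressionMatrix(
        feature_ids=np.array(feature_ids, dtype=object),
        gene_symbols=np.array(symbols, dtype=object),
        sample_ids=np.array(sample_ids, dtype=object),
        values=values,
    )


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    return make_matrix([[1.0, 4.0], [2.0, 2.0], [3.0, 6.0]])


@pytest.fixture(scope="session")
def small_paired():
    """Three small paired datasets with a strong planted signal."""
    cfg = SyntheticConfig(
        n_genes=300,
        n_signature=30,
        n_datasets=3,
        pairs_per_dataset=8,
        prior_rate_b=8.0,
        injury_effect=1.5,
        seed=11,
    )
    datasets, truth = generate_paired_datasets(cfg)
    return cfg, datasets, truth
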