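import numpy as np
import pytest

from metarecover import ExpressionMatrix, MetadataTable, SyntheticConfig, generate
from metarecover.synthdata import truth_labels


@pytest.fixture(scope="session")
def small_signal_data():
    """Small dataset with strong, learnable signal (shared across tests)."""
    cfg = SyntheticConfig(
        n_samples=150, n_genes=300, n_informative=20, effect_size=2.0,
        minority_fraction=0.3, noise_sd=0.5, missing_rate=0.0, seed=42,
    )
    X, meta, truth = generate(cfg)
    y = truth_labels(truth, X.sample_ids)
    return X, meta, truth, y


@pytest.fixture(scope="session")
def noise_data():
    """No informative genes: labels independent of expression."""
    cfg = SyntheticConfig(
        n_samples=120, n_genes=100, n_informative=0, effect_size=0.0,
        minority_fraction=0.3, missing_rate=0.0, seed=7,
    )
    X, meta, truth = generate(cfg)
    y = truth_labels(truth, X.sample_ids)
    return X, y


@pytest.fixture
def tiny_matrix():
    return ExpressionMatrix(
        ["gA", "gB"], ["s1", "s2"], np.array([[1.0, 2.0], [3.0, 4.0]])
    )


def make_metadata(counts: dict[str, int], variable: str = "var") -> MetadataTable:
    """Metadata table with the given per-class sample counts."""
    sample_ids, values = [], []
    i = 0
    for cls, n in counts.items():
        for _ in range(n):
            sample_ids.append(f"s{i:05d}")
            values.append(cls)
            i += 1
    return MetadataTable(sample_ids, {variable: values})
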