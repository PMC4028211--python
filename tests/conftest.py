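import numpy as np
import pytest

from gcselect import ExpressionDataset, SyntheticSpec, generate


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """3 genes x 4 samples, two classes."""
    return ExpressionDataset(
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        X=np.arange(12, dtype=float).reshape(3, 4),
        y=np.array([0, 0, 1, 1]),
        class_names=["A", "B"],
    )


@pytest.fixture
def planted():
    """Default planted construction: 5 informative groups, 250 noise genes."""
    return generate(SyntheticSpec(seed=0))


def make_dataset(n_per_class=(20, 20), n_genes=10, seed=0, n_classes=None):
    """Pure-noise labelled dataset for permutation-style checks."""
    rng = np.random.default_rng(seed)
    counts = n_per_class
    y = np.concatenate([np.full(n, k) for k, n in enumerate(counts)])
    X = rng.normal(size=(n_genes, y.size))
    return ExpressionDataset(
        [f"g{i}" for i in range(n_genes)],
        [f"s{j}" for j in range(y.size)],
        X,
        y,
        [f"c{k}" for k in range(len(counts))],
    )
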