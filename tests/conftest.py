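import numpy as np
import pytest

from synpair import ExpressionDataset


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """3 genes x 6 samples, labels 0,0,0,1,1,1."""
    values = np.array([
        [3.2, 1.1, 2.5, 4.0, 5.5, 0.7],
        [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        [2.2, 2.2, 2.2, 9.9, 9.9, 9.9],
    ])
    return ExpressionDataset(
        values=values,
        gene_ids=["GA", "GB", "GC"],
        sample_ids=[f"S{i}" for i in range(1, 7)],
        labels=np.array([0, 0, 0, 1, 1, 1]),
    )


@pytest.fixture
def random_dataset():
    """Factory for random expression datasets with balanced labels."""

    def make(m=12, n=20, seed=0) -> ExpressionDataset:
        rng = np.random.default_rng(seed)
        return ExpressionDataset(
            values=rng.normal(size=(m, n)),
            gene_ids=[f"G{j}" for j in range(m)],
            sample_ids=[f"S{i}" for i in range(n)],
            labels=np.tile([0, 1], n // 2),
        )

    return make
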