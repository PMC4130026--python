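import numpy as np
import pytest

from irgdc import ExpressionDataset


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """3 genes x 4 samples, two classes — small enough to check by hand."""
    return ExpressionDataset(
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=[[1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 1.0, 2.0], [1.0, 2.0, 5.0, 6.0]],
        labels=["A", "A", "B", "B"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def random_dataset(rng) -> ExpressionDataset:
    """Random 12-gene, 15-sample, 3-class dataset."""
    p, n = 12, 15
    y = np.concatenate([np.zeros(5), np.ones(5), np.full(5, 2)]).astype(int)
    return ExpressionDataset(
        gene_ids=[f"g{i:02d}" for i in range(p)],
        sample_ids=[f"s{i:02d}" for i in range(n)],
        values=rng.normal(size=(p, n)),
        labels=np.array(["A", "B", "C"])[y],
    )
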