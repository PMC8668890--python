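import numpy as np
import pytest

from gnnsc import ExpressionDataset, generate_synthetic_study


@pytest.fixture(scope="session")
def study7():
    """Default synthetic study (seed 7): dataset, edge list, truth."""
    return generate_synthetic_study(seed=7)


@pytest.fixture()
def tiny_ds():
    """3 samples x 4 genes with an obvious class structure."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(6, 4))
    return ExpressionDataset(
        sample_ids=[f"s{i}" for i in range(6)],
        gene_ids=["a", "b", "c", "d"],
        X=X,
        y=np.array([0, 0, 0, 1, 1, 1]),
    )
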