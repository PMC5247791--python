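import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from dcnet.io import ExpressionDataset

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_dataset(
    values: np.ndarray,
    *,
    genes=None,
    n_a: int | None = None,
    paired: bool = False,
    dataset_id: str = "ds",
) -> ExpressionDataset:
    """Wrap a raw gene-by-sample array into an ExpressionDataset.

    The first ``n_a`` columns become condition A, the rest condition B
    (default: an even split).
    """
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    genes = list(genes) if genes is not None else [f"g{i}" for i in range(g)]
    n_a = n // 2 if n_a is None else n_a
    samples = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n - n_a)]
    condition = pd.Series(["A"] * n_a + ["B"] * (n - n_a), index=samples)
    pairing = None
    if paired:
        assert n - n_a == n_a, "paired datasets need equal condition sizes"
        pairing = {f"a{i}": f"b{i}" for i in range(n_a)}
    return ExpressionDataset(
        dataset_id=dataset_id,
        values=pd.DataFrame(values, index=genes, columns=samples),
        condition=condition,
        pairing=pairing,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20160922)


@pytest.fixture
def tiny_dataset():
    """3 genes x 8 samples (4 A + 4 B), fixed values."""
    rng = np.random.default_rng(42)
    return make_dataset(rng.normal(size=(3, 8)))
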