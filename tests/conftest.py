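import numpy as np
import pandas as pd
import pytest

from lhasig import simulate
from lhasig.containers import CountMatrix, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts():
    """Tiny two-group count matrix with balanced sex/batch metadata."""
    rng = np.random.default_rng(7)
    genes = simulate.gene_ids(50)
    samples = pd.Index([f"S{i:02d}" for i in range(12)], name="sample")
    counts = pd.DataFrame(
        rng.poisson(100, (50, 12)), index=genes, columns=samples
    )
    metadata = pd.DataFrame(
        {
            "group": ["case"] * 6 + ["control"] * 6,
            "age": [95] * 6 + [60] * 6,
            "sex": ["F", "M"] * 6,
            "batch": (["b1"] * 3 + ["b2"] * 3) * 2,
            "library": ["polyA"] * 12,
        },
        index=samples,
    )
    return CountMatrix(counts=counts, metadata=metadata)


def expression_from_values(values: np.ndarray, metadata: pd.DataFrame | None = None):
    """Wrap a raw gene x sample array as an ExpressionMatrix."""
    values = np.asarray(values, dtype=float)
    genes = simulate.gene_ids(values.shape[0])
    samples = pd.Index([f"S{i:03d}" for i in range(values.shape[1])], name="sample")
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        metadata=metadata.set_axis(samples) if metadata is not None else None,
    )
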