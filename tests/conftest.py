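import numpy as np
import pytest

from refmireo.io_core import ExpressionMatrix, SampleAnnotation


@pytest.fixture
def toy_expr() -> ExpressionMatrix:
    """3 features x 2 samples, distinct values, total order per sample."""
    return ExpressionMatrix(
        feature_ids=["A", "B", "C"],
        sample_ids=["s1", "s2"],
        values=np.array([[3.0, 5.0], [2.0, 4.0], [1.0, 1.0]]),
        scale="log2",
    )


@pytest.fixture
def toy_ann(toy_expr) -> SampleAnnotation:
    return SampleAnnotation(sample_ids=["s1", "s2"], groups=["T_cells", "T_cells"])


def random_matrix(
    rng: np.random.Generator, n_features: int, n_samples: int
) -> ExpressionMatrix:
    feats = [f"f{i:02d}" for i in range(n_features)]
    samples = [f"s{j:02d}" for j in range(n_samples)]
    return ExpressionMatrix(
        feature_ids=feats,
        sample_ids=samples,
        values=rng.normal(5.0, 2.0, size=(n_features, n_samples)),
        scale="log2",
    )
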