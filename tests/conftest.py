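import numpy as np
import pandas as pd
import pytest

from margin_profiler import ExpressionMatrix, GeneSet, GeneSetCollection


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 2 samples, TPM scale."""
    df = pd.DataFrame(
        {"s1": [1.0, 2.5, 0.0], "s2": [4.0, 0.5, 3.0]},
        index=["gA", "gB", "gC"],
    )
    return ExpressionMatrix(df, "tpm")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_log2_matrix(values: np.ndarray, genes=None, samples=None) -> ExpressionMatrix:
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), "log2_tpm_plus1")


@pytest.fixture
def toy_sets() -> GeneSetCollection:
    return GeneSetCollection([
        GeneSet("top", "front of ranking", ("g0", "g1", "g2")),
        GeneSet("bottom", "back of ranking", ("g7", "g8", "g9")),
    ])
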