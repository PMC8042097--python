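import numpy as np
import pandas as pd
import pytest

from wmniche.containers import CountMatrix, ExpressionMatrix


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """Two-sample count matrix whose size factors are known in closed form."""
    return CountMatrix(pd.DataFrame({"a:1": [2, 10], "b:1": [4, 20]}, index=["g1", "g2"]))


@pytest.fixture
def block_atlas() -> ExpressionMatrix:
    """Noise-free atlas: three cell types, two perfectly separable marker blocks each."""
    genes = [f"m{t}_{i}" for t in (1, 2, 3) for i in (1, 2)]
    cols = {}
    for t in (1, 2, 3):
        for rep in (1, 2):
            col = []
            for g in genes:
                gt = int(g[1])
                col.append(16.0 if gt == t else 2.0)
            cols[f"type{t}:{rep}"] = col
    return ExpressionMatrix(pd.DataFrame(cols, index=genes))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
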