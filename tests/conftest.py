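import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expr(rng):
    """8 genes x 30 samples of independent standard-normal expression."""
    genes = [f"G{i}" for i in range(1, 9)]
    return pd.DataFrame(
        rng.standard_normal((8, 30)),
        index=genes,
        columns=[f"S{j}" for j in range(1, 31)],
    )


def exact_correlated_pair(r: float, n: int = 40, seed: int = 0):
    """Two profiles whose sample correlation is exactly r (to float precision)."""
    g = np.random.default_rng(seed)
    a = g.standard_normal(n)
    b = g.standard_normal(n)
    a = (a - a.mean()) / a.std()
    b = b - b.mean()
    b -= (b @ a) / (a @ a) * a  # orthogonalize
    b /= b.std()
    y = r * a + np.sqrt(1.0 - r * r) * b
    return a, y
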