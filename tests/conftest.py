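import numpy as np
import pytest

from cgemga.matrix import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240912)


@pytest.fixture
def small_matrix():
    """4 genes × 5 samples with assorted values."""
    values = np.array([
        [1.0, 2.0, 3.0, 4.0, 5.0],
        [5.0, 5.0, 5.0, 5.0, 5.0],
        [0.1, -0.2, 0.7, 1.9, -1.3],
        [10.0, 20.0, 15.0, 12.0, 18.0],
    ])
    return ExpressionMatrix([f"g{i}" for i in range(4)],
                            [f"s{j}" for j in range(5)], values)


def naive_msr(values: np.ndarray, rows, cols) -> float:
    """Independent double-loop evaluation of the mean squared residue."""
    rows, cols = list(rows), list(cols)
    sub = [[values[i][j] for j in cols] for i in rows]
    n_i, n_j = len(rows), len(cols)
    row_means = [sum(r) / n_j for r in sub]
    col_means = [sum(sub[i][j] for i in range(n_i)) / n_i for j in range(n_j)]
    grand = sum(sum(r) for r in sub) / (n_i * n_j)
    total = 0.0
    for i in range(n_i):
        for j in range(n_j):
            res = sub[i][j] - row_means[i] - col_means[j] + grand
            total += res * res
    return total / (n_i * n_j)
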