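import numpy as np
import pandas as pd
import pytest

from tripla import ExpressionMatrix, SyntheticConfig, generate_switching_dataset, transform_matrix


def naive_mla(x1, x2, x3, n_bins):
    """Independent brute-force MLA: explicit sort, split, textbook Pearson.

    Written with plain Python loops so it shares no code path with the
    library implementation.
    """
    n = len(x1)
    order = sorted(range(n), key=lambda i: (x3[i], i))  # stable in input order
    base, extra = divmod(n, n_bins)
    sizes = [base + 1] * extra + [base] * (n_bins - extra)
    total = 0.0
    start = 0
    for size in sizes:
        idx = order[start : start + size]
        start += size
        a = [x1[i] for i in idx]
        b = [x2[i] for i in idx]
        ma = sum(a) / size
        mb = sum(b) / size
        sab = sum((u - ma) * (v - mb) for u, v in zip(a, b))
        saa = sum((u - ma) ** 2 for u in a)
        sbb = sum((v - mb) ** 2 for v in b)
        rho = 0.0 if saa == 0 or sbb == 0 else sab / (saa * sbb) ** 0.5
        mean_x3 = sum(x3[i] for i in idx) / size
        total += rho * mean_x3
    return total / n_bins


@pytest.fixture(scope="session")
def planted_dataset():
    """Small dataset with 5 planted triplets among 100 background genes."""
    config = SyntheticConfig(n_genes=115, n_planted_triplets=5, n_de_genes=5, seed=0)
    matrix, truth = generate_switching_dataset(config)
    return matrix, truth


@pytest.fixture(scope="session")
def planted_transformed(planted_dataset):
    matrix, truth = planted_dataset
    return transform_matrix(matrix), truth


@pytest.fixture()
def toy_matrix():
    rng = np.random.default_rng(123)
    data = pd.DataFrame(
        rng.normal(size=(6, 12)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{j}" for j in range(12)],
    )
    groups = pd.Series(["A"] * 6 + ["B"] * 6, index=data.columns)
    return ExpressionMatrix(data, groups)
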