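import numpy as np
import pandas as pd
import pytest

from uratenet.containers import AbundanceMatrix, CovariateTable


def make_matrix(values, stage="raw", runday=None, sample_ids=None,
                metabolite_ids=None):
    """Small AbundanceMatrix builder for fixtures (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return AbundanceMatrix(
        sample_ids or [f"S{i + 1}" for i in range(n)],
        metabolite_ids or [f"M{j + 1}" for j in range(p)],
        values,
        np.asarray(runday) if runday is not None else np.array(["d1"] * n),
        stage=stage,
    )


def make_covariates(n, seed=0, n_snps=0):
    rng = np.random.default_rng(seed)
    cols = {
        "age": rng.uniform(32, 81, n).round(1),
        "sex": rng.integers(0, 2, n),
        "medication": (rng.random(n) < 0.08).astype(int),
    }
    snps = [f"snp{i + 1}" for i in range(n_snps)]
    for s in snps:
        cols[s] = rng.binomial(2, 0.3, n)
    return CovariateTable(pd.DataFrame(cols, index=[f"S{i + 1}" for i in range(n)]),
                          snps)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
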