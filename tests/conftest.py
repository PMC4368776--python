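import numpy as np
import pytest

from disis import FeatureMatrix, generate_synthetic, sigma_for_r2


def weak_family(seed: int, n: int = 400, p: int = 1000, r2: float = 0.8,
                expr_subblock: int = 50):
    """The weak-marginal study family: 3 strong predictors plus one planted
    feature with zero population correlation to the response."""
    return generate_synthetic(
        n=n, p=p, s_strong=3, rho=0.5, sigma=sigma_for_r2(3, r2), seed=seed,
        expr_subblock=expr_subblock,
    )


def random_matrix(rng: np.random.Generator, n: int, p: int) -> FeatureMatrix:
    return FeatureMatrix(
        feature_ids=[f"CNV:g{j}" for j in range(p)],
        sample_ids=[f"s{i}" for i in range(n)],
        values=rng.standard_normal((n, p)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20150320)


@pytest.fixture
def small_xy(rng):
    X = rng.standard_normal((60, 5))
    beta = np.array([1.5, -2.0, 0.0, 0.8, 0.0])
    y = 0.5 + X @ beta + 0.3 * rng.standard_normal(60)
    return X, y
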