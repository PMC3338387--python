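import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_problem(rng):
    """n=120, 12 penalized features, 2 planted effects, 2 covariates."""
    from vbnetrec.vb_core import RegressionProblem

    n, P = 120, 12
    W = rng.standard_normal((n, P))
    T = rng.standard_normal((n, 2))
    beta = np.zeros(P)
    beta[[2, 7]] = [1.5, -1.2]
    y = W @ beta + T @ np.array([0.5, -0.3]) + rng.standard_normal(n)
    return RegressionProblem.from_design(y, W, T=T)
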