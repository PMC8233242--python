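import numpy as np
import pytest

from masslasso import zscore_columns


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_design(rng):
    """Z-scored 30 x 6 design with mild correlations."""
    raw = rng.standard_normal((30, 6))
    raw[:, 1] += 0.5 * raw[:, 0]  # induce correlation
    X, _ = zscore_columns(raw)
    return X


@pytest.fixture
def small_responses(rng):
    return rng.standard_normal((30, 4))


def orthonormal_design(rng, n, p):
    """Design whose columns are orthonormal in the (1/n) inner product
    and z-scored: Gram matrix exactly (numerically) the identity."""
    assert p < n
    raw = rng.standard_normal((n, p + 1))
    raw[:, 0] = 1.0  # force orthogonality to the constant => centered columns
    q, _ = np.linalg.qr(raw)
    return q[:, 1:p + 1] * np.sqrt(n)


@pytest.fixture
def ortho_design(rng):
    return orthonormal_design(rng, 24, 5)
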