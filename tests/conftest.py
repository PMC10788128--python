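import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20231227)


def random_correlation(rng: np.random.Generator, k: int) -> np.ndarray:
    """A random positive-definite correlation matrix (Gram construction)."""
    A = rng.standard_normal((k, k + 2))
    S = A @ A.T
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return R
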