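import numpy as np
import pytest

from npca import DataMatrix, standardize


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    return DataMatrix(values=rng.normal(size=(50, 5)))


@pytest.fixture
def standardized_matrix(small_matrix):
    Z, _ = standardize(small_matrix)
    return Z


def canonical_correlations(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Canonical correlations between two column blocks, via QR + SVD."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    qa, _ = np.linalg.qr(A)
    qb, _ = np.linalg.qr(B)
    return np.linalg.svd(qa.T @ qb, compute_uv=False)
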