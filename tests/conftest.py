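import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_orthonormal(rng, n, k):
    """Random n-by-k matrix with orthonormal columns (QR of a Gaussian)."""
    q, r = np.linalg.qr(rng.standard_normal((n, k)))
    return q * np.sign(np.diag(r))


def matrix_with_spectrum(rng, n, m, spectrum):
    """Random matrix with prescribed singular values (distinct, ordered)."""
    s = np.asarray(spectrum, dtype=float)
    u = random_orthonormal(rng, n, s.size)
    v = random_orthonormal(rng, m, s.size)
    return (u * s) @ v.T


@pytest.fixture()
def spectrum_matrix(rng):
    """A 10x8 matrix with well-separated singular values [9, 7, 5, 3]."""
    return matrix_with_spectrum(rng, 10, 8, [9.0, 7.0, 5.0, 3.0])
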