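import numpy as np
import pytest

from rhopca import CovariancePair, random_spd_pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def diag_pair():
    """sigma_t = diag(8, 2), sigma_b = diag(2, 1): eigenvalues (4, 2) by hand."""
    return CovariancePair(np.diag([8.0, 2.0]), np.diag([2.0, 1.0]))


@pytest.fixture
def spd_pairs():
    """Random well-conditioned SPD pairs across dimensions 2..8."""
    pairs = []
    for i, dim in enumerate([2, 3, 4, 5, 6, 7, 8] * 3):
        pairs.append(random_spd_pair(dim, condition=50.0, seed=1000 + i))
    return pairs


def brute_force_geneig(sigma_t, sigma_b_reg):
    """Independent oracle: dense eigendecomposition of inv(B) @ A.

    Deliberately avoids the symmetric-definite solver used by the package:
    forms the (non-symmetric) matrix product and uses the general
    eigensolver, then sorts by descending real eigenvalue.
    """
    m = np.linalg.inv(sigma_b_reg) @ sigma_t
    w, v = np.linalg.eig(m)
    order = np.argsort(-w.real)
    return w.real[order], v.real[:, order]
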