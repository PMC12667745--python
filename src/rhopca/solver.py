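"""Rayleigh-quotient evaluation and its exact maximization.

The quotient rho(v) = v'S_T v / v'S_B v measures target-to-background
variance along a direction v. Its stationary points are the solutions of the
symmetric-definite generalized eigenproblem S_T v = lambda S_B v, and the
top-d eigenvectors maximize the trace-ratio objective
tr((V'S_B V)^-1 V'S_T V): eigenvalue i equals the variance ratio along
eigenvector i. Solutions are normalized to v' (S_B + mu I) v = 1, so
returned eigenvectors are orthonormal in the (regularized) background inner
product rather than the Euclidean one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .covariance import CovariancePair, auto_mu, tikhonov_regularize
from .errors import DegenerateBackgroundError, InvalidInputError, SingularBackgroundError


def rayleigh_quotient(v: np.ndarray, pair: CovariancePair) -> float:
    """Target-to-background variance ratio (v'S_T v)/(v'S_B v) along v.

    Invariant to rescaling of ``v``. A direction in the null space of the
    background covariance is an error rather than +/-inf: it signals that
    the caller must regularize before the ratio is meaningful.
    """
    v = np.asarray(v, dtype=float).ravel()
    if v.shape[0] != pair.dim:
        raise InvalidInputError(f"v has length {v.shape[0]}, expected {pair.dim}")
    if not np.any(v):
        raise InvalidInputError("v must be a nonzero vector")
    denom = float(v @ pair.sigma_b @ v)
    if denom <= 0.0:
        raise DegenerateBackgroundError(
            f"background quadratic form v' sigma_b v = {denom:.3e} is not "
            "positive; v lies in the null space of the background covariance "
            "(consider Tikhonov regularization)"
        )
    return float(v @ pair.sigma_t @ v) / denom


@dataclass
class GeneralizedEigenSolution:
    """Top-d generalized eigenpairs of (S_T, S_B + mu I).

    Attributes
    ----------
    vectors : (D, d) ndarray
        Columns are generalized eigenvectors, normalized so that
        ``V' (S_B + mu I) V = I`` and sign-fixed so each column's
        largest-magnitude entry is positive.
    values : (d,) ndarray
        Eigenvalues in non-increasing order; ``values[i]`` equals the
        Rayleigh quotient of ``vectors[:, i]`` under the regularized
        background.
    mu : float
        Regularization strength actually applied.
    feature_names : list of str
        Feature labels carried over from the covariance pair.
    """

    vectors: np.ndarray
    values: np.ndarray
    mu: float
    feature_names: list[str]

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    @property
    def dim(self) -> int:
        return self.vectors.shape[0]


def fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive.

    Generalized eigenvectors are determined only up to sign; this convention
    makes loadings tables reproducible across runs and platforms. Ties in
    magnitude resolve to the lowest row index (argmax convention).
    """
    v = np.array(vectors, dtype=float)
    idx = np.argmax(np.abs(v), axis=0)
    signs = np.sign(v[idx, np.arange(v.shape[1])])
    signs[signs == 0] = 1.0
    return v * signs


def solve_rho_pca(
    pair: CovariancePair,
    d: int | None = None,
    mu: float | str = "auto",
) -> GeneralizedEigenSolution:
    """Maximize the Rayleigh quotient: top-d eigenpairs of S_T v = lambda (S_B + mu I) v.

    Parameters
    ----------
    pair : CovariancePair
        Validated target/background covariances.
    d : int, optional
        Number of components to retain (default: all D).
    mu : float or "auto"
        Tikhonov strength. ``"auto"`` applies 0 for a well-conditioned
        background and a small trace-scaled shift otherwise (see
        :func:`rhopca.covariance.auto_mu`). An explicitly given ``mu`` that
        leaves the background non-positive-definite raises
        :class:`SingularBackgroundError`.

    Returns
    -------
    GeneralizedEigenSolution
        Eigenvalues sorted non-increasing; the first equals the global
        maximum of the quotient over all nonzero v.
    """
    D = pair.dim
    if d is None:
        d = D
    if not (1 <= d <= D):
        raise InvalidInputError(f"d must be in [1, {D}], got {d}")
    if isinstance(mu, str):
        if mu != "auto":
            raise InvalidInputError(f"mu must be a nonnegative float or 'auto', got {mu!r}")
        mu_val = auto_mu(pair.sigma_b)
        explicit = False
    else:
        mu_val = float(mu)
        if mu_val < 0:
            raise InvalidInputError(f"mu must be nonnegative, got {mu_val}")
        explicit = True

    b_reg = tikhonov_regularize(pair.sigma_b, mu_val)
    try:
        # scipy returns eigenvalues ascending with B-orthonormal eigenvectors
        values, vectors = scipy.linalg.eigh(pair.sigma_t, b_reg)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as exc:
        if explicit:
            raise SingularBackgroundError(
                f"sigma_b + mu*I with mu={mu_val:g} is not positive definite; "
                "increase mu or pass mu='auto'"
            ) from exc
        # auto path: fall back to a larger, still trace-scaled shift
        mu_val = 1e-6 * float(np.trace(pair.sigma_b)) / D + 1e-12
        b_reg = tikhonov_regularize(pair.sigma_b, mu_val)
        values, vectors = scipy.linalg.eigh(pair.sigma_t, b_reg)

    # stable sort on -values keeps the solver's original order among ties
    order = np.argsort(-values, kind="stable")[:d]
    return GeneralizedEigenSolution(
        vectors=fix_signs(vectors[:, order]),
        values=values[order],
        mu=mu_val,
        feature_names=list(pair.feature_names),
    )
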