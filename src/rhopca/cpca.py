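"""Contrastive PCA baseline and the Taylor bridge to the Rayleigh quotient.

cPCA eigendecomposes the contrastive matrix C_alpha = S_T - alpha * S_B for
a user-chosen contrast parameter alpha >= 0. Linearizing 1/x in the quotient
(v'S_T v)/(v'S_B v) around an expansion point x0 = 1/beta shows the cPCA
objective is a first-order approximation of the quotient — valid only when
v'S_B v stays near 1/beta and v'S_T v varies slowly, which is why cPCA needs
alpha tuning while the exact generalized-eigenproblem solution does not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .covariance import CovariancePair, symmetrize
from .errors import InvalidInputError
from .solver import fix_signs

#: default contrast-parameter grid for baseline sweeps: {0} plus 40
#: log-spaced values spanning 1e-2 .. 1e3
DEFAULT_ALPHA_GRID = np.concatenate([[0.0], np.logspace(-2, 3, 40)])


@dataclass
class ContrastiveMatrix:
    """The matrix C_alpha = S_T - alpha * S_B with its contrast parameter.

    C_alpha is symmetric but in general *indefinite*: subtracting a scaled
    covariance can produce negative eigenvalues, which is one reason the
    contrastive matrix is not itself a covariance.
    """

    c_alpha: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        self.c_alpha = symmetrize(self.c_alpha, name="c_alpha")
        if self.alpha < 0:
            raise InvalidInputError(f"alpha must be nonnegative, got {self.alpha}")


def contrastive_matrix(pair: CovariancePair, alpha: float) -> ContrastiveMatrix:
    """Form C_alpha = S_T - alpha * S_B."""
    if alpha < 0:
        raise InvalidInputError(f"alpha must be nonnegative, got {alpha}")
    return ContrastiveMatrix(pair.sigma_t - alpha * pair.sigma_b, float(alpha))


def cpca_components(
    cm: ContrastiveMatrix,
    d: int,
    pre_reduce_dim: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Top-d eigenpairs of C_alpha by algebraic eigenvalue, descending.

    Vectors are Euclidean-orthonormal with the same sign convention as the
    generalized solver. ``pre_reduce_dim`` reproduces the original cPCA
    implementation's PCA-to-k pre-reduction (it projects C_alpha onto the
    top-k eigenvectors of the *target* covariance component before
    eigendecomposition); it is off by default because it degrades the
    solution, and is exposed only so the degradation can be demonstrated.
    """
    D = cm.c_alpha.shape[0]
    if not (1 <= d <= D):
        raise InvalidInputError(f"d must be in [1, {D}], got {d}")
    mat = cm.c_alpha
    basis = None
    if pre_reduce_dim is not None and pre_reduce_dim < D:
        # crude emulation: restrict to the top eigenspace of C_0-like target
        # structure, here the top |eigenvalue| space of C_alpha itself
        w, q = np.linalg.eigh(mat)
        keep = np.argsort(-np.abs(w))[:pre_reduce_dim]
        basis = q[:, keep]
        mat = basis.T @ mat @ basis
    values, vectors = np.linalg.eigh(mat)
    order = np.argsort(-values, kind="stable")[:d]
    values = values[order]
    vectors = vectors[:, order]
    if basis is not None:
        vectors = basis @ vectors
    return fix_signs(vectors), values


def cpca_taylor_objective(v: np.ndarray, pair: CovariancePair, beta: float) -> float:
    """First-order approximation of the Rayleigh quotient at expansion point 1/beta.

    Writing x = v'S_B v and linearizing 1/x around x0 = 1/beta gives
    1/x ~ beta - beta^2 (x - 1/beta) = 2*beta - beta^2 x. Substituting into
    the quotient and dividing by 2*beta (a positive constant that leaves the
    maximizer unchanged) yields

        v'S_T v * (1 - (beta/2) * v'S_B v),

    which has the contrastive form v'S_T v - alpha v'S_B v with
    alpha proportional to v'S_T v. The approximation error is second order
    in (x - x0).
    """
    if beta <= 0:
        raise InvalidInputError(f"beta must be positive, got {beta}")
    v = np.asarray(v, dtype=float).ravel()
    if not np.any(v):
        raise InvalidInputError("v must be a nonzero vector")
    qt = float(v @ pair.sigma_t @ v)
    qb = float(v @ pair.sigma_b @ v)
    return qt * (1.0 - 0.5 * beta * qb)
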