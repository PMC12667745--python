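"""Covariance containers and matrix utilities for the generalized eigenproblem.

The whole method operates on a pair of symmetric covariance matrices: the
*target* covariance ``sigma_t`` whose variance we want to maximize and the
*background* covariance ``sigma_b`` whose variance we want to suppress.
``CovariancePair`` validates and stores that pair; ``ReplicateSet`` averages
per-replicate covariance estimates into one pair; ``tikhonov_regularize``
lifts a semidefinite background to positive definiteness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

#: relative tolerance for declaring a matrix symmetric: max|A - A'| <= SYM_RTOL * max|A|
SYM_RTOL = 1e-10
#: relative tolerance on the most negative eigenvalue of a PSD matrix
PSD_RTOL = 1e-8


def symmetrize(a: np.ndarray, rtol: float = SYM_RTOL, name: str = "matrix") -> np.ndarray:
    """Return (A + A')/2, rejecting matrices whose asymmetry exceeds tolerance.

    Guards against I/O round-off: tiny asymmetry from CSV serialization is
    repaired silently, anything larger is treated as corrupt input.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise InvalidInputError(f"{name} must be square, got shape {a.shape}")
    scale = np.max(np.abs(a)) if a.size else 0.0
    asym = np.max(np.abs(a - a.T)) if a.size else 0.0
    if asym > rtol * max(scale, 1e-300):
        raise InvalidInputError(
            f"{name} is not symmetric: max|A - A'| = {asym:.3e} exceeds "
            f"{rtol:.1e} * max|A| = {rtol * scale:.3e}"
        )
    return (a + a.T) / 2.0


@dataclass
class CovariancePair:
    """Symmetric target/background covariance matrices on a shared feature set.

    Parameters
    ----------
    sigma_t, sigma_b : (D, D) ndarray
        Target and background sample covariances. Symmetrized on
        construction; asymmetry beyond ``SYM_RTOL`` or a background that is
        not positive semidefinite raises :class:`InvalidInputError`.
    feature_names : sequence of str, optional
        Length-D feature labels; defaults to ``f0..f{D-1}``.
    n_t, n_b : int, optional
        Sample counts behind each estimate (must be >= 2 when given).
    """

    sigma_t: np.ndarray
    sigma_b: np.ndarray
    feature_names: list[str] = field(default=None)  # type: ignore[assignment]
    n_t: int | None = None
    n_b: int | None = None

    def __post_init__(self) -> None:
        self.sigma_t = symmetrize(self.sigma_t, name="sigma_t")
        self.sigma_b = symmetrize(self.sigma_b, name="sigma_b")
        if self.sigma_t.shape != self.sigma_b.shape:
            raise InvalidInputError(
                f"dimension mismatch: sigma_t is {self.sigma_t.shape}, "
                f"sigma_b is {self.sigma_b.shape}"
            )
        d = self.sigma_t.shape[0]
        if self.feature_names is None:
            self.feature_names = [f"f{i}" for i in range(d)]
        else:
            self.feature_names = [str(n) for n in self.feature_names]
            if len(self.feature_names) != d:
                raise InvalidInputError(
                    f"{len(self.feature_names)} feature names for {d} features"
                )
        for label, n in (("n_t", self.n_t), ("n_b", self.n_b)):
            if n is not None and n < 2:
                raise InvalidInputError(f"{label} must be >= 2, got {n}")
        evals = np.linalg.eigvalsh(self.sigma_b)
        top = max(evals[-1], 0.0)
        if evals[0] < -PSD_RTOL * max(top, 1e-300):
            raise InvalidInputError(
                f"sigma_b is not positive semidefinite: min eigenvalue "
                f"{evals[0]:.3e} < -{PSD_RTOL:.0e} * max eigenvalue {top:.3e}"
            )

    @property
    def dim(self) -> int:
        return self.sigma_t.shape[0]


@dataclass
class ReplicateSet:
    """Per-replicate covariance estimates to be averaged into one pair.

    Averaging is justified when each replicate covariance estimates the same
    population covariance: the mean has lower estimation variance than any
    single replicate. Optional nonnegative ``weights`` (one list per side,
    each summing to 1) allow sample-size or confidence weighting.
    """

    target_covs: Sequence[np.ndarray]
    background_covs: Sequence[np.ndarray]
    target_weights: Sequence[float] | None = None
    background_weights: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if len(self.target_covs) < 1 or len(self.background_covs) < 1:
            raise InvalidInputError("need at least one replicate on each side")
        mats = [np.asarray(m, float) for m in self.target_covs] + [
            np.asarray(m, float) for m in self.background_covs
        ]
        shapes = {m.shape for m in mats}
        if len(shapes) != 1:
            raise InvalidInputError(f"replicate dimension mismatch: {sorted(shapes)}")
        for w, covs, side in (
            (self.target_weights, self.target_covs, "target"),
            (self.background_weights, self.background_covs, "background"),
        ):
            if w is None:
                continue
            w = np.asarray(w, float)
            if len(w) != len(covs):
                raise InvalidInputError(f"{side} weights length != replicate count")
            if np.any(w < 0):
                raise InvalidInputError(f"{side} weights must be nonnegative")
            if abs(w.sum() - 1.0) > 1e-8:
                raise InvalidInputError(f"{side} weights must sum to 1, got {w.sum()}")


def average_covariances(reps: ReplicateSet, feature_names: Sequence[str] | None = None) -> CovariancePair:
    """Average replicate covariances into a single :class:`CovariancePair`.

    Unweighted, this is the arithmetic mean (1/r) sum_i Sigma_T_i on the
    target side and (1/s) sum_j Sigma_B_j on the background side.
    """

    def _mean(covs: Sequence[np.ndarray], weights) -> np.ndarray:
        arr = np.stack([symmetrize(c, name="replicate") for c in covs])
        if weights is None:
            return arr.mean(axis=0)
        return np.einsum("i,ijk->jk", np.asarray(weights, float), arr)

    return CovariancePair(
        _mean(reps.target_covs, reps.target_weights),
        _mean(reps.background_covs, reps.background_weights),
        feature_names=list(feature_names) if feature_names is not None else None,
    )


def tikhonov_regularize(sigma_b: np.ndarray, mu: float) -> np.ndarray:
    """Additive Tikhonov shrinkage: return Sigma_B + mu*I.

    Shifts every eigenvalue up by exactly ``mu`` while leaving eigenvectors
    untouched, so small eigenvalues are lifted proportionally much more than
    large ones and the background keeps its original scale.
    """
    if mu < 0:
        raise InvalidInputError(f"mu must be nonnegative, got {mu}")
    s = symmetrize(sigma_b, name="sigma_b")
    return s + mu * np.eye(s.shape[0])


def auto_mu(sigma_b: np.ndarray, rtol: float = 1e-10, scale: float = 1e-6) -> float:
    """Scale-aware automatic regularization strength.

    Returns 0 when the background is comfortably positive definite
    (min eigenvalue > ``rtol`` * max eigenvalue); otherwise
    ``scale * trace(Sigma_B) / D``, i.e. a small fraction of the mean
    eigenvalue, which tracks the data's units.
    """
    s = symmetrize(sigma_b, name="sigma_b")
    evals = np.linalg.eigvalsh(s)
    if evals[0] > rtol * max(evals[-1], 0.0):
        return 0.0
    mu = scale * float(np.trace(s)) / s.shape[0]
    logger.info("background near-singular (min eig %.3e); auto mu = %.3e", evals[0], mu)
    return mu


def loewner_dominates(a: np.ndarray, b: np.ndarray, rtol: float = 1e-10) -> bool:
    """True iff A - B is positive semidefinite (A dominates B in Loewner order).

    Tolerance: min eigenvalue of the difference may be as low as
    ``-rtol * max|A - B|`` to absorb round-off.
    """
    a = symmetrize(a, name="a")
    b = symmetrize(b, name="b")
    if a.shape != b.shape:
        raise InvalidInputError(f"dimension mismatch: {a.shape} vs {b.shape}")
    diff = a - b
    scale = np.max(np.abs(diff))
    if scale == 0.0:
        return True
    return bool(np.linalg.eigvalsh(diff)[0] >= -rtol * scale)
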