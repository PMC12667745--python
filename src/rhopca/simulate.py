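"""Synthetic data generators: planted-axis Gaussian scenarios and count fixtures.

``ContrastiveScenario`` builds mean-zero multivariate Gaussians in which the
target and background share variance along some axes while the target has
extra variance along axes absent from the background, on top of isotropic
noise. The default scenario plants two shared axes (variance 10 in both
groups), one target-only axis (variance 10) and unit noise in 30
dimensions with 1,000 samples per group — chosen so the unique axis is tied
with, not above, the shared axes in the target spectrum, which is exactly
the regime where plain PCA and cPCA fail to isolate it.

``simulate_counts`` produces overdispersed (Gamma-Poisson) integer counts
with log-normal depth variation for exercising the preprocessing chain; it
emulates the *structure* of single-nucleus RNA-seq data (sparsity,
overdispersion, depth spread), not any particular tissue's distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .covariance import CovariancePair
from .errors import InvalidInputError
from .preprocess import CountMatrix


@dataclass
class ContrastiveScenario:
    """Population covariances with planted shared and target-only axes.

    shared_axes: list of (unit vector, target variance, background variance)
    unique_axes: list of (unit vector, target-only variance); the background
    gets only noise along these. All axes must be mutually orthogonal unit
    vectors; remaining directions carry isotropic ``noise_variance`` on both
    sides.
    """

    dim: int
    shared_axes: list[tuple[np.ndarray, float, float]]
    unique_axes: list[tuple[np.ndarray, float]]
    noise_variance: float = 1.0
    n_t: int = 1000
    n_b: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_variance < 0:
            raise InvalidInputError("noise_variance must be nonnegative")
        axes = [np.asarray(a, float) for a, *_ in self.shared_axes] + [
            np.asarray(a, float) for a, _ in self.unique_axes
        ]
        for a in axes:
            if a.shape != (self.dim,):
                raise InvalidInputError(f"axis has shape {a.shape}, expected ({self.dim},)")
            if abs(np.linalg.norm(a) - 1.0) > 1e-8:
                raise InvalidInputError("axes must be unit vectors")
        for i in range(len(axes)):
            for j in range(i + 1, len(axes)):
                if abs(axes[i] @ axes[j]) > 1e-8:
                    raise InvalidInputError("axes must be mutually orthogonal")
        for _, vt, vb in self.shared_axes:
            if vt <= 0 or vb <= 0:
                raise InvalidInputError("shared-axis variances must be positive")
        for _, vu in self.unique_axes:
            if vu <= 0:
                raise InvalidInputError("unique-axis variances must be positive")

    def population_covariances(self) -> CovariancePair:
        """Assemble the exact population covariance pair the scenario encodes."""
        st = self.noise_variance * np.eye(self.dim)
        sb = self.noise_variance * np.eye(self.dim)
        for a, vt, vb in self.shared_axes:
            a = np.asarray(a, float)
            # planted variance replaces (not adds to) the noise along the axis
            st += (vt - self.noise_variance) * np.outer(a, a)
            sb += (vb - self.noise_variance) * np.outer(a, a)
        for a, vu in self.unique_axes:
            a = np.asarray(a, float)
            st += (vu - self.noise_variance) * np.outer(a, a)
        return CovariancePair(st, sb)


def default_scenario(
    dim: int = 30,
    n: int = 1000,
    shared_variance: float = 10.0,
    unique_variance: float = 10.0,
    noise_variance: float = 1.0,
    seed: int = 0,
) -> ContrastiveScenario:
    """Two shared axes, one target-only axis, on coordinate directions."""
    e = np.eye(dim)
    return ContrastiveScenario(
        dim=dim,
        shared_axes=[(e[0], shared_variance, shared_variance),
                     (e[1], shared_variance, shared_variance)],
        unique_axes=[(e[2], unique_variance)],
        noise_variance=noise_variance,
        n_t=n,
        n_b=n,
        seed=seed,
    )


def simulate_contrastive(sc: ContrastiveScenario) -> tuple[np.ndarray, np.ndarray]:
    """Draw (target n_t x D, background n_b x D) from the scenario's Gaussians.

    Reproducible: all randomness comes from ``numpy.random.default_rng(sc.seed)``.
    """
    pair = sc.population_covariances()
    rng = np.random.default_rng(sc.seed)
    lt = np.linalg.cholesky(pair.sigma_t + 1e-12 * np.eye(sc.dim))
    lb = np.linalg.cholesky(pair.sigma_b + 1e-12 * np.eye(sc.dim))
    x_t = rng.standard_normal((sc.n_t, sc.dim)) @ lt.T
    x_b = rng.standard_normal((sc.n_b, sc.dim)) @ lb.T
    return x_t, x_b


def simulate_counts(
    n_per_group: int,
    n_genes: int,
    planted_variable_genes: list[int] | None = None,
    seed: int = 0,
    extra_dispersion: float = 10.0,
) -> tuple[CountMatrix, CountMatrix]:
    """Overdispersed count matrices for a target and a background group.

    Gamma-Poisson counts: gene base means are log-normal, each cell has a
    log-normal depth factor, and per-cell rates get multiplicative Gamma
    noise (shape 1/phi, baseline dispersion phi = 0.5). Genes listed in
    ``planted_variable_genes`` (column indices) additionally respond to a
    shared per-cell log-normal activity factor in the *target* group only,
    with squared coefficient of variation ``extra_dispersion - 1`` and unit
    mean. The factor plants excess *and correlated* cell-to-cell
    variability — exactly the kind of coordinated variation a contrastive
    fit can still see after per-group standard scaling turns covariances
    into correlation matrices — while leaving mean expression matched
    between groups.
    """
    if planted_variable_genes is None:
        planted_variable_genes = []
    planted = np.asarray(planted_variable_genes, dtype=int)
    if planted.size and (planted.min() < 0 or planted.max() >= n_genes):
        raise InvalidInputError("planted gene indices out of range")
    if extra_dispersion < 1:
        raise InvalidInputError("extra_dispersion must be >= 1")
    rng = np.random.default_rng(seed)
    base_mean = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    gene_names = [f"gene{i}" for i in range(n_genes)]
    sigma_f = np.sqrt(np.log(extra_dispersion))  # lognormal sd giving CV^2 = extra - 1

    def _group(target: bool, tag: str) -> CountMatrix:
        depth = rng.lognormal(mean=0.0, sigma=0.3, size=n_per_group)
        gamma_noise = rng.gamma(shape=2.0, scale=0.5, size=(n_per_group, n_genes))
        rates = depth[:, None] * base_mean[None, :] * gamma_noise
        if target and planted.size and sigma_f > 0:
            # unit-mean shared activity factor: correlated target-only variance
            factor = rng.lognormal(mean=-0.5 * sigma_f**2, sigma=sigma_f,
                                   size=n_per_group)
            rates[:, planted] *= factor[:, None]
        counts = rng.poisson(rates).astype(float)
        names = [f"{tag}{i}" for i in range(n_per_group)]
        return CountMatrix(counts, names, gene_names)

    return _group(True, "t"), _group(False, "b")


def random_spd_pair(dim: int, condition: float = 10.0, seed: int = 0) -> CovariancePair:
    """Two random symmetric positive-definite matrices with bounded condition number.

    Eigenvalues are geometrically spaced over [1, condition] (all equal when
    condition == 1, giving positive multiples of the identity) and rotated
    by independent Haar-random orthogonal bases.
    """
    if dim < 1:
        raise InvalidInputError(f"dim must be >= 1, got {dim}")
    if condition < 1:
        raise InvalidInputError(f"condition must be >= 1, got {condition}")
    rng = np.random.default_rng(seed)

    def _one() -> np.ndarray:
        if dim == 1:
            return np.array([[float(rng.uniform(0.5, 2.0))]])
        evals = np.geomspace(1.0, condition, dim) * rng.uniform(0.5, 2.0)
        q, r = np.linalg.qr(rng.standard_normal((dim, dim)))
        q *= np.sign(np.diag(r))  # Haar correction
        return (q * evals) @ q.T

    return CovariancePair(_one(), _one())
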