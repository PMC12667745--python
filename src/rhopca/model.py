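"""Model / Results objects tying the method together.

``RhoPCA`` holds a target/background covariance pair (built directly, from
data matrices, from dataframes, or from raw counts via the preprocessing
chain) and ``fit()`` returns ``RhoPCAResults`` carrying the generalized
eigenpairs, projections, per-group variance ratios and a ``summary()``
table. ``ContrastivePCA`` is the same surface for the cPCA baseline.

Example
-------
>>> import numpy as np
>>> from rhopca import RhoPCA
>>> rng = np.random.default_rng(0)
>>> x_t = rng.standard_normal((200, 5)) * [1, 1, 3, 1, 1]
>>> x_b = rng.standard_normal((200, 5))
>>> res = RhoPCA.from_data(x_t, x_b).fit(n_components=2)
>>> res.eigenvalues.shape
(2,)
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .analysis import ProjectionReport, build_report, top_loadings
from .covariance import CovariancePair, ReplicateSet, average_covariances
from .cpca import DEFAULT_ALPHA_GRID, contrastive_matrix, cpca_components
from .errors import InvalidInputError
from .preprocess import (
    CountMatrix,
    ScaledMatrix,
    preprocess_pair,
    sample_covariance,
    standard_scale,
)
from .solver import GeneralizedEigenSolution, rayleigh_quotient, solve_rho_pca


def _as_scaled(x, feature_names, labels, prefix) -> ScaledMatrix:
    x = np.asarray(x, dtype=float)
    n, g = x.shape
    names = list(feature_names) if feature_names is not None else [f"f{i}" for i in range(g)]
    return ScaledMatrix(
        x, [f"{prefix}{i}" for i in range(n)], names,
        list(labels) if labels is not None else None,
    )


class RhoPCA:
    """Contrastive dimension reduction by Rayleigh-quotient maximization.

    Parameters
    ----------
    pair : CovariancePair
        Target and background covariances on a shared feature set.
    data_t, data_b : ScaledMatrix, optional
        The matrices the covariances came from; when present, ``fit``
        also computes projections and per-group variance ratios.
    """

    def __init__(
        self,
        pair: CovariancePair,
        data_t: ScaledMatrix | None = None,
        data_b: ScaledMatrix | None = None,
    ) -> None:
        self.pair = pair
        self.data_t = data_t
        self.data_b = data_b

    # ---------------------------------------------------------------- constructors
    @classmethod
    def from_covariances(
        cls,
        sigma_t: np.ndarray,
        sigma_b: np.ndarray,
        feature_names: Sequence[str] | None = None,
    ) -> "RhoPCA":
        """Build directly from precomputed covariance matrices."""
        names = list(feature_names) if feature_names is not None else None
        return cls(CovariancePair(sigma_t, sigma_b, feature_names=names))

    @classmethod
    def from_data(
        cls,
        x_t: np.ndarray,
        x_b: np.ndarray | None = None,
        *,
        feature_names: Sequence[str] | None = None,
        labels_t: Sequence[str] | None = None,
        labels_b: Sequence[str] | None = None,
        scale: bool = False,
    ) -> "RhoPCA":
        """Build from data matrices (rows = observations).

        ``x_b=None`` uses an identity background, reducing the method to
        ordinary PCA of the target covariance. ``scale=True`` standard-scales
        each group separately first, making both covariances correlation
        matrices.
        """
        sm_t = _as_scaled(x_t, feature_names, labels_t, "t")
        if x_b is None:
            sm_b = None
            if scale:
                sm_t = standard_scale(sm_t)
            pair = CovariancePair(
                sample_covariance(sm_t), np.eye(sm_t.n_features),
                feature_names=sm_t.feature_names, n_t=sm_t.n_samples,
            )
        else:
            sm_b = _as_scaled(x_b, feature_names, labels_b, "b")
            if sm_t.feature_names != sm_b.feature_names:
                raise InvalidInputError("target/background feature names differ")
            if scale:
                sm_t = standard_scale(sm_t)
                sm_b = standard_scale(sm_b)
            pair = CovariancePair(
                sample_covariance(sm_t), sample_covariance(sm_b),
                feature_names=sm_t.feature_names,
                n_t=sm_t.n_samples, n_b=sm_b.n_samples,
            )
        return cls(pair, sm_t, sm_b)

    @classmethod
    def from_dataframes(
        cls,
        df_t: pd.DataFrame,
        df_b: pd.DataFrame | None = None,
        *,
        labels_t: Sequence[str] | None = None,
        labels_b: Sequence[str] | None = None,
        scale: bool = False,
    ) -> "RhoPCA":
        """Build from pandas DataFrames (columns = features, index = samples)."""
        if df_b is not None and list(df_t.columns) != list(df_b.columns):
            raise InvalidInputError("target/background dataframe columns differ")
        model = cls.from_data(
            df_t.to_numpy(dtype=float),
            df_b.to_numpy(dtype=float) if df_b is not None else None,
            feature_names=[str(c) for c in df_t.columns],
            labels_t=labels_t, labels_b=labels_b, scale=scale,
        )
        model.data_t.sample_names = [str(i) for i in df_t.index]
        if df_b is not None:
            model.data_b.sample_names = [str(i) for i in df_b.index]
        return model

    @classmethod
    def from_counts(
        cls,
        target: CountMatrix,
        background: CountMatrix,
        *,
        percentile: float = 80.0,
        target_sum: float = 10_000.0,
        n_top: int | None = 2000,
        n_bins: int = 20,
        scale: bool = True,
    ) -> "RhoPCA":
        """Build from raw counts via the full preprocessing chain.

        Filter high-expression features (pooled totals), depth-normalize to
        ``target_sum`` and log1p, select ``n_top`` highly variable features
        on the target group, standard-scale each group separately.
        """
        sm_t, sm_b, pair = preprocess_pair(
            target, background, percentile=percentile, target_sum=target_sum,
            n_top=n_top, n_bins=n_bins, scale=scale,
        )
        return cls(pair, sm_t, sm_b)

    @classmethod
    def from_replicates(cls, reps: ReplicateSet,
                        feature_names: Sequence[str] | None = None) -> "RhoPCA":
        """Build from per-replicate covariances by (weighted) averaging."""
        return cls(average_covariances(reps, feature_names))

    # ---------------------------------------------------------------------- fit
    def fit(self, n_components: int | None = None, mu: float | str = "auto") -> "RhoPCAResults":
        """Solve the generalized eigenproblem and assemble results."""
        sol = solve_rho_pca(self.pair, d=n_components, mu=mu)
        report = None
        if self.data_t is not None and self.data_b is not None:
            report = build_report(self.data_t, self.data_b, sol)
        elif self.data_t is not None:
            # identity background: report against the same scores
            report = build_report(self.data_t, self.data_t, sol)
        return RhoPCAResults(self, sol, report)


class RhoPCAResults:
    """Fitted generalized eigenpairs plus interpretive outputs.

    Attributes
    ----------
    solution : GeneralizedEigenSolution
    eigenvalues : (d,) ndarray — target/background variance ratio per component
    components : (D, d) ndarray — generalized eigenvectors (columns)
    report : ProjectionReport or None — present when the model held data
    """

    method = "rhoPCA"

    def __init__(self, model: RhoPCA, solution: GeneralizedEigenSolution,
                 report: ProjectionReport | None) -> None:
        self.model = model
        self.solution = solution
        self.report = report

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.solution.values

    @property
    def components(self) -> np.ndarray:
        return self.solution.vectors

    @property
    def mu(self) -> float:
        return self.solution.mu

    @property
    def loadings(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.solution.vectors,
            index=pd.Index(self.solution.feature_names, name="feature"),
            columns=[f"GE{i + 1}" for i in range(self.solution.d)],
        )

    def transform(self, x: np.ndarray | ScaledMatrix) -> np.ndarray:
        """Project new observations onto the fitted components."""
        from .analysis import project

        return project(x, self.solution)

    def rayleigh(self, v: np.ndarray) -> float:
        """Rayleigh quotient of an arbitrary direction under the fitted pair."""
        return rayleigh_quotient(v, self.model.pair)

    def top_loadings(self, k: int = 10) -> pd.DataFrame:
        return top_loadings(self.solution, k)

    def group_variance_ratios(self) -> pd.DataFrame:
        if self.report is None:
            raise InvalidInputError("no data attached; fit from data to get ratios")
        return self.report.group_ratios

    def save(self, directory) -> None:
        """Write the report directory (scores, loadings, eigenvalues, ratios)."""
        from .io import write_report, write_solution

        write_solution(directory, self.solution)
        if self.report is not None:
            write_report(directory, self.report)

    def summary(self, k_loadings: int = 3) -> str:
        """Human-readable fit summary in the spirit of statsmodels results."""
        sol = self.solution
        lines = [
            f"{self.method} fit",
            "=" * 64,
            f"features:            {sol.dim}",
            f"components retained: {sol.d}",
            f"regularization mu:   {sol.mu:.6g}",
        ]
        if self.model.pair.n_t:
            lines.append(f"n target / background: {self.model.pair.n_t} / {self.model.pair.n_b}")
        lines.append("-" * 64)
        lines.append("component  eigenvalue (target/background variance ratio)")
        for i, lam in enumerate(sol.values):
            lines.append(f"  GE{i + 1:<7d} {lam:.6g}")
        lines.append("-" * 64)
        lines.append(f"top {k_loadings} loadings per component:")
        tl = self.top_loadings(min(k_loadings, sol.dim))
        for comp, sub in tl.groupby("component", sort=False):
            feats = ", ".join(f"{r.feature} ({r.loading:+.3f})" for r in sub.itertuples())
            lines.append(f"  {comp}: {feats}")
        return "\n".join(lines)


class ContrastivePCA:
    """cPCA baseline: eigendecomposition of C_alpha = S_T - alpha * S_B."""

    def __init__(self, pair: CovariancePair,
                 data_t: ScaledMatrix | None = None,
                 data_b: ScaledMatrix | None = None) -> None:
        self.pair = pair
        self.data_t = data_t
        self.data_b = data_b

    from_covariances = classmethod(RhoPCA.from_covariances.__func__)
    from_data = classmethod(RhoPCA.from_data.__func__)

    def fit(self, alpha: float = 1.0, n_components: int | None = None,
            pre_reduce_dim: int | None = None) -> "ContrastivePCAResults":
        d = n_components if n_components is not None else self.pair.dim
        cm = contrastive_matrix(self.pair, alpha)
        vectors, values = cpca_components(cm, d, pre_reduce_dim=pre_reduce_dim)
        return ContrastivePCAResults(self, alpha, vectors, values)

    def fit_grid(self, alphas: Sequence[float] | None = None,
                 n_components: int | None = None) -> list["ContrastivePCAResults"]:
        """Fit across a contrast-parameter grid (default: {0} + 40 log-spaced)."""
        if alphas is None:
            alphas = DEFAULT_ALPHA_GRID
        return [self.fit(alpha=a, n_components=n_components) for a in alphas]


class ContrastivePCAResults:
    """Eigenpairs of the contrastive matrix at one alpha."""

    method = "cPCA"

    def __init__(self, model: ContrastivePCA, alpha: float,
                 components: np.ndarray, values: np.ndarray) -> None:
        self.model = model
        self.alpha = float(alpha)
        self.components = components
        self.eigenvalues = values

    def transform(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, float) @ self.components

    def summary(self) -> str:
        lines = [
            f"{self.method} fit (alpha = {self.alpha:g})",
            "=" * 64,
            f"features:            {self.components.shape[0]}",
            f"components retained: {self.components.shape[1]}",
            "component  eigenvalue of C_alpha (may be negative)",
        ]
        for i, lam in enumerate(self.eigenvalues):
            lines.append(f"  CPC{i + 1:<6d} {lam:.6g}")
        return "\n".join(lines)
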