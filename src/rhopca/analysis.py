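"""Interpretive outputs: projections, per-group variance ratios, loadings.

The central interpretability identity: projecting the same matrices that
produced the covariances onto generalized eigenvector i and taking the
ratio of target to background score variance recovers eigenvalue i exactly,
because var(X_T v) / var(X_B v) = (v'S_T v)/(v'S_B v) = lambda_i. Computing
the ratio per group then localizes which group drives each contrastive
axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .preprocess import ScaledMatrix
from .solver import GeneralizedEigenSolution


def project(data: ScaledMatrix | np.ndarray, sol: GeneralizedEigenSolution) -> np.ndarray:
    """Scores X @ V of the data on the generalized eigenvectors.

    The data must be scaled with the same per-group convention used to form
    the covariances; feature names (when present) must match the solution's.
    """
    if isinstance(data, ScaledMatrix):
        if data.feature_names != sol.feature_names:
            raise InvalidInputError(
                "feature names of data do not match the fitted solution"
            )
        x = data.values
    else:
        x = np.asarray(data, dtype=float)
    if x.shape[1] != sol.dim:
        raise InvalidInputError(
            f"data has {x.shape[1]} features, solution expects {sol.dim}"
        )
    return x @ sol.vectors


def group_variance_ratios(
    scores_t: np.ndarray,
    scores_b: np.ndarray,
    labels_t: list[str] | None = None,
    labels_b: list[str] | None = None,
) -> pd.DataFrame:
    """Target/background score-variance ratio per group and component.

    Rows are group labels (a single ``"all"`` group when labels are absent),
    columns ``GE1..GEd``. Variances use ddof=1. A group with fewer than two
    members on either side gets NaN for that row, never 0 or inf.
    """
    scores_t = np.atleast_2d(np.asarray(scores_t, float))
    scores_b = np.atleast_2d(np.asarray(scores_b, float))
    if scores_t.shape[1] != scores_b.shape[1]:
        raise InvalidInputError("score matrices disagree on component count")
    d = scores_t.shape[1]
    if labels_t is None:
        labels_t = ["all"] * scores_t.shape[0]
    if labels_b is None:
        labels_b = ["all"] * scores_b.shape[0]
    if len(labels_t) != scores_t.shape[0] or len(labels_b) != scores_b.shape[0]:
        raise InvalidInputError("label vectors must cover all score rows")
    lt = np.asarray(labels_t)
    lb = np.asarray(labels_b)
    shared = sorted(set(lt) & set(lb))
    if not shared:
        raise InvalidInputError("target and background share no group labels")
    rows = {}
    for g in shared:
        st = scores_t[lt == g]
        sb = scores_b[lb == g]
        if st.shape[0] < 2 or sb.shape[0] < 2:
            rows[g] = np.full(d, np.nan)
            continue
        var_t = st.var(axis=0, ddof=1)
        var_b = sb.var(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(var_b > 0, var_t / var_b, np.nan)
        rows[g] = ratio
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"GE{i + 1}" for i in range(d)]
    ).rename_axis("group")


def top_loadings(sol: GeneralizedEigenSolution, k: int) -> pd.DataFrame:
    """Top-k features per component, ranked by loading magnitude.

    Returns a long-format table (component, rank, feature, loading) with the
    signed loading value. Ties in magnitude order by feature index, so the
    table is deterministic under the solver's sign convention.
    """
    if not (1 <= k <= sol.dim):
        raise InvalidInputError(f"k must be in [1, {sol.dim}], got {k}")
    records = []
    for j in range(sol.d):
        col = sol.vectors[:, j]
        order = np.argsort(-np.abs(col), kind="stable")[:k]
        for rank, i in enumerate(order, start=1):
            records.append(
                {
                    "component": f"GE{j + 1}",
                    "rank": rank,
                    "feature": sol.feature_names[i],
                    "loading": col[i],
                }
            )
    return pd.DataFrame.from_records(records)


@dataclass
class ProjectionReport:
    """Everything needed to interpret a fit: scores, loadings, ratios, eigenvalues.

    ``group_ratios`` is oriented target/background throughout; NaN marks a
    ratio undefined because a group had fewer than two members on a side.
    """

    scores_t: np.ndarray
    scores_b: np.ndarray
    loadings: pd.DataFrame  # D x d, indexed by feature name
    eigenvalues: np.ndarray
    group_ratios: pd.DataFrame
    mu: float
    sample_names_t: list[str] | None = None
    sample_names_b: list[str] | None = None

    @property
    def d(self) -> int:
        return len(self.eigenvalues)


def build_report(
    data_t: ScaledMatrix | np.ndarray,
    data_b: ScaledMatrix | np.ndarray,
    sol: GeneralizedEigenSolution,
    labels_t: list[str] | None = None,
    labels_b: list[str] | None = None,
) -> ProjectionReport:
    """Project both groups and assemble the full interpretive report."""
    scores_t = project(data_t, sol)
    scores_b = project(data_b, sol)
    if labels_t is None and isinstance(data_t, ScaledMatrix):
        labels_t = data_t.group_labels
    if labels_b is None and isinstance(data_b, ScaledMatrix):
        labels_b = data_b.group_labels
    ratios = group_variance_ratios(scores_t, scores_b, labels_t, labels_b)
    loadings = pd.DataFrame(
        sol.vectors,
        index=pd.Index(sol.feature_names, name="feature"),
        columns=[f"GE{i + 1}" for i in range(sol.d)],
    )
    names_t = data_t.sample_names if isinstance(data_t, ScaledMatrix) else None
    names_b = data_b.sample_names if isinstance(data_b, ScaledMatrix) else None
    return ProjectionReport(
        scores_t=scores_t,
        scores_b=scores_b,
        loadings=loadings,
        eigenvalues=np.asarray(sol.values, float),
        group_ratios=ratios,
        mu=sol.mu,
        sample_names_t=names_t,
        sample_names_b=names_b,
    )
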