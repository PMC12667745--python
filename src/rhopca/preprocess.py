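"""Count-matrix preprocessing: filtering, depth normalization, HVG selection, scaling.

The chain mirrors standard single-cell practice: drop lowly expressed genes
(feature totals below a percentile of all feature totals), depth-normalize
each cell to a fixed total (10,000 by default) and log1p-transform, select
highly variable genes by binned-dispersion z-scores, then standard-scale
each group separately so that group covariances are correlation matrices.

Conventions (the published protocols leave these open, so they are fixed
here and logged): percentiles use linear interpolation between order
statistics with an inclusive (>=) threshold; variances use ddof=1
throughout, so a standard-scaled matrix has a sample covariance with exactly
unit diagonal; rows are observations (cells/samples) everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .covariance import CovariancePair
from .errors import AlignmentError, EmptySampleError, InvalidInputError

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Raw nonnegative counts, rows = cells/samples, columns = genes/features."""

    counts: np.ndarray
    sample_names: list[str]
    feature_names: list[str]
    group_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise InvalidInputError(f"counts must be 2-D, got shape {self.counts.shape}")
        n, g = self.counts.shape
        if n == 0 or g == 0:
            raise InvalidInputError("count matrix must be non-empty")
        if np.any(self.counts < 0):
            raise InvalidInputError("counts must be nonnegative")
        self.sample_names = [str(s) for s in self.sample_names]
        self.feature_names = [str(f) for f in self.feature_names]
        if len(self.sample_names) != n:
            raise InvalidInputError(f"{len(self.sample_names)} sample names for {n} rows")
        if len(self.feature_names) != g:
            raise InvalidInputError(f"{len(self.feature_names)} feature names for {g} columns")
        if len(set(self.sample_names)) != n or len(set(self.feature_names)) != g:
            raise InvalidInputError("sample and feature names must be unique")
        if self.group_labels is not None:
            self.group_labels = [str(x) for x in self.group_labels]
            if len(self.group_labels) != n:
                raise InvalidInputError("group_labels length must equal number of rows")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def subset_features(self, names: list[str]) -> "CountMatrix":
        """Restrict to the given features, preserving this matrix's column order."""
        wanted = set(names)
        missing = wanted - set(self.feature_names)
        if missing:
            raise AlignmentError(f"features not present: {sorted(missing)[:5]}")
        keep = [i for i, f in enumerate(self.feature_names) if f in wanted]
        return CountMatrix(
            self.counts[:, keep],
            self.sample_names,
            [self.feature_names[i] for i in keep],
            self.group_labels,
        )


@dataclass
class ScaledMatrix:
    """A transformed expression matrix with provenance flags.

    ``col_means`` / ``col_scales`` record the statistics used by the most
    recent standard-scaling step (None before scaling).
    """

    values: np.ndarray
    sample_names: list[str]
    feature_names: list[str]
    group_labels: list[str] | None = None
    depth_normalized: bool = False
    log1p: bool = False
    scaled: bool = False
    col_means: np.ndarray | None = field(default=None, repr=False)
    col_scales: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError(f"values must be 2-D, got shape {self.values.shape}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def filter_high_expression(cm: CountMatrix, percentile: float = 80.0) -> CountMatrix:
    """Keep features whose total count is at or above the given percentile of feature totals.

    The threshold is the linear-interpolation percentile of per-feature
    totals; comparison is inclusive, so ties at the threshold are kept and
    a percentile of 0 keeps everything. Column order is preserved.
    """
    if not (0 <= percentile < 100):
        raise InvalidInputError(f"percentile must be in [0, 100), got {percentile}")
    totals = cm.counts.sum(axis=0)
    threshold = float(np.percentile(totals, percentile))
    keep = totals >= threshold
    logger.info(
        "high-expression filter: percentile %.1f -> threshold %.4g, kept %d/%d features",
        percentile, threshold, int(keep.sum()), cm.n_features,
    )
    return CountMatrix(
        cm.counts[:, keep],
        cm.sample_names,
        [f for f, k in zip(cm.feature_names, keep) if k],
        cm.group_labels,
    )


def depth_normalize_log1p(cm: CountMatrix, target_sum: float = 10_000.0) -> ScaledMatrix:
    """Rescale each row to sum to ``target_sum``, then apply log(1 + x).

    Zero columns are fixed points of both steps. Rows with zero total cannot
    be normalized and raise :class:`EmptySampleError` naming them.
    """
    row_totals = cm.counts.sum(axis=1)
    empty = np.flatnonzero(row_totals <= 0)
    if empty.size:
        names = [cm.sample_names[i] for i in empty[:10]]
        raise EmptySampleError(
            f"{empty.size} sample(s) with zero total count cannot be depth-"
            f"normalized: {names}"
        )
    values = np.log1p(cm.counts * (target_sum / row_totals)[:, None])
    return ScaledMatrix(
        values,
        cm.sample_names,
        cm.feature_names,
        cm.group_labels,
        depth_normalized=True,
        log1p=True,
    )


def select_highly_variable(
    sm: ScaledMatrix, n_top: int = 2000, n_bins: int = 20
) -> list[str]:
    """Select the top features by mean-binned, z-scored dispersion.

    Per feature, compute the mean and the dispersion (variance/mean) of the
    log-normalized values; place features into ``n_bins`` equal-count bins
    by mean; z-score dispersions within each bin; return the names of the
    ``n_top`` features with the largest normalized dispersion. Binning
    removes the mean-dispersion trend so selection favors features unusually
    variable *for their expression level*.

    Zero-mean features get dispersion 0; a bin with a single member (or zero
    dispersion spread) gets z-scores of 0, which is logged. Ties in the
    final ranking break by feature index, so selection is deterministic.
    """
    g = sm.n_features
    if not (1 <= n_top <= g):
        raise InvalidInputError(f"n_top must be in [1, {g}], got {n_top}")
    if n_bins < 1:
        raise InvalidInputError(f"n_bins must be >= 1, got {n_bins}")
    means = sm.values.mean(axis=0)
    if sm.n_samples > 1:
        variances = sm.values.var(axis=0, ddof=1)
    else:
        variances = np.zeros(g)
    dispersions = np.zeros(g)
    nz = means > 0
    dispersions[nz] = variances[nz] / means[nz]

    # equal-count bins: rank features by mean, split ranks into n_bins chunks
    order = np.argsort(means, kind="stable")
    bin_ids = np.empty(g, dtype=int)
    bin_ids[order] = np.minimum((np.arange(g) * n_bins) // g, n_bins - 1)

    z = np.zeros(g)
    for b in range(n_bins):
        members = np.flatnonzero(bin_ids == b)
        if members.size == 0:
            continue
        if members.size == 1:
            logger.info("HVG bin %d has a single member; z-score set to 0", b)
            continue
        d = dispersions[members]
        sd = d.std(ddof=1)
        if sd == 0:
            z[members] = 0.0
        else:
            z[members] = (d - d.mean()) / sd

    # stable sort on -z breaks ties by feature index
    top = np.argsort(-z, kind="stable")[:n_top]
    top_sorted = np.sort(top)  # preserve original column order
    return [sm.feature_names[i] for i in top_sorted]


def standard_scale(sm: ScaledMatrix) -> ScaledMatrix:
    """Center each column to mean 0 and scale to unit variance (ddof=1).

    Constant columns cannot be scaled; they are set to all-zero and a
    warning is logged naming them. With ddof=1, the sample covariance of the
    output has exactly unit diagonal, i.e. it is the correlation matrix of
    the input.
    """
    if sm.n_samples < 2:
        raise InvalidInputError("standard scaling requires at least 2 rows")
    means = sm.values.mean(axis=0)
    stds = sm.values.std(axis=0, ddof=1)
    constant = stds == 0
    if np.any(constant):
        names = [f for f, c in zip(sm.feature_names, constant) if c]
        logger.warning(
            "%d constant column(s) set to zero after scaling: %s%s",
            len(names), names[:5], "..." if len(names) > 5 else "",
        )
    safe = np.where(constant, 1.0, stds)
    values = (sm.values - means) / safe
    values[:, constant] = 0.0
    return ScaledMatrix(
        values,
        sm.sample_names,
        sm.feature_names,
        sm.group_labels,
        depth_normalized=sm.depth_normalized,
        log1p=sm.log1p,
        scaled=True,
        col_means=means,
        col_scales=safe,
    )


def sample_covariance(sm: ScaledMatrix) -> np.ndarray:
    """Sample covariance (1/(n-1)) X'X of the column-centered matrix.

    If the input was standard-scaled this is the correlation matrix of the
    pre-scaling data (unit diagonal up to constant columns).
    """
    if sm.n_samples < 2:
        raise InvalidInputError("sample covariance requires at least 2 rows")
    centered = sm.values - sm.values.mean(axis=0)
    return (centered.T @ centered) / (sm.n_samples - 1)


def preprocess_pair(
    target: CountMatrix,
    background: CountMatrix,
    *,
    percentile: float = 80.0,
    target_sum: float = 10_000.0,
    n_top: int | None = 2000,
    n_bins: int = 20,
    scale: bool = True,
) -> tuple[ScaledMatrix, ScaledMatrix, CovariancePair]:
    """Run the full chain on a target/background pair of count matrices.

    The high-expression filter uses feature totals pooled over both groups;
    HVG selection uses the *target* group only and the chosen subset is
    applied to both; standard scaling is per group, so the covariances are
    per-group correlation matrices. Feature names must match exactly at
    every stage — divergence raises :class:`AlignmentError` rather than
    silently reindexing.
    """
    if target.feature_names != background.feature_names:
        first = next(
            (
                (a, b)
                for a, b in zip(target.feature_names, background.feature_names)
                if a != b
            ),
            None,
        )
        raise AlignmentError(
            "target and background feature names differ"
            + (f"; first divergence: {first[0]!r} vs {first[1]!r}" if first else
               " in length")
        )

    pooled_totals = target.counts.sum(axis=0) + background.counts.sum(axis=0)
    threshold = float(np.percentile(pooled_totals, percentile)) if percentile > 0 else -np.inf
    keep = [f for f, t in zip(target.feature_names, pooled_totals) if t >= threshold]
    t_f = target.subset_features(keep)
    b_f = background.subset_features(keep)

    t_norm = depth_normalize_log1p(t_f, target_sum)
    b_norm = depth_normalize_log1p(b_f, target_sum)

    if n_top is not None:
        n_top_eff = min(n_top, t_norm.n_features)
        hvgs = select_highly_variable(t_norm, n_top=n_top_eff, n_bins=n_bins)
        keep_idx = [i for i, f in enumerate(t_norm.feature_names) if f in set(hvgs)]
        t_norm = _subset_scaled(t_norm, keep_idx)
        b_norm = _subset_scaled(b_norm, keep_idx)

    if scale:
        t_out = standard_scale(t_norm)
        b_out = standard_scale(b_norm)
    else:
        t_out, b_out = t_norm, b_norm

    pair = CovariancePair(
        sample_covariance(t_out),
        sample_covariance(b_out),
        feature_names=t_out.feature_names,
        n_t=t_out.n_samples,
        n_b=b_out.n_samples,
    )
    return t_out, b_out, pair


def _subset_scaled(sm: ScaledMatrix, idx: list[int]) -> ScaledMatrix:
    return ScaledMatrix(
        sm.values[:, idx],
        sm.sample_names,
        [sm.feature_names[i] for i in idx],
        sm.group_labels,
        depth_normalized=sm.depth_normalized,
        log1p=sm.log1p,
        scaled=sm.scaled,
    )
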