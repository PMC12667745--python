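"""Readers and writers for matrices, covariances, solutions and reports.

Dense matrices travel as CSV/TSV with a header row of feature names and a
first column of sample names. Sparse counts travel as Matrix Market triplets
(``matrix.mtx``) with ``features.tsv``/``barcodes.tsv`` sidecars, assumed
features x observations (the genomics convention) unless ``transpose=False``.
Covariances are square CSVs with a feature-name header. A fitted report is a
directory of named CSVs. All dialect decisions are logged.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .analysis import ProjectionReport
from .covariance import CovariancePair
from .errors import DataError
from .preprocess import CountMatrix, ScaledMatrix
from .solver import GeneralizedEigenSolution

logger = logging.getLogger(__name__)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_dense_values(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a dense samples x features matrix as (values, sample_names, feature_names).

    Accepts any real-valued matrix (scores, scaled data, covariate tables);
    use :func:`read_dense_matrix` when nonnegative counts are required.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"cannot read {path}: no such file")
    sep = _sep_for(path)
    logger.info("reading dense matrix %s (sep=%r)", path, sep)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
    except (ValueError, OSError) as exc:
        raise DataError(f"cannot parse {path}: {exc}") from exc
    return values, [str(i) for i in df.index], [str(c) for c in df.columns]


def read_dense_matrix(path: str | Path, group_labels: list[str] | None = None) -> CountMatrix:
    """Read a dense samples x features count matrix (CSV or TSV by extension)."""
    values, samples, features = read_dense_values(path)
    return CountMatrix(values, samples, features, group_labels)


def write_dense_matrix(path: str | Path, values: np.ndarray,
                       sample_names: list[str], feature_names: list[str]) -> None:
    path = Path(path)
    pd.DataFrame(values, index=sample_names, columns=feature_names).to_csv(
        path, sep=_sep_for(path), index_label="sample"
    )


def read_mtx_values(directory: str | Path,
                    transpose: bool = True) -> tuple[np.ndarray, list[str], list[str]]:
    """Read an MTX triplet as (values, sample_names, feature_names).

    ``transpose=True`` (default) treats the MTX as features x observations
    and transposes to rows = observations; pass ``transpose=False`` for
    matrices already stored observations x features.
    """
    directory = Path(directory)
    mtx = directory / "matrix.mtx"
    feats = directory / "features.tsv"
    bars = directory / "barcodes.tsv"
    for p in (mtx, feats, bars):
        if not p.exists():
            raise DataError(f"cannot read {p}: no such file")
    logger.info("reading MTX triplet from %s (transpose=%s)", directory, transpose)
    m = scipy.io.mmread(mtx)
    if scipy.sparse.issparse(m):
        m = m.toarray()
    m = np.asarray(m, dtype=float)
    if transpose:
        m = m.T
    feature_names = [line.split("\t")[0] for line in feats.read_text().splitlines() if line]
    sample_names = [line.split("\t")[0] for line in bars.read_text().splitlines() if line]
    return m, sample_names, feature_names


def read_mtx(directory: str | Path, transpose: bool = True,
             group_labels: list[str] | None = None) -> CountMatrix:
    """Read ``matrix.mtx`` + sidecars as a validated count matrix."""
    m, samples, features = read_mtx_values(directory, transpose)
    return CountMatrix(m, samples, features, group_labels)


def write_mtx(directory: str | Path, cm: CountMatrix) -> None:
    """Write counts as an MTX triplet (features x observations) with sidecars."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(directory / "matrix.mtx", scipy.sparse.coo_matrix(cm.counts.T))
    (directory / "features.tsv").write_text("\n".join(cm.feature_names) + "\n")
    (directory / "barcodes.tsv").write_text("\n".join(cm.sample_names) + "\n")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample, label) TSV into a dict."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"cannot read {path}: no such file")
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "label"], dtype=str)
    if df["sample"].duplicated().any():
        raise DataError(f"duplicate sample names in {path}")
    return dict(zip(df["sample"], df["label"]))


def labels_for(samples: list[str] | CountMatrix | ScaledMatrix,
               mapping: dict[str, str]) -> list[str]:
    """Align a sample->label mapping to a matrix's (or name list's) row order."""
    names = samples if isinstance(samples, list) else samples.sample_names
    missing = [s for s in names if s not in mapping]
    if missing:
        raise DataError(f"{len(missing)} sample(s) missing from labels: {missing[:5]}")
    return [mapping[s] for s in names]


def read_covariance(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a square covariance CSV with a feature-name header row."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"cannot read {path}: no such file")
    df = pd.read_csv(path, sep=_sep_for(path))
    names = [str(c) for c in df.columns]
    mat = df.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise DataError(f"covariance in {path} is not square: {mat.shape}")
    return mat, names


def write_covariance(path: str | Path, mat: np.ndarray, feature_names: list[str]) -> None:
    pd.DataFrame(mat, columns=feature_names).to_csv(path, sep=_sep_for(Path(path)), index=False)


def write_solution(directory: str | Path, sol: GeneralizedEigenSolution) -> None:
    """Serialize a solution as ``vectors.csv`` (D x d) and ``values.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cols = [f"GE{i + 1}" for i in range(sol.d)]
    pd.DataFrame(sol.vectors, index=pd.Index(sol.feature_names, name="feature"),
                 columns=cols).to_csv(directory / "vectors.csv")
    pd.DataFrame({"lambda": sol.values, "mu": sol.mu, "d": sol.d}).to_csv(
        directory / "values.csv", index=False
    )


def read_solution(directory: str | Path) -> GeneralizedEigenSolution:
    directory = Path(directory)
    vec = pd.read_csv(directory / "vectors.csv", index_col=0)
    val = pd.read_csv(directory / "values.csv")
    return GeneralizedEigenSolution(
        vectors=vec.to_numpy(dtype=float),
        values=val["lambda"].to_numpy(dtype=float),
        mu=float(val["mu"].iloc[0]),
        feature_names=[str(i) for i in vec.index],
    )


_RATIO_HEADER = "# per-group score-variance ratios, oriented target/background\n"


def write_report(directory: str | Path, report: ProjectionReport) -> None:
    """Write the report directory: scores, loadings, eigenvalues, group ratios."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cols = [f"GE{i + 1}" for i in range(report.d)]

    def _scores(name: str, scores: np.ndarray, idx: list[str] | None) -> None:
        index = idx if idx is not None else [str(i) for i in range(scores.shape[0])]
        pd.DataFrame(scores, index=pd.Index(index, name="sample"),
                     columns=cols).to_csv(directory / name)

    _scores("scores_target.csv", report.scores_t, report.sample_names_t)
    _scores("scores_background.csv", report.scores_b, report.sample_names_b)
    report.loadings.to_csv(directory / "loadings.csv")
    pd.DataFrame({"component": cols, "lambda": report.eigenvalues,
                  "mu": report.mu}).to_csv(directory / "eigenvalues.csv", index=False)
    with open(directory / "group_ratios.csv", "w") as fh:
        fh.write(_RATIO_HEADER)
        report.group_ratios.to_csv(fh)


def read_report(directory: str | Path) -> ProjectionReport:
    directory = Path(directory)
    st = pd.read_csv(directory / "scores_target.csv", index_col=0)
    sb = pd.read_csv(directory / "scores_background.csv", index_col=0)
    loadings = pd.read_csv(directory / "loadings.csv", index_col=0)
    ev = pd.read_csv(directory / "eigenvalues.csv")
    ratios = pd.read_csv(directory / "group_ratios.csv", index_col=0, comment="#")
    return ProjectionReport(
        scores_t=st.to_numpy(dtype=float),
        scores_b=sb.to_numpy(dtype=float),
        loadings=loadings,
        eigenvalues=ev["lambda"].to_numpy(dtype=float),
        group_ratios=ratios,
        mu=float(ev["mu"].iloc[0]),
        sample_names_t=[str(i) for i in st.index],
        sample_names_b=[str(i) for i in sb.index],
    )


def write_manifest(path: str | Path, manifest: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
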