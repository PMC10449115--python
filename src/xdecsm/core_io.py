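"""Reading, writing and preprocessing of expression matrices.

Expression data move through the pipeline as :class:`ExpressionMatrix`
objects: a dense nonnegative genes x samples array with unique string
identifiers on both axes.  Files are plain TSV/CSV (header row = sample
ids, first column = gene ids) or MatrixMarket coordinate triplets with
sidecar gene/cell id files, the usual scRNA-seq exchange convention.

Preprocessing mirrors standard bulk RNA-seq practice: quantile
normalization across samples, and removal of genes whose transformed
expression is uniformly close to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.stats

if TYPE_CHECKING:  # pragma: no cover
    from .transform import TransformedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_list",
    "read_sample_annotations",
    "quantile_normalize",
    "filter_low_expression",
]


def _check_ids(ids: Sequence[str], axis: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {axis} identifier: {dup!r}")
    return ids


@dataclass
class ExpressionMatrix:
    """Dense nonnegative genes x samples expression matrix.

    Parameters
    ----------
    values
        2D array of finite, nonnegative expression values (counts or
        abundances; scale is arbitrary).
    gene_ids, sample_ids
        Unique string identifiers for rows and columns.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2D matrix")
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be nonnegative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` (order taken from the argument)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(self.values[rows, :], list(genes), list(self.sample_ids))

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        cols = [index[s] for s in samples]
        return ExpressionMatrix(self.values[:, cols], list(self.gene_ids), list(samples))


@dataclass
class SampleAnnotation:
    """Per-sample metadata: intrinsic subtype, therapy response, grouping."""

    sample_id: str
    subtype_label: Optional[str] = None
    response: Optional[int] = None
    group: Optional[str] = None


def read_expression_matrix(
    path: str | Path,
    format: str = "tsv",
    *,
    genes_path: str | Path | None = None,
    samples_path: str | Path | None = None,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from disk.

    ``format`` is one of ``tsv``, ``csv`` (header = sample ids, first
    column = gene ids) or ``mtx-triplet`` (MatrixMarket coordinate file
    with one-column ``genes_path``/``samples_path`` sidecars).  With
    ``transpose`` the file is read samples-in-rows and flipped; matrix
    orientation is never guessed from the contents.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        if transpose:
            df = df.T
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError(f"non-numeric entries in {path}")
        return ExpressionMatrix(values, list(df.index.astype(str)), list(df.columns.astype(str)))
    if format == "mtx-triplet":
        if genes_path is None or samples_path is None:
            raise ValueError("mtx-triplet requires genes_path and samples_path sidecars")
        for p in (genes_path, samples_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        mat = scipy.io.mmread(str(path)).toarray()
        genes = Path(genes_path).read_text().split()
        samples = Path(samples_path).read_text().split()
        if transpose:
            mat = mat.T
        if mat.shape != (len(genes), len(samples)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match id files "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        return ExpressionMatrix(mat, genes, samples)
    raise ValueError(f"unknown format {format!r}")


def write_expression_matrix(X: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    sep = "\t" if format == "tsv" else ","
    X.to_frame().to_csv(path, sep=sep, index_label="gene_id")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line gene list, skipping blanks."""
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def read_sample_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read an annotation TSV with columns sample_id, subtype_label, response, group."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "sample_id" not in df.columns:
        raise ValueError("annotation file must have a sample_id column")
    out = []
    for _, row in df.iterrows():
        resp = row.get("response", "")
        out.append(
            SampleAnnotation(
                sample_id=row["sample_id"],
                subtype_label=row.get("subtype_label", "") or None,
                response=int(resp) if resp != "" else None,
                group=row.get("group", "") or None,
            )
        )
    return out


def quantile_normalize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns to a common distribution.

    Every sample's values are replaced by the mean, across samples, of
    the values at the same rank; ties within a sample receive the mean
    of their ranks' reference values.  After normalization all columns
    share the identical sorted value multiset.
    """
    if X.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    V = X.values
    reference = np.mean(np.sort(V, axis=0), axis=1)
    out = np.empty_like(V)
    for j in range(V.shape[1]):
        # midranks map ties to the mean of the tied reference values
        ranks = scipy.stats.rankdata(V[:, j], method="average") - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    return ExpressionMatrix(out, list(X.gene_ids), list(X.sample_ids))


def filter_low_expression(T: "TransformedMatrix", min_mean: float = 0.01) -> "TransformedMatrix":
    """Drop genes whose across-sample mean transformed value is below ``min_mean``.

    Retains exactly the genes with mean >= ``min_mean`` (strict-< removal);
    the sample set and the gene order are unchanged.
    """
    from .transform import TransformedMatrix

    means = T.values.mean(axis=1)
    keep = means >= min_mean
    if not keep.any():
        raise ValueError(f"all {T.values.shape[0]} genes fall below mean {min_mean}")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("filter_low_expression: removed %d genes with mean < %g", n_dropped, min_mean)
    return TransformedMatrix(
        T.values[keep, :],
        [g for g, k in zip(T.gene_ids, keep) if k],
        list(T.sample_ids),
        scale_a=T.scale_a,
    )


def intersect_gene_list(requested: Sequence[str], available: Sequence[str], label: str = "gene list") -> list[str]:
    """Exact, case-sensitive intersection of a requested gene list with a matrix.

    Warns when fewer than 90% of the requested symbols are found (a
    typical literature list loses a symbol or two to annotation drift).
    """
    avail = set(available)
    found = [g for g in requested if g in avail]
    if requested and len(found) / len(requested) < 0.9:
        logger.warning(
            "%s: only %d/%d symbols found in the matrix", label, len(found), len(requested)
        )
    return found
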