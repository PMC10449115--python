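"""Negative-exponential mapping of expression counts into the 0-1 range.

The factorization stages operate on values bounded in [0, 1), an
"activation-like" scale that de-emphasizes absolute transcript
abundance in favour of on/off transcriptional state.  The mapping is a
single-parameter negative exponential,

    y = 1 - exp(-a * x),    a = 1 / max{x},

where the scale ``a`` is fit as the reciprocal of the global maximum of
the matrix, so the largest observed count maps to 1 - 1/e and zeros map
to 0.  The mapping is strictly monotone, hence rank-preserving within
every gene and sample, and has the analytic inverse x = -ln(1 - y) / a.

Note the image of the fitted transform on observed data is
[0, 1 - 1/e], not the full unit interval; values are deliberately not
rescaled to reach 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core_io import ExpressionMatrix, _check_ids

__all__ = ["TransformedMatrix", "transform_counts", "inverse_transform"]


@dataclass
class TransformedMatrix:
    """Genes x samples matrix of transformed values in [0, 1).

    ``scale_a`` records the transform parameter so the raw scale can be
    recovered analytically.  With per-gene scaling ``scale_a`` is a
    vector with one entry per gene.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    scale_a: float | np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("shape does not match identifier lists")
        if np.any(self.values < 0) or np.any(self.values >= 1):
            raise ValueError("transformed values must lie in [0, 1)")
        if np.any(np.asarray(self.scale_a) <= 0):
            raise ValueError("scale_a must be positive")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: Sequence[str]) -> "TransformedMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [index[g] for g in genes]
        a = self.scale_a
        if isinstance(a, np.ndarray):
            a = a[rows]
        return TransformedMatrix(self.values[rows, :], list(genes), list(self.sample_ids), a)

    def subset_samples(self, samples: Sequence[str]) -> "TransformedMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        cols = [index[s] for s in samples]
        return TransformedMatrix(self.values[:, cols], list(self.gene_ids), list(samples), self.scale_a)


def transform_counts(
    X: ExpressionMatrix,
    scale_a: Optional[float] = None,
    per_gene: bool = False,
) -> TransformedMatrix:
    """Map nonnegative counts into [0, 1) via y = 1 - exp(-a*x).

    When ``scale_a`` is omitted it is fit as 1/max over all entries of
    ``X`` (one scalar per matrix), so the global maximum maps to
    1 - 1/e.  ``per_gene`` instead fits one scale per gene row (an
    experimentation option; genes with an all-zero row are rejected).
    """
    V = X.values
    if per_gene:
        row_max = V.max(axis=1)
        if np.any(row_max <= 0):
            raise ValueError("per-gene scaling undefined for all-zero gene rows")
        a: float | np.ndarray = 1.0 / row_max
        y = -np.expm1(-a[:, None] * V)  # expm1 keeps tiny counts distinct
    else:
        if scale_a is None:
            m = V.max()
            if m <= 0:
                raise ValueError("scale undefined for an all-zero matrix")
            scale_a = 1.0 / m
        elif scale_a <= 0:
            raise ValueError("scale_a must be positive")
        a = float(scale_a)
        y = -np.expm1(-a * V)
    return TransformedMatrix(y, list(X.gene_ids), list(X.sample_ids), a)


def inverse_transform(T: TransformedMatrix) -> ExpressionMatrix:
    """Recover raw counts via the analytic inverse x = -ln(1 - y) / a."""
    a = np.asarray(T.scale_a)
    if a.ndim == 1:
        x = -np.log1p(-T.values) / a[:, None]
    else:
        x = -np.log1p(-T.values) / float(a)
    return ExpressionMatrix(x, list(T.gene_ids), list(T.sample_ids))
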