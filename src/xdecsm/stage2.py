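"""Stage 2: recovery of untransformed per-cell-type expression profiles.

Stage 1 proportions are taken as known and, for each gene
independently, the untransformed expression of each constituent cell
type is estimated by non-negative least squares against the raw (or
quantile-normalized, but untransformed) counts:

    m_g = argmin ||x_g - m' P||^2   subject to  m >= 0.

The recovered profile is the average expression of that cell type over
the sample set used, so Stage 2 is typically run per cohort subgroup
(e.g. samples grouped by their dominant epithelial component).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from ._qp import solve_box_batch
from .core_io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["Stage2Profiles", "run_stage2", "group_samples_by_dominant_profile"]


@dataclass
class Stage2Profiles:
    """Untransformed genes x k expression profiles for one sample group.

    Components whose mean proportion in the group is negligible are
    unidentifiable there; their columns are NaN, not zero.
    """

    values: np.ndarray
    gene_ids: list[str]
    component_labels: list[str]
    group_id: str = "all"

    def __post_init__(self) -> None:
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < 0:
            raise ValueError("recovered expression must be nonnegative")


def run_stage2(
    X: ExpressionMatrix,
    P: np.ndarray,
    sample_subset: Optional[Sequence[str]] = None,
    component_labels: Optional[Sequence[str]] = None,
    group_id: str = "all",
    min_mean_proportion: float = 0.01,
) -> Stage2Profiles:
    """Per-gene NNLS recovery of untransformed cell-type expression.

    ``X`` is the untransformed matrix whose samples align with the
    columns of the proportion matrix ``P`` (k x samples).  With
    ``sample_subset`` both are restricted first.  Components averaging
    below ``min_mean_proportion`` in the subset are reported as NaN
    columns (flagged unidentifiable) rather than fitted.
    """
    P = np.asarray(P, dtype=float)
    k = P.shape[0]
    if P.shape[1] != X.n_samples:
        raise ValueError("P columns must align with the samples of X")
    if np.any(P < 0) or np.abs(P.sum(axis=0) - 1.0).max() > 1e-6:
        raise ValueError("proportion columns must lie on the simplex")
    labels = list(component_labels) if component_labels else [f"component_{i}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("one label per component is required")
    if sample_subset is not None:
        idx = [X.sample_ids.index(s) for s in sample_subset]
        if len(idx) < k:
            raise ValueError(
                f"sample subset has {len(idx)} samples, fewer than k={k} components"
            )
        X_values = X.values[:, idx]
        P = P[:, idx]
    else:
        if X.n_samples < k:
            raise ValueError("fewer samples than components")
        X_values = X.values

    usable = P.mean(axis=1) >= min_mean_proportion
    if not usable.all():
        bad = [labels[i] for i in range(k) if not usable[i]]
        logger.warning("components unidentifiable in group %s: %s", group_id, bad)
    M = np.full((X_values.shape[0], k), np.nan)
    if usable.any():
        sub = solve_box_batch(P[usable, :], X_values, upper=None)
        M[:, usable] = sub
    return Stage2Profiles(M, list(X.gene_ids), labels, group_id)


def group_samples_by_dominant_profile(
    P: np.ndarray,
    sample_ids: Sequence[str],
    component_labels: Sequence[str],
    aggregate: Mapping[str, str],
    candidate_components: Optional[Sequence[str]] = None,
) -> tuple[dict[str, list[str]], np.ndarray, list[str]]:
    """Group samples by their single largest (epithelial) component.

    ``aggregate`` maps every component label to a super-class (e.g. the
    nine-component model collapsing to epithelial/stromal/immune);
    super-class proportions are sums of mapped components, so each
    sample's super-class proportions still total 1.  Grouping uses the
    per-component (not super-class) proportions restricted to
    ``candidate_components`` (default: all); exact ties go to the
    earlier component in label order and are logged.

    Returns (groups, super-class proportion matrix, super-class order).
    """
    P = np.asarray(P, dtype=float)
    labels = list(component_labels)
    if set(aggregate) != set(labels):
        raise ValueError("aggregation mapping must cover exactly the component labels")
    supers: list[str] = []
    for lab in labels:
        if aggregate[lab] not in supers:
            supers.append(aggregate[lab])
    S = np.zeros((len(supers), P.shape[1]))
    for i, lab in enumerate(labels):
        S[supers.index(aggregate[lab]), :] += P[i, :]

    cand = list(candidate_components) if candidate_components is not None else labels
    cand_idx = [labels.index(c) for c in cand]
    sub = P[cand_idx, :]
    groups: dict[str, list[str]] = {c: [] for c in cand}
    for j, s in enumerate(sample_ids):
        col = sub[:, j]
        top = np.flatnonzero(col == col.max())
        if len(top) > 1:
            logger.info("sample %s ties between components %s", s,
                        [cand[i] for i in top])
        groups[cand[top[0]]].append(s)
    return groups, S, supers
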