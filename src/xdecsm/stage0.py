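"""Stage 0: reference construction and informative-gene selection.

The factorization itself is reference-free; references enter only here,
to decide *which* genes carry cell-type information.  Two reference
routes are supported:

* bulk reference profiles (e.g. sorted cell lines), already one column
  per profile with a cell-type class label;
* labelled single-cell counts, collapsed into pseudo-bulk profiles:
  per cell type, cells passing a total-count floor are ranked by
  coverage, summed in consecutive groups of five, depth-matched to the
  deepest pseudo-bulk, and 0-1 transformed.

Informative genes are chosen by differential expression on the
transformed values: one-vs-rest pooled-variance t-tests per class plus optional
direct pairwise contrasts; within each contrast, the top up- and
down-regulated genes passing the p threshold are kept.  A gene selected
by more than one contrast is *excluded* outright (it cannot cleanly
represent a single cell type); a literature list (e.g. PAM50) may be
unioned afterwards and is exempt from that exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.stats

from .core_io import ExpressionMatrix, intersect_gene_list
from .transform import TransformedMatrix, transform_counts

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceSet",
    "InformativeGeneSet",
    "build_pseudobulks",
    "differential_t_test",
    "select_informative_genes",
    "SELECTION_PRESETS",
]

# Named contrast recipes (p threshold, per-contrast top-n up/down, pairwise
# contrasts with their own thresholds) for the three typical reference kinds.
SELECTION_PRESETS: dict[str, dict] = {
    # four bulk classes: cancer epithelial, normal epithelial, immune, stroma
    "simulated": {
        "p_threshold": 1e-4,
        "n_top": 25,
        "pairwise": [
            ("cancer_epithelial", "stroma", 1e-4, 25),
            ("normal_epithelial", "stroma", 1e-4, 25),
        ],
    },
    # seven sorted cell-line classes; one deeper epithelial/stroma contrast
    "cell-line": {
        "p_threshold": 1e-4,
        "n_top": 25,
        "pairwise": [("epithelial", "stroma", 1e-5, 75)],
    },
    # four pseudo-bulk classes from labelled single cells
    "single-cell": {
        "p_threshold": 0.05,
        "n_top": 50,
        "pairwise": [("T cell", "macrophage", 0.05, 25)],
    },
}


@dataclass
class ReferenceSet:
    """Transformed reference profiles grouped by cell-type class."""

    profiles: TransformedMatrix
    class_labels: list[str]
    provenance: str = "bulk reference"

    def __post_init__(self) -> None:
        if len(self.class_labels) != self.profiles.n_samples:
            raise ValueError("one class label per profile column is required")
        counts = {c: self.class_labels.count(c) for c in set(self.class_labels)}
        small = [c for c, n in counts.items() if n < 2]
        if small:
            raise ValueError(f"classes with fewer than 2 profiles: {small}")

    def classes(self) -> list[str]:
        seen: list[str] = []
        for c in self.class_labels:
            if c not in seen:
                seen.append(c)
        return seen

    def class_columns(self, cls: str) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.class_labels) if c == cls])

    def class_mean(self, cls: str) -> np.ndarray:
        return self.profiles.values[:, self.class_columns(cls)].mean(axis=1)


@dataclass
class InformativeGeneSet:
    """Ordered informative genes with per-gene provenance records."""

    gene_ids: list[str]
    source: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("informative gene set contains duplicates")

    @property
    def n_total(self) -> int:
        return len(self.gene_ids)


def build_pseudobulks(
    sc: ExpressionMatrix,
    cell_labels: Sequence[str],
    group_size: int = 5,
    min_total_counts: float = 100_000,
) -> ReferenceSet:
    """Collapse labelled single-cell counts into transformed pseudo-bulks.

    Per cell type: cells with total counts below ``min_total_counts``
    are dropped, survivors are ranked by descending total counts and
    summed in consecutive blocks of ``group_size`` (an incomplete
    trailing block is discarded).  Every pseudo-bulk is then rescaled
    to the depth of the deepest pseudo-bulk across all types, and the
    whole set is 0-1 transformed.  Types ending up with zero
    pseudo-bulks are dropped with a warning.
    """
    if len(cell_labels) != sc.n_samples:
        raise ValueError("one label per cell is required")
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    totals = sc.values.sum(axis=0)
    columns: list[np.ndarray] = []
    labels: list[str] = []
    names: list[str] = []
    seen: list[str] = []
    for c in cell_labels:
        if c not in seen:
            seen.append(c)
    for cls in seen:
        idx = np.array([i for i, c in enumerate(cell_labels) if c == cls])
        idx = idx[totals[idx] >= min_total_counts]
        # t-tests downstream need within-class replication: 2 full blocks
        if len(idx) < 2 * group_size:
            logger.warning(
                "cell type %r dropped: %d cells pass the coverage floor "
                "(need >= %d for two pseudo-bulks)", cls, len(idx), 2 * group_size
            )
            continue
        order = idx[np.argsort(-totals[idx], kind="stable")]
        n_blocks = len(order) // group_size
        for b in range(n_blocks):
            block = order[b * group_size : (b + 1) * group_size]
            columns.append(sc.values[:, block].sum(axis=1))
            labels.append(cls)
            names.append(f"{cls}_pb{b + 1}")
    if not columns:
        raise ValueError("no cell type yields a complete pseudo-bulk")
    V = np.column_stack(columns)
    depth = V.sum(axis=0)
    V = V * (depth.max() / depth)[None, :]
    raw = ExpressionMatrix(V, list(sc.gene_ids), names)
    return ReferenceSet(transform_counts(raw), labels, provenance="single-cell pseudo-bulk")


def differential_t_test(
    group_a: np.ndarray, group_b: np.ndarray
) -> tuple[float, float, float]:
    """Pooled-variance two-sample t-test plus the difference of group means (a - b).

    The pooled (Student) form is used throughout selection: with
    reference classes as small as 4 profiles, separate-variance df
    collapse and stringent p thresholds become unreachable.  Degenerate
    case: both groups constant with equal means gives (0, 1, 0) by
    convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 observations")
    mean_diff = float(a.mean() - b.mean())
    if a.std() == 0 and b.std() == 0:
        if mean_diff == 0:
            return 0.0, 1.0, 0.0
        return float("inf") * np.sign(mean_diff), 0.0, mean_diff
    t, p = scipy.stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p), mean_diff


def _contrast_select(
    values: np.ndarray,
    gene_ids: Sequence[str],
    cols_a: np.ndarray,
    cols_b: np.ndarray,
    p_threshold: float,
    n_top: int,
    contrast_name: str,
) -> tuple[list[str], list[str]]:
    """Top up-/down-regulated genes of one contrast, ranked by t-statistic.

    Pooled-variance (Student) two-sample t-tests gate (p < threshold)
    and rank the candidates.  Ranking by t rather than raw mean
    difference matters for the down direction: genes that are merely
    high in one *other* class have a large negative mean difference but
    a noisy rest group, so the t ranking favours genes consistently low
    in the class — exactly what should represent it — instead of
    re-selecting other classes' markers, which the multi-appearance
    exclusion would then delete.  Ties break by |mean difference| then
    gene id, so selection is deterministic.
    """
    A, B = values[:, cols_a], values[:, cols_b]
    t, p = scipy.stats.ttest_ind(A, B, axis=1, equal_var=True)
    diff = A.mean(axis=1) - B.mean(axis=1)
    both_const = (A.std(axis=1) == 0) & (B.std(axis=1) == 0)
    p = np.where(both_const & (diff == 0), 1.0, p)
    p = np.where(both_const & (diff != 0), 0.0, p)
    t = np.where(both_const, np.sign(diff) * np.inf, t)
    sig = np.where(np.nan_to_num(p, nan=1.0) < p_threshold)[0]

    def take(direction: int) -> list[str]:
        cand = sig[np.sign(diff[sig]) == direction]
        order = sorted(
            cand, key=lambda i: (-direction * t[i], -abs(diff[i]), gene_ids[i])
        )
        chosen = [gene_ids[i] for i in order[:n_top]]
        if len(chosen) < n_top:
            logger.warning(
                "contrast %s: only %d/%d %s-regulated significant genes",
                contrast_name, len(chosen), n_top, "up" if direction > 0 else "down",
            )
        return chosen

    return take(+1), take(-1)


def select_informative_genes(
    refs: ReferenceSet,
    p_threshold: float = 1e-4,
    n_top: int = 25,
    pairwise: Optional[Sequence[tuple]] = None,
    literature_genes: Optional[Sequence[str]] = None,
    preset: Optional[str] = None,
) -> InformativeGeneSet:
    """Select informative genes by one-vs-rest and pairwise contrasts.

    For each class a one-vs-rest pooled-variance t-test on the transformed values
    picks the ``n_top`` most up- and most down-regulated significant
    genes; each ``pairwise`` contrast ``(class_a, class_b, p, n_top)``
    does the same directly between two classes.  Any gene appearing in
    more than one contrast's list is removed entirely — exclusion, not
    deduplication.  ``literature_genes`` present in the reference
    matrix are unioned last and never excluded by that rule.  A
    ``preset`` name (see :data:`SELECTION_PRESETS`) fills the contrast
    parameters.
    """
    if preset is not None:
        recipe = SELECTION_PRESETS[preset]
        p_threshold = recipe["p_threshold"]
        n_top = recipe["n_top"]
        pairwise = recipe["pairwise"]
    values = refs.profiles.values
    gene_ids = list(refs.profiles.gene_ids)
    classes = refs.classes()
    all_cols = np.arange(values.shape[1])

    lists: list[tuple[str, list[str]]] = []
    for cls in classes:
        cols = refs.class_columns(cls)
        rest = np.setdiff1d(all_cols, cols)
        up, down = _contrast_select(
            values, gene_ids, cols, rest, p_threshold, n_top, f"{cls}_vs_rest"
        )
        lists.append((f"{cls}_vs_rest", up + down))
    for contrast in pairwise or []:
        cls_a, cls_b, p_thr, ntop = contrast
        up, down = _contrast_select(
            values, gene_ids, refs.class_columns(cls_a), refs.class_columns(cls_b),
            p_thr, ntop, f"{cls_a}_vs_{cls_b}",
        )
        lists.append((f"{cls_a}_vs_{cls_b}", up + down))

    appearances: dict[str, list[str]] = {}
    for name, genes in lists:
        for g in genes:
            appearances.setdefault(g, []).append(name)
    selected: list[str] = []
    source: dict[str, str] = {}
    for name, genes in lists:
        for g in genes:
            if len(appearances[g]) == 1 and g not in source:
                selected.append(g)
                source[g] = name
    n_excluded = sum(1 for g, a in appearances.items() if len(a) > 1)
    if n_excluded:
        logger.info("excluded %d genes selected by multiple contrasts", n_excluded)

    if literature_genes:
        present = intersect_gene_list(literature_genes, gene_ids, "literature list")
        for g in present:
            if g not in source:
                selected.append(g)
                source[g] = "literature"
            elif source[g] != "literature":
                source[g] += "+literature"
    return InformativeGeneSet(selected, source)
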