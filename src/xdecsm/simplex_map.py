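"""The cancer cell state map: a Basal-HER2-Luminal proportion simplex.

Samples whose composition is dominated by epithelial components and
that carry an appreciable cancer-epithelial fraction are projected onto
the 2-simplex spanned by the three cancer-epithelial components.  The
three proportions, renormalized to sum to 1, are the barycentric
coordinates; the nearest vertex gives a data-driven subtype call that
can be cross-tabulated against PAM50 or any other labelling.

Vertex convention for Cartesian rendering: Basal at the lower-left
corner (0, 0), HER2 at the lower-right (1, 0), Luminal at the top
(1/2, sqrt(3)/2) — an equilateral triangle of unit side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger(__name__)

__all__ = [
    "SimplexPoint",
    "VERTEX_ORDER",
    "filter_mappable_samples",
    "to_simplex_coordinates",
    "classify_by_vertex",
    "compare_classifications",
    "correlate_proportions",
    "plot_state_map",
]

VERTEX_ORDER = ("Basal", "HER2", "Luminal")
_VERTICES_XY = {"Basal": (0.0, 0.0), "HER2": (1.0, 0.0), "Luminal": (0.5, np.sqrt(3) / 2)}


@dataclass
class SimplexPoint:
    """One sample's position on the cancer cell state map."""

    sample_id: str
    coords: tuple[float, float, float]  # (basal, her2, luminal), sums to 1
    vertex_class: str
    plot_xy: tuple[float, float]
    tie: bool = False

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.min() < 0 or abs(c.sum() - 1.0) > 1e-9:
            raise ValueError("coords must be nonnegative and sum to 1")


def filter_mappable_samples(
    P: np.ndarray,
    sample_ids: Sequence[str],
    epithelial_components: Sequence[int],
    cancer_components: Sequence[int],
    min_epithelial: float = 0.7,
    min_cancer: float = 0.1,
) -> list[str]:
    """Samples well modelled by the three cancer-epithelial profiles.

    Retains samples whose summed epithelial proportion is strictly
    greater than ``min_epithelial`` *and* whose summed Basal + HER2 +
    Luminal proportion is strictly greater than ``min_cancer``.
    """
    if len(cancer_components) != 3:
        raise ValueError("exactly three cancer-epithelial components (Basal, HER2, Luminal) required")
    P = np.asarray(P, dtype=float)
    epi = P[list(epithelial_components), :].sum(axis=0)
    cancer = P[list(cancer_components), :].sum(axis=0)
    keep = (epi > min_epithelial) & (cancer > min_cancer)
    return [s for s, k in zip(sample_ids, keep) if k]


def _xy(basal: float, her2: float, luminal: float) -> tuple[float, float]:
    return (her2 + 0.5 * luminal, (np.sqrt(3) / 2) * luminal)


def to_simplex_coordinates(
    P: np.ndarray,
    sample_ids: Sequence[str],
    cancer_components: tuple[int, int, int],
) -> list[SimplexPoint]:
    """Barycentric (Basal, HER2, Luminal) coordinates for mapped samples.

    The three raw proportions are divided by their sum; samples must
    already have passed :func:`filter_mappable_samples`, so the sum is
    strictly positive (asserted).
    """
    P = np.asarray(P, dtype=float)
    b_i, h_i, l_i = cancer_components
    trio = P[[b_i, h_i, l_i], :]
    total = trio.sum(axis=0)
    assert np.all(total > 0), "zero cancer trio: run filter_mappable_samples first"
    norm = trio / total[None, :]
    points = []
    for j, sid in enumerate(sample_ids):
        basal, her2, luminal = (float(v) for v in norm[:, j])
        label, tie = _argmax_vertex(basal, her2, luminal)
        points.append(
            SimplexPoint(sid, (basal, her2, luminal), label, _xy(basal, her2, luminal), tie)
        )
    return points


def _argmax_vertex(basal: float, her2: float, luminal: float) -> tuple[str, bool]:
    coords = np.array([basal, her2, luminal])
    top = np.flatnonzero(coords == coords.max())
    # ties resolve in fixed order Basal > HER2 > Luminal
    return VERTEX_ORDER[top[0]], len(top) > 1


def classify_by_vertex(point: SimplexPoint) -> str:
    """Nearest-vertex class of a simplex point (argmax coordinate)."""
    label, tie = _argmax_vertex(*point.coords)
    if tie:
        logger.info("sample %s: exact vertex tie, resolved to %s", point.sample_id, label)
    return label


def compare_classifications(
    labels_a: Mapping[str, str],
    labels_b: Mapping[str, str],
    label_order: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Cross-tabulate two labelings of the same samples.

    Returns the contingency table (rows = labels_a, columns = labels_b,
    both in fixed ``label_order`` with unseen labels appended
    alphabetically) and the simple agreement fraction.
    """
    if set(labels_a) != set(labels_b):
        raise ValueError("the two labelings cover different sample sets")
    samples = sorted(labels_a)
    a = [labels_a[s] for s in samples]
    b = [labels_b[s] for s in samples]
    order = list(label_order) if label_order else list(VERTEX_ORDER)
    for lab in sorted(set(a) | set(b)):
        if lab not in order:
            order.append(lab)
    table = pd.DataFrame(0, index=order, columns=order, dtype=int)
    for la, lb in zip(a, b):
        table.loc[la, lb] += 1
    agreement = float(np.mean([la == lb for la, lb in zip(a, b)]))
    return table, agreement


def correlate_proportions(
    P: np.ndarray, component_x: int, component_y: int
) -> tuple[float, float]:
    """Pearson correlation (with two-sided p) between two components' proportions.

    Used to relate microenvironment fractions (e.g. macrophages, CAFs)
    to cancer-epithelial fractions across a cohort.
    """
    P = np.asarray(P, dtype=float)
    if P.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    x, y = P[component_x, :], P[component_y, :]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a component; correlation undefined")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


def plot_state_map(points: Sequence[SimplexPoint], path: str, color_by: Mapping[str, float] | None = None):
    """Scatter the mapped samples inside the ternary triangle (cosmetic)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.6))
    tri = np.array([_VERTICES_XY[v] for v in VERTEX_ORDER] + [_VERTICES_XY["Basal"]])
    ax.plot(tri[:, 0], tri[:, 1], color="0.3", lw=1)
    xs = [p.plot_xy[0] for p in points]
    ys = [p.plot_xy[1] for p in points]
    if color_by is not None:
        c = [color_by.get(p.sample_id, np.nan) for p in points]
        sc = ax.scatter(xs, ys, c=c, s=12, cmap="viridis")
        fig.colorbar(sc, ax=ax)
    else:
        colors = {"Basal": "tab:red", "HER2": "tab:purple", "Luminal": "tab:blue"}
        ax.scatter(xs, ys, c=[colors[p.vertex_class] for p in points], s=12)
    for name, (x, y) in _VERTICES_XY.items():
        ax.annotate(name, (x, y), textcoords="offset points", xytext=(0, 5), ha="center")
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
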