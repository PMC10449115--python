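"""Stage 1: constrained matrix factorization of transformed bulk profiles.

Given a transformed bulk matrix T (informative genes x samples) and a
number of cell types k, Stage 1 seeks

    T  ~  M P,    0 <= M <= 1 (genes x k),   P >= 0, 1'P = 1 (k x samples),

by alternating exact constrained least-squares steps: all gene rows of
M are updated under box constraints, then all sample columns of P are
updated under the simplex constraint, both via quadratic programming.
Iteration stops when the residual sum of squares (RSS) changes by less
than ``rss_tol`` or after ``max_iter`` iterations.

The number of cell types is chosen by stability: for each candidate k,
the factorization is repeated on random 80% subsamples of the samples,
replicate proportion estimates are matched component-to-component by
optimal correlation assignment, and k is stable while every matched
correlation remains statistically significant.  The selected k is the
largest stable value before stability is first lost.

Estimated components are anonymous; identities are assigned post hoc by
correlating each estimated profile against class-mean reference
profiles over the informative genes.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import scipy.optimize
import scipy.stats

from ._qp import solve_box_batch, solve_simplex_batch
from .core_io import SampleAnnotation
from .stage0 import InformativeGeneSet, ReferenceSet
from .transform import TransformedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DeconvolutionResult",
    "StabilityReport",
    "CellTypeAssignment",
    "solve_proportions",
    "solve_profiles",
    "run_stage1",
    "match_components",
    "estimate_stability",
    "assign_cell_types",
    "label_epithelial_subtypes",
]


@dataclass
class DeconvolutionResult:
    """Factor pair from one Stage 1 run.

    ``M`` holds the estimated transformed profiles (genes x k, entries
    in [0, 1]); ``P`` the per-sample proportions (k x samples, simplex
    columns).  ``explained_variance`` is relative to the centered total
    sum of squares; the uncentered variant is reported alongside since
    the baseline convention differs between tools.
    """

    M: np.ndarray
    P: np.ndarray
    k: int
    gene_ids: list[str]
    sample_ids: list[str]
    rss_trajectory: np.ndarray
    iterations: int
    converged: bool
    explained_variance: float
    explained_variance_uncentered: float
    seed: int

    def __post_init__(self) -> None:
        if np.any(self.P < 0) or np.abs(self.P.sum(axis=0) - 1.0).max() > 1e-8:
            raise ValueError("proportion columns must lie on the simplex")
        if self.M.min() < 0 or self.M.max() > 1:
            raise ValueError("profile entries must lie in [0, 1]")
        if np.any(np.diff(self.rss_trajectory) > 1e-9 * max(1.0, self.rss_trajectory[0])):
            raise AssertionError("RSS trajectory must be non-increasing")

    @property
    def rss(self) -> float:
        return float(self.rss_trajectory[-1])


@dataclass
class StabilityRecord:
    k: int
    pair_correlations: list[float]
    pair_p_values: list[float]
    all_significant: bool
    mean_matched_correlation: float


@dataclass
class StabilityReport:
    records: list[StabilityRecord]
    chosen_k: int


@dataclass
class ComponentAssignment:
    component: int
    label: str
    correlation: float
    runner_up: float
    subtype: Optional[str] = None


@dataclass
class CellTypeAssignment:
    assignments: list[ComponentAssignment]

    def labels(self) -> list[str]:
        return [a.label for a in self.assignments]


def solve_proportions(M: np.ndarray, t_col: np.ndarray) -> np.ndarray:
    """Proportions of one sample: argmin ||t - M p||^2, p >= 0, sum(p) = 1."""
    M = np.asarray(M, dtype=float)
    if M.min() < 0 or M.max() > 1:
        raise ValueError("profile matrix entries must lie in [0, 1]")
    t = np.asarray(t_col, dtype=float).reshape(-1, 1)
    if t.shape[0] != M.shape[0]:
        raise ValueError("dimension mismatch between M and t")
    return solve_simplex_batch(M, t)[:, 0]


def solve_profiles(P: np.ndarray, t_row: np.ndarray) -> np.ndarray:
    """Transformed profile of one gene: argmin ||t - m'P||^2, 0 <= m <= 1."""
    P = np.asarray(P, dtype=float)
    if np.any(P < 0) or np.abs(P.sum(axis=0) - 1.0).max() > 1e-6:
        raise ValueError("proportion columns must lie on the simplex")
    t = np.asarray(t_row, dtype=float).reshape(1, -1)
    if t.shape[1] != P.shape[1]:
        raise ValueError("dimension mismatch between P and t")
    return solve_box_batch(P, t)[0, :]


def _initial_profiles(V: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Seed M with k distinct sample columns perturbed by uniform noise."""
    n = V.shape[1]
    cols = rng.choice(n, size=k, replace=False)
    M0 = V[:, cols] + rng.uniform(-0.05, 0.05, size=(V.shape[0], k))
    return np.clip(M0, 0.0, 1.0)


def run_stage1(
    T: TransformedMatrix | np.ndarray,
    k: int,
    max_iter: int = 2000,
    rss_tol: float = 1e-10,
    seed: int = 0,
    anchors: Optional[np.ndarray] = None,
) -> DeconvolutionResult:
    """Alternating constrained factorization of a transformed matrix.

    One iteration is a box-constrained profile step over all genes
    followed by a simplex-constrained proportion step over all samples;
    both are warm-started monotone QP solves, so the RSS trajectory is
    non-increasing.  Stops at |dRSS| < ``rss_tol`` or ``max_iter``.

    ``anchors`` optionally appends pure reference profile columns
    (genes x n_anchors, same gene order, transformed scale) to the
    sample set during factorization to stabilize the solution; anchor
    columns are excluded from the returned proportions and from all
    reported metrics.
    """
    if isinstance(T, TransformedMatrix):
        V = T.values
        gene_ids = list(T.gene_ids)
        sample_ids = list(T.sample_ids)
    else:
        V = np.asarray(T, dtype=float)
        gene_ids = [f"g{i}" for i in range(V.shape[0])]
        sample_ids = [f"s{j}" for j in range(V.shape[1])]
    n_real = V.shape[1]
    if anchors is not None:
        anchors = np.asarray(anchors, dtype=float)
        if anchors.shape[0] != V.shape[0]:
            raise ValueError("anchor profiles must share the gene axis of T")
        V = np.column_stack([V, anchors])
    if not np.all(np.isfinite(V)):
        raise ValueError("input matrix contains non-finite values")
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > V.shape[1]:
        raise ValueError(f"k={k} exceeds the number of samples ({V.shape[1]})")

    rng = np.random.default_rng(seed)
    M = _initial_profiles(V, k, rng)
    P = solve_simplex_batch(M, V)
    rss_prev = float(((V - M @ P) ** 2).sum())
    trajectory = [rss_prev]
    converged = False
    it = 0
    # inner solvers run a bounded number of warm-started monotone steps per
    # outer iteration; the outer RSS criterion governs overall convergence.
    # Once the trajectory plateaus, a polish phase re-checks the criterion
    # with fully converged inner solves so slack left by the caps does not
    # masquerade as convergence.
    polish_left: Optional[int] = None
    it = 0
    while True:
        it += 1
        cap_m, cap_p = (25, 60) if polish_left is None else (2000, 5000)
        M = solve_box_batch(P, V, M0=M, max_iter=cap_m, tol=1e-13)
        P = solve_simplex_batch(M, V, P0=P, max_iter=cap_p, tol=1e-13)
        rss = float(((V - M @ P) ** 2).sum())
        trajectory.append(rss)
        plateau = abs(rss_prev - rss) < rss_tol
        rss_prev = rss
        if polish_left is None:
            if plateau:
                polish_left = 50
            elif it >= max_iter:
                break
        else:
            if plateau:
                converged = True
                break
            polish_left -= 1
            if polish_left <= 0:
                break

    # metrics and outputs cover only the real samples, never the anchors
    V_real = V[:, :n_real]
    P_real = P[:, :n_real]
    rss = float(((V_real - M @ P_real) ** 2).sum())
    tss_centered = float(((V_real - V_real.mean(axis=1, keepdims=True)) ** 2).sum())
    tss_uncentered = float((V_real**2).sum())
    ev = 1.0 - rss / tss_centered if tss_centered > 0 else 0.0
    ev_u = 1.0 - rss / tss_uncentered if tss_uncentered > 0 else 0.0
    return DeconvolutionResult(
        M=np.clip(M, 0.0, 1.0),
        P=np.maximum(P_real, 0.0) / np.maximum(P_real, 0.0).sum(axis=0, keepdims=True),
        k=k,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        rss_trajectory=np.asarray(trajectory),
        iterations=it,
        converged=converged,
        explained_variance=ev,
        explained_variance_uncentered=ev_u,
        seed=seed,
    )


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def match_components(
    result_a: DeconvolutionResult,
    result_b: DeconvolutionResult,
    on: Literal["proportions", "profiles"] = "proportions",
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one matching of components between two runs.

    Builds the Pearson-correlation matrix between component proportion
    vectors over shared samples (or profile columns over shared genes)
    and solves the assignment maximizing total correlation.  Returns
    (permutation, correlations): component i of ``result_a`` matches
    component permutation[i] of ``result_b``.  Zero-variance components
    get correlation 0.
    """
    if result_a.k != result_b.k:
        raise ValueError("results have different numbers of components")
    if on == "proportions":
        shared = [s for s in result_a.sample_ids if s in set(result_b.sample_ids)]
        if not shared:
            raise ValueError("no shared samples to match on")
        ia = [result_a.sample_ids.index(s) for s in shared]
        ib = [result_b.sample_ids.index(s) for s in shared]
        A, B = result_a.P[:, ia], result_b.P[:, ib]
    else:
        shared = [g for g in result_a.gene_ids if g in set(result_b.gene_ids)]
        if not shared:
            raise ValueError("no shared genes to match on")
        ia = [result_a.gene_ids.index(g) for g in shared]
        ib = [result_b.gene_ids.index(g) for g in shared]
        A, B = result_a.M[ia, :].T, result_b.M[ib, :].T
    k = result_a.k
    corr = np.array([[_safe_corr(A[i], B[j]) for j in range(k)] for i in range(k)])
    rows, cols = scipy.optimize.linear_sum_assignment(-corr)
    perm = np.empty(k, dtype=int)
    perm[rows] = cols
    return perm, corr[rows, cols]


def _corr_p_value(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson correlation under the null (t test)."""
    if n < 3:
        return 1.0
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * scipy.stats.t.sf(abs(t), df=n - 2))


def estimate_stability(
    T: TransformedMatrix,
    k_range: Sequence[int],
    n_reps: int = 3,
    subsample_frac: float = 0.8,
    alpha: float = 0.05,
    seed: int = 0,
    max_iter: int = 2000,
    rss_tol: float = 1e-10,
) -> StabilityReport:
    """Choose the number of cell types by replicate-subsample stability.

    For each k, ``n_reps`` factorizations are run on independent random
    subsets of ceil(``subsample_frac`` * samples) samples (genes are
    never subsampled; both the subsample and the initialization are
    re-randomized per replicate).  Matched proportion correlations are
    computed between every replicate pair over their shared samples; k
    is stable when every matched correlation is significant at
    ``alpha``.  Scanning upward, the chosen k is the largest stable
    value before the first unstable one (the whole range if none is
    unstable); ties toward the richer model.
    """
    if n_reps < 2:
        raise ValueError("stability needs at least 2 replicates for pairwise comparison")
    ks = sorted(set(int(k) for k in k_range))
    n = T.n_samples
    n_sub = int(np.ceil(subsample_frac * n))
    if ks[0] < 2 or ks[-1] > n_sub:
        raise ValueError(f"k range must lie within [2, {n_sub}]")
    rng = np.random.default_rng(seed)
    records: list[StabilityRecord] = []
    stable_ks: list[int] = []
    for k in ks:
        results = []
        for _ in range(n_reps):
            cols = rng.choice(n, size=n_sub, replace=False)
            sub = TransformedMatrix(
                T.values[:, cols],
                list(T.gene_ids),
                [T.sample_ids[c] for c in cols],
                T.scale_a,
            )
            results.append(
                run_stage1(sub, k, max_iter=max_iter, rss_tol=rss_tol,
                           seed=int(rng.integers(2**31)))
            )
        corrs: list[float] = []
        pvals: list[float] = []
        for ra, rb in itertools.combinations(results, 2):
            shared = len(set(ra.sample_ids) & set(rb.sample_ids))
            _, cs = match_components(ra, rb, on="proportions")
            corrs.extend(cs.tolist())
            pvals.extend(_corr_p_value(c, shared) for c in cs)
        all_sig = all(p < alpha for p in pvals)
        records.append(
            StabilityRecord(
                k=k,
                pair_correlations=corrs,
                pair_p_values=pvals,
                all_significant=all_sig,
                mean_matched_correlation=float(np.mean(corrs)),
            )
        )
        logger.info("stability k=%d: all_significant=%s mean r=%.3f", k, all_sig,
                    records[-1].mean_matched_correlation)
        if all_sig:
            stable_ks.append(k)
        else:
            break
    if not stable_ks:
        raise ValueError(
            "no stable number of cell types in the scanned range; "
            "widen the range or provide more samples"
        )
    return StabilityReport(records=records, chosen_k=max(stable_ks))


def assign_cell_types(
    result: DeconvolutionResult,
    refs: ReferenceSet,
    genes: InformativeGeneSet,
) -> CellTypeAssignment:
    """Name each estimated component after its best-correlated reference class.

    Each column of M is correlated (Pearson) against the class-mean
    reference profile over the informative genes; the top class wins.
    Components whose best correlation is below 0.2 stay "unassigned".
    """
    gene_list = [g for g in genes.gene_ids if g in set(result.gene_ids) and g in set(refs.profiles.gene_ids)]
    if not gene_list:
        raise ValueError("no informative genes shared between result and references")
    ridx = [result.gene_ids.index(g) for g in gene_list]
    fidx = [refs.profiles.gene_ids.index(g) for g in gene_list]
    classes = refs.classes()
    class_means = {
        c: refs.profiles.values[np.ix_(fidx, [i for i, l in enumerate(refs.class_labels) if l == c])].mean(axis=1)
        for c in classes
    }
    assignments = []
    for comp in range(result.k):
        col = result.M[ridx, comp]
        corrs = {c: _safe_corr(col, class_means[c]) for c in classes}
        ranked = sorted(corrs.items(), key=lambda kv: -kv[1])
        best_class, best_r = ranked[0]
        runner = ranked[1][1] if len(ranked) > 1 else float("nan")
        label = best_class if best_r >= 0.2 else "unassigned"
        assignments.append(ComponentAssignment(comp, label, best_r, runner))
    return CellTypeAssignment(assignments)


def label_epithelial_subtypes(
    result: DeconvolutionResult,
    annotations: Sequence[SampleAnnotation],
    components: Optional[Sequence[int]] = None,
    control_labels: Sequence[str] = ("Normal", "Control"),
) -> dict[int, str]:
    """Label epithelial components by the subtype in which they dominate.

    Each component (all by default) is labeled with the annotated
    subtype whose samples carry its highest mean proportion; a
    component peaking in control/normal samples is labeled "Normal".
    Two components claiming the same subtype are both labeled and the
    tie is logged, never silently reassigned.
    """
    ann = {a.sample_id: a.subtype_label for a in annotations if a.subtype_label}
    subtypes = sorted(set(ann.values()))
    if not subtypes:
        raise ValueError("annotations carry no subtype labels")
    groups = {
        st: [i for i, s in enumerate(result.sample_ids) if ann.get(s) == st]
        for st in subtypes
    }
    groups = {st: idx for st, idx in groups.items() if idx}
    comps = list(components) if components is not None else list(range(result.k))
    labels: dict[int, str] = {}
    for comp in comps:
        means = {st: float(result.P[comp, idx].mean()) for st, idx in groups.items()}
        best = max(means, key=lambda s: means[s])
        labels[comp] = "Normal" if best in control_labels else best
    claimed: dict[str, list[int]] = {}
    for comp, lab in labels.items():
        claimed.setdefault(lab, []).append(comp)
    for lab, comps_ in claimed.items():
        if len(comps_) > 1:
            logger.warning("subtype %s claimed by components %s", lab, comps_)
    return labels
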