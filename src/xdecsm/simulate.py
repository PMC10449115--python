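"""Synthetic data emulating the in-silico mixture study and scRNA inputs.

The generator stands in for experimentally isolated reference profiles:
four cell types (cancer epithelial, normal epithelial, immune, stroma)
with replicate profiles, disjoint planted marker genes, and a shared
log-normal expression baseline.  Mixtures follow a four-class purity
design —

* high purity:   cancer fraction ~ Uniform(0.6, 0.9)
* impure:        cancer fraction = 0.40
* low purity:    cancer = 0.10, normal epithelial ~ Uniform(0.5, 0.8)
* control:       cancer = 0, normal epithelial = 0.70

— with the remaining mass split between stroma and immune by a
symmetric Dirichlet.  Per mixture one replicate per type is drawn at
random, perturbed by Gaussian noise whose variance is a fraction of the
type's maximum per-gene replicate variance (10% for cancer, 5% for the
normal types), and the mixture is the proportion-weighted linear
combination of the perturbed transformed profiles.

A companion generator produces labelled single-cell counts (multinomial
reads over class-specific expression programs, log-normal depths, and
deliberately under-sequenced cells) to exercise pseudo-bulk
construction end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.optimize

from .core_io import ExpressionMatrix
from .stage0 import ReferenceSet
from .transform import TransformedMatrix, transform_counts

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationTruth",
    "RecoveryReport",
    "TypeSpec",
    "DEFAULT_TYPES",
    "generate_reference_profiles",
    "add_profile_noise",
    "generate_mixtures",
    "generate_synthetic_scrna",
    "score_recovery",
]


@dataclass
class TypeSpec:
    name: str
    n_replicates: int
    n_markers: int = 25
    marker_fold: float = 8.0
    lineage: Optional[str] = None  # types sharing a lineage share an expression program
    replicate_log_sd: Optional[float] = None  # overrides the panel-wide default


# Replicate counts and within-type heterogeneity mirror a reference panel of
# sorted profiles: a cancer-epithelial panel of cell lines spanning several
# intrinsic subtypes (hence the largest replicate spread), normal epithelial
# lines, an immune panel pooling several lymphoid/myeloid lineages, and a
# small homogeneous set of cancer-associated fibroblasts.  The two epithelial
# types share a lineage program, so epithelial-vs-stroma contrasts select
# lineage genes rather than re-selecting type markers.
DEFAULT_TYPES = [
    TypeSpec("cancer_epithelial", 12, lineage="epithelial"),
    TypeSpec("normal_epithelial", 10, lineage="epithelial"),
    TypeSpec("immune", 10),
    TypeSpec("stroma", 4),
]
CANCER_TYPES = ("cancer_epithelial",)


@dataclass
class SimulationTruth:
    """Ground truth of one mixture simulation."""

    true_profiles: np.ndarray  # genes x types, transformed type means
    true_proportions: np.ndarray  # types x mixtures, simplex columns
    type_names: list[str]
    gene_ids: list[str]
    purity_class: list[str]
    seed: int

    def __post_init__(self) -> None:
        if np.abs(self.true_proportions.sum(axis=0) - 1.0).max() > 1e-9:
            raise ValueError("truth proportion columns must sum to 1")


@dataclass
class RecoveryReport:
    """Per-type recovery quality of a deconvolution against known truth."""

    type_names: list[str]
    proportion_r2: dict[str, float]
    profile_r2: dict[str, float]
    permutation: np.ndarray  # truth type i -> estimated component permutation[i]

    @property
    def min_proportion_r2(self) -> float:
        return min(self.proportion_r2.values())

    @property
    def min_profile_r2(self) -> float:
        return min(self.profile_r2.values())


def generate_reference_profiles(
    n_genes: int = 1000,
    type_spec: Sequence[TypeSpec] = tuple(DEFAULT_TYPES),
    seed: int = 0,
    baseline_log_mean: float = 4.0,
    baseline_log_sd: float = 1.0,
    type_effect_log_sd: float = 0.5,
    lineage_effect_log_sd: float = 0.8,
    replicate_log_sd: float = 0.15,
    marker_log_mean: float = 5.0,
    marker_log_sd: float = 0.5,
) -> tuple[ExpressionMatrix, list[str]]:
    """Reference expression panel with realistic cell-type structure.

    Expression is built multiplicatively on the log scale: a shared
    per-gene baseline, a genome-wide per-type effect
    (``type_effect_log_sd``, so types differ broadly, not only at
    markers), a lineage effect shared by types declaring the same
    ``lineage`` (``lineage_effect_log_sd``), and per-replicate noise
    (``replicate_log_sd``).  Each type's disjoint marker block is
    additionally multiplied by ``marker_fold``, with marker baselines
    drawn well-expressed (``marker_log_mean``) as true cell-type
    markers are.  Returns the raw count-scale matrix and one class
    label per profile column.
    """
    specs = list(type_spec)
    total_markers = sum(t.n_markers for t in specs)
    if n_genes < total_markers:
        raise ValueError("n_genes must accommodate all planted markers")
    for t in specs:
        if t.marker_fold <= 1:
            raise ValueError(f"marker_fold must exceed 1 (type {t.name})")
    rng = np.random.default_rng(seed)
    baseline = rng.lognormal(baseline_log_mean, baseline_log_sd, size=n_genes)
    baseline[:total_markers] = rng.lognormal(marker_log_mean, marker_log_sd, size=total_markers)
    gene_ids = [f"gene{g:05d}" for g in range(n_genes)]
    marker_slices = {}
    start = 0
    for t in specs:
        marker_slices[t.name] = slice(start, start + t.n_markers)
        start += t.n_markers

    lineages = {t.lineage for t in specs if t.lineage}
    lineage_effect = {
        lin: rng.lognormal(0.0, lineage_effect_log_sd, size=n_genes) for lin in sorted(lineages)
    }
    columns, labels, names = [], [], []
    for t in specs:
        type_mean = baseline * rng.lognormal(0.0, type_effect_log_sd, size=n_genes)
        if t.lineage:
            type_mean = type_mean * lineage_effect[t.lineage]
        type_mean[marker_slices[t.name]] *= t.marker_fold
        rep_sd = t.replicate_log_sd if t.replicate_log_sd is not None else replicate_log_sd
        for r in range(t.n_replicates):
            col = type_mean * rng.lognormal(0.0, rep_sd, size=n_genes)
            columns.append(col)
            labels.append(t.name)
            names.append(f"{t.name}_{r + 1}")
    X = ExpressionMatrix(np.column_stack(columns), gene_ids, names)
    return X, labels


def planted_markers(
    type_spec: Sequence[TypeSpec] = tuple(DEFAULT_TYPES), n_genes: int = 1000
) -> dict[str, list[str]]:
    """Gene ids of the markers planted by :func:`generate_reference_profiles`."""
    out = {}
    start = 0
    for t in type_spec:
        out[t.name] = [f"gene{g:05d}" for g in range(start, start + t.n_markers)]
        start += t.n_markers
    return out


def _type_noise_sd(values: np.ndarray, labels: Sequence[str], frac_by_type: dict[str, float]) -> dict[str, float]:
    sds = {}
    for cls, frac in frac_by_type.items():
        cols = [i for i, l in enumerate(labels) if l == cls]
        if len(cols) < 2:
            raise ValueError(f"type {cls} has a single replicate; noise variance undefined")
        gene_var = values[:, cols].var(axis=1, ddof=1)
        sds[cls] = float(np.sqrt(frac * gene_var.max()))
    return sds


def add_profile_noise(
    refs: ReferenceSet,
    cancer_types: Sequence[str] = CANCER_TYPES,
    cancer_noise_frac: float = 0.10,
    normal_noise_frac: float = 0.05,
    seed: int = 0,
) -> ReferenceSet:
    """Additive Gaussian noise scaled to each type's replicate variance.

    Noise variance is ``frac`` times the maximum per-gene variance
    among that type's replicate profiles — ``cancer_noise_frac`` for
    the cancer types and ``normal_noise_frac`` for everything else.
    Applied on the transformed scale and clipped back into [0, 1).
    """
    for frac in (cancer_noise_frac, normal_noise_frac):
        if not 0 < frac < 1:
            raise ValueError("noise fractions must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    V = refs.profiles.values
    frac_by_type = {
        cls: (cancer_noise_frac if cls in cancer_types else normal_noise_frac)
        for cls in refs.classes()
    }
    sds = _type_noise_sd(V, refs.class_labels, frac_by_type)
    noisy = V.copy()
    for j, cls in enumerate(refs.class_labels):
        noisy[:, j] = V[:, j] + rng.normal(0.0, sds[cls], size=V.shape[0])
    np.clip(noisy, 0.0, np.nextafter(1.0, 0.0), out=noisy)
    return ReferenceSet(
        TransformedMatrix(noisy, list(refs.profiles.gene_ids),
                          list(refs.profiles.sample_ids), refs.profiles.scale_a),
        list(refs.class_labels),
        provenance=refs.provenance,
    )


def generate_mixtures(
    refs: ReferenceSet,
    n: int = 100,
    class_mix: Optional[dict[str, int]] = None,
    cancer_type: str | Sequence[str] = "cancer_epithelial",
    normal_type: str = "normal_epithelial",
    cancer_noise_frac: float = 0.10,
    normal_noise_frac: float = 0.05,
    noise: bool = True,
    seed: int = 0,
) -> tuple[TransformedMatrix, SimulationTruth]:
    """Linear mixtures of transformed reference profiles in four purity classes.

    Per mixture: one replicate per cell type is drawn at random and
    perturbed with type-scaled Gaussian noise; the mixture column is
    the proportion-weighted combination of the perturbed profiles.
    ``class_mix`` gives per-purity-class mixture counts (default: n
    split evenly across high/impure/low/control).  When ``cancer_type``
    lists several classes (e.g. three cancer-epithelial subtypes), the
    purity-class cancer fraction is split among them by a symmetric
    Dirichlet draw.
    """
    classes = refs.classes()
    cancer_types = [cancer_type] if isinstance(cancer_type, str) else list(cancer_type)
    missing = [c for c in cancer_types + [normal_type] if c not in classes]
    if missing:
        raise ValueError(f"reference set lacks required types: {missing}")
    others = [c for c in classes if c not in cancer_types and c != normal_type]
    if class_mix is None:
        q, r = divmod(n, 4)
        counts = [q + (1 if i < r else 0) for i in range(4)]
        class_mix = dict(zip(("high", "impure", "low", "control"), counts))
    if sum(class_mix.values()) != n:
        raise ValueError("purity class counts must sum to n")
    rng = np.random.default_rng(seed)
    V = refs.profiles.values
    frac_by_type = {
        cls: (cancer_noise_frac if cls in cancer_types else normal_noise_frac)
        for cls in classes
    }
    sds = _type_noise_sd(V, refs.class_labels, frac_by_type) if noise else {c: 0.0 for c in classes}
    class_cols = {c: [i for i, l in enumerate(refs.class_labels) if l == c] for c in classes}

    def split_cancer(total: float) -> dict[str, float]:
        if len(cancer_types) == 1 or total == 0:
            return {c: (total if i == 0 else 0.0) for i, c in enumerate(cancer_types)}
        w = rng.dirichlet(np.ones(len(cancer_types)))
        return {c: total * wi for c, wi in zip(cancer_types, w)}

    proportions = np.zeros((len(classes), n))
    purity = []
    cols = []
    j = 0
    for purity_class, count in class_mix.items():
        for _ in range(count):
            p = {c: 0.0 for c in classes}
            if purity_class == "high":
                p.update(split_cancer(rng.uniform(0.6, 0.9)))
            elif purity_class == "impure":
                p.update(split_cancer(0.40))
            elif purity_class == "low":
                p.update(split_cancer(0.10))
                p[normal_type] = rng.uniform(0.5, 0.8)
            elif purity_class == "control":
                p[normal_type] = 0.70
            else:
                raise ValueError(f"unknown purity class {purity_class!r}")
            rest = 1.0 - sum(p.values())
            if rest < 0:
                raise ValueError(f"infeasible purity constraints in class {purity_class!r}")
            split = rng.dirichlet(np.ones(len(others))) * rest
            for c, s in zip(others, split):
                p[c] = s
            mix = np.zeros(V.shape[0])
            for i, c in enumerate(classes):
                pick = int(rng.choice(class_cols[c]))
                profile = V[:, pick]
                if noise and sds[c] > 0:
                    profile = np.clip(
                        profile + rng.normal(0.0, sds[c], size=V.shape[0]),
                        0.0, np.nextafter(1.0, 0.0),
                    )
                mix += p[c] * profile
                proportions[i, j] = p[c]
            cols.append(mix)
            purity.append(purity_class)
            j += 1

    mixtures = TransformedMatrix(
        np.clip(np.column_stack(cols), 0.0, np.nextafter(1.0, 0.0)),
        list(refs.profiles.gene_ids),
        [f"mix{m + 1:03d}" for m in range(n)],
        refs.profiles.scale_a,
    )
    true_profiles = np.column_stack([refs.class_mean(c) for c in classes])
    truth = SimulationTruth(
        true_profiles=true_profiles,
        true_proportions=proportions,
        type_names=list(classes),
        gene_ids=list(refs.profiles.gene_ids),
        purity_class=purity,
        seed=seed,
    )
    return mixtures, truth


def simulated_reference_set(
    n_genes: int = 1000,
    type_spec: Sequence[TypeSpec] = tuple(DEFAULT_TYPES),
    seed: int = 0,
    **kwargs,
) -> ReferenceSet:
    """Generate the raw panel and wrap it as a transformed reference set."""
    X, labels = generate_reference_profiles(n_genes, type_spec, seed, **kwargs)
    return ReferenceSet(transform_counts(X), labels, provenance="bulk reference")


def generate_synthetic_scrna(
    n_genes: int = 300,
    class_cells: Optional[dict[str, int]] = None,
    n_markers: int = 20,
    marker_fold: float = 8.0,
    mean_depth: float = 300_000,
    depth_log_sd: float = 0.25,
    n_low_coverage: int = 3,
    low_coverage_depth: float = 50_000,
    seed: int = 0,
) -> tuple[ExpressionMatrix, list[str]]:
    """Labelled single-cell counts with planted markers and shallow cells.

    Each cell's reads are multinomial over its class's expression
    program (shared log-normal baseline, ``marker_fold``-amplified
    marker block per class); depths are log-normal around
    ``mean_depth``, except ``n_low_coverage`` cells per class drawn at
    ~``low_coverage_depth`` to exercise the coverage filter.
    """
    if class_cells is None:
        class_cells = {"epithelial": 40, "stromal": 20, "T cell": 15, "macrophage": 15}
    if n_genes < n_markers * len(class_cells):
        raise ValueError("n_genes must accommodate all class marker blocks")
    rng = np.random.default_rng(seed)
    baseline = rng.lognormal(2.0, 1.0, size=n_genes)
    programs = {}
    for i, cls in enumerate(class_cells):
        prog = baseline.copy()
        prog[i * n_markers : (i + 1) * n_markers] *= marker_fold
        programs[cls] = prog / prog.sum()
    cols, labels, names = [], [], []
    for cls, n_cells in class_cells.items():
        for c in range(n_cells):
            if c < n_low_coverage:
                depth = int(low_coverage_depth * rng.uniform(0.5, 0.9))
            else:
                depth = int(mean_depth * rng.lognormal(0.0, depth_log_sd))
                depth = max(depth, 110_000)  # keep intended survivors above the floor
            cols.append(rng.multinomial(depth, programs[cls]).astype(float))
            labels.append(cls)
            names.append(f"{cls.replace(' ', '_')}_c{c + 1}")
    X = ExpressionMatrix(
        np.column_stack(cols), [f"gene{g:05d}" for g in range(n_genes)], names
    )
    return X, labels


def run_simulation_study(
    seed: int = 0,
    n: int = 100,
    n_genes: int = 1000,
    k: int = 4,
    anchors_per_type: int = 4,
    max_iter: int = 2000,
    rss_tol: float = 1e-10,
) -> tuple[RecoveryReport, "object"]:
    """The full in-silico mixture study: generate, select, factorize, score.

    Reference panel and 100 four-purity-class mixtures from the
    generator; informative genes by the four-class contrast recipe
    (one-vs-rest p < 1e-4, top 25 up/down, plus cancer-vs-stroma and
    normal-vs-stroma pairwise contrasts); the factorization run with
    k = 4 and, mirroring the study design, ``anchors_per_type`` pure
    non-cancer reference profiles appended as stabilizing anchor
    columns.  Returns the recovery report and the factorization result.
    """
    from .stage0 import select_informative_genes
    from .stage1 import run_stage1

    refs = simulated_reference_set(n_genes=n_genes, seed=seed)
    genes = select_informative_genes(refs, preset="simulated")
    mixtures, truth = generate_mixtures(refs, n=n, seed=seed + 1)
    T = mixtures.subset_genes(genes.gene_ids)
    anchors = None
    if anchors_per_type:
        cols = []
        for cls in ("normal_epithelial", "immune", "stroma"):
            cols.extend(refs.class_columns(cls)[:anchors_per_type].tolist())
        ref_inf = refs.profiles.subset_genes(genes.gene_ids)
        anchors = ref_inf.values[:, cols]
    result = run_stage1(T, k, max_iter=max_iter, rss_tol=rss_tol, seed=seed + 2,
                        anchors=anchors)
    report = score_recovery(result, truth, informative_genes=genes.gene_ids)
    return report, result


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def score_recovery(
    result,
    truth: SimulationTruth,
    informative_genes: Optional[Sequence[str]] = None,
) -> RecoveryReport:
    """Match estimated components to truth and report per-type R-squared.

    Components are paired to true types by the assignment maximizing
    total proportion correlation; each pair's proportion R^2 is the
    squared Pearson correlation of estimated vs true per-sample
    proportions, and profile R^2 the squared correlation of the
    estimated transformed profile vs the true type-mean profile over
    ``informative_genes`` (default: all genes of the result).
    """
    if result.k != truth.true_proportions.shape[0]:
        raise ValueError("component count differs between result and truth")
    k = result.k
    corr = np.array(
        [
            [
                np.corrcoef(truth.true_proportions[i], result.P[j])[0, 1]
                if truth.true_proportions[i].std() > 0 and result.P[j].std() > 0
                else 0.0
                for j in range(k)
            ]
            for i in range(k)
        ]
    )
    rows, cols = scipy.optimize.linear_sum_assignment(-corr)
    perm = np.empty(k, dtype=int)
    perm[rows] = cols

    genes = list(informative_genes) if informative_genes is not None else list(result.gene_ids)
    g_res = [result.gene_ids.index(g) for g in genes]
    g_tru = [truth.gene_ids.index(g) for g in genes]
    prop_r2, prof_r2 = {}, {}
    for i, name in enumerate(truth.type_names):
        j = perm[i]
        prop_r2[name] = _r2(truth.true_proportions[i], result.P[j])
        prof_r2[name] = _r2(truth.true_profiles[g_tru, i], result.M[g_res, j])
    return RecoveryReport(list(truth.type_names), prop_r2, prof_r2, perm)
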