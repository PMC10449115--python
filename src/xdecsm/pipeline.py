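"""End-to-end orchestration with a config file and a reproducibility manifest.

A run executes simulate -> stage0 -> transform -> stage1 -> stage2 ->
map (-> response, when enabled) and writes every intermediate to the
output directory plus a JSON manifest recording the seed, a hash of
the effective configuration, and the SHA-256 of each output file, so a
rerun with the same config and seed is verifiably identical.

The config is TOML with one section per stage; unknown sections or
keys are rejected before any computation, as is an out-of-range k.
In simulated mode (the default) the built-in generator provides the
reference panel and mixtures; file mode instead reads a bulk counts
matrix plus a reference matrix with class labels.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import simulate as sim
from .core_io import ExpressionMatrix, read_expression_matrix, write_expression_matrix
from .simplex_map import filter_mappable_samples, to_simplex_coordinates
from .stage0 import ReferenceSet, select_informative_genes
from .stage1 import assign_cell_types, estimate_stability, run_stage1
from .stage2 import run_stage2
from .transform import TransformedMatrix, inverse_transform, transform_counts

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

# three cancer-epithelial subtypes so the downstream simplex map is exercised
PIPELINE_TYPES = [
    sim.TypeSpec("epithelial_basal", 6),
    sim.TypeSpec("epithelial_her2", 6),
    sim.TypeSpec("epithelial_luminal", 6),
    sim.TypeSpec("normal_epithelial", 8),
    sim.TypeSpec("immune", 8),
    sim.TypeSpec("stroma", 4),
]
PIPELINE_CANCER_TYPES = ["epithelial_basal", "epithelial_her2", "epithelial_luminal"]


@dataclass
class RunConfig:
    """Validated parameters of one pipeline run."""

    seed: int = 0
    outdir: str = "xdecsm_run"
    # simulate
    simulate: bool = True
    n_mixtures: int = 100
    n_genes: int = 1000
    # file inputs (used when simulate is False)
    bulk_path: Optional[str] = None
    reference_path: Optional[str] = None
    reference_labels_path: Optional[str] = None
    # stage0
    p_threshold: float = 1e-4
    n_top: int = 25
    literature_path: Optional[str] = None
    # transform
    quantile_normalize: bool = False
    # stage1
    k: Optional[int] = 6
    scan: Optional[tuple[int, int]] = None
    n_reps: int = 3
    subsample_frac: float = 0.8
    alpha: float = 0.05
    max_iter: int = 2000
    rss_tol: float = 1e-10
    # map
    min_epithelial: float = 0.7
    min_cancer: float = 0.1
    # response
    response: bool = False
    response_path: Optional[str] = None

    def validate(self) -> None:
        if self.k is None and self.scan is None:
            raise ValueError("either a fixed k or a scan range is required")
        if self.scan is not None:
            lo, hi = self.scan
            if not (2 <= lo <= hi):
                raise ValueError(f"invalid scan range {self.scan}")
            if self.k is not None and not (lo <= self.k <= hi):
                raise ValueError(f"k={self.k} lies outside the scan range {self.scan}")
        elif self.k is not None and self.k < 2:
            raise ValueError("k must be at least 2")
        if not 0 < self.subsample_frac <= 1:
            raise ValueError("subsample_frac must lie in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.n_top < 1 or self.max_iter < 1 or self.n_reps < 2:
            raise ValueError("n_top >= 1, max_iter >= 1 and n_reps >= 2 are required")
        if not self.simulate and (self.bulk_path is None or self.reference_path is None):
            raise ValueError("file mode requires bulk_path and reference_path")


_SECTION_FIELDS = {
    "run": {"seed": "seed", "outdir": "outdir"},
    "simulate": {"enabled": "simulate", "n_mixtures": "n_mixtures", "n_genes": "n_genes"},
    "inputs": {
        "bulk": "bulk_path",
        "reference": "reference_path",
        "reference_labels": "reference_labels_path",
    },
    "stage0": {
        "p_threshold": "p_threshold",
        "n_top": "n_top",
        "literature": "literature_path",
    },
    "transform": {"quantile_normalize": "quantile_normalize"},
    "stage1": {
        "k": "k",
        "scan": "scan",
        "n_reps": "n_reps",
        "subsample_frac": "subsample_frac",
        "alpha": "alpha",
        "max_iter": "max_iter",
        "rss_tol": "rss_tol",
    },
    "map": {"min_epithelial": "min_epithelial", "min_cancer": "min_cancer"},
    "response": {"enabled": "response", "labels": "response_path"},
}


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Parse a TOML config with one ``[section]`` per stage; reject unknowns."""
    raw = tomllib.loads(Path(path).read_text())
    kwargs: dict = {}
    for section, entries in raw.items():
        if section not in _SECTION_FIELDS:
            raise ValueError(f"unknown config section [{section}]")
        if not isinstance(entries, dict):
            raise ValueError(f"top-level keys must live in a section ([{section}])")
        for key, value in entries.items():
            if key not in _SECTION_FIELDS[section]:
                raise ValueError(f"unknown key {key!r} in section [{section}]")
            kwargs[_SECTION_FIELDS[section][key]] = value
    kwargs.update(overrides)
    if isinstance(kwargs.get("scan"), list):
        kwargs["scan"] = tuple(kwargs["scan"])
    config = RunConfig(**kwargs)
    config.validate()
    return config


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def _write_tsv(df, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": [],
        "outputs": {},
    }
    stage_files: list[Path] = []

    def finish_stage(name: str, **meta) -> None:
        for f in stage_files:
            manifest["outputs"][f.name] = _sha256(f)
        stage_files.clear()
        manifest["stages"].append({"name": name, **meta})

    current_stage = "setup"
    try:
        import pandas as pd

        # --- simulate ---------------------------------------------------
        current_stage = "simulate"
        if config.simulate:
            refs = sim.simulated_reference_set(
                n_genes=config.n_genes, type_spec=PIPELINE_TYPES, seed=config.seed
            )
            mixtures, truth = sim.generate_mixtures(
                refs,
                n=config.n_mixtures,
                cancer_type=PIPELINE_CANCER_TYPES,
                seed=config.seed + 1,
            )
            raw_bulk = inverse_transform(mixtures)
            f = outdir / "mixtures.tsv"
            _write_tsv(mixtures.to_frame(), f)
            stage_files.append(f)
            f = outdir / "truth_proportions.tsv"
            _write_tsv(
                pd.DataFrame(truth.true_proportions, index=truth.type_names,
                             columns=mixtures.sample_ids), f,
            )
            stage_files.append(f)
            finish_stage("simulate", n_mixtures=config.n_mixtures, n_genes=config.n_genes)
        else:
            from .core_io import read_gene_list

            raw_bulk = read_expression_matrix(config.bulk_path)
            ref_raw = read_expression_matrix(config.reference_path)
            labels = [
                line.strip()
                for line in Path(config.reference_labels_path).read_text().splitlines()
                if line.strip()
            ]
            refs = ReferenceSet(transform_counts(ref_raw), labels)
            truth = None
            finish_stage("simulate", skipped=True)

        # --- stage0 ------------------------------------------------------
        current_stage = "stage0"
        literature = None
        if config.literature_path:
            from .core_io import read_gene_list

            literature = read_gene_list(config.literature_path)
        genes = select_informative_genes(
            refs,
            p_threshold=config.p_threshold,
            n_top=config.n_top,
            pairwise=[("normal_epithelial", "stroma", config.p_threshold, config.n_top)]
            if "normal_epithelial" in refs.classes() and "stroma" in refs.classes()
            else None,
            literature_genes=literature,
        )
        f = outdir / "informative_genes.txt"
        f.write_text("\n".join(genes.gene_ids) + "\n")
        stage_files.append(f)
        finish_stage("stage0", n_genes=genes.n_total)

        # --- transform ----------------------------------------------------
        current_stage = "transform"
        if config.simulate:
            transformed = mixtures  # generator already mixes on the 0-1 scale
        else:
            bulk = raw_bulk
            if config.quantile_normalize:
                from .core_io import quantile_normalize as qn

                bulk = qn(bulk)
                raw_bulk = bulk  # stage 2 uses normalized, untransformed counts
            transformed = transform_counts(bulk)
        f = outdir / "transform_meta.json"
        scale = transformed.scale_a
        f.write_text(json.dumps({"scale_a": float(np.atleast_1d(scale)[0])}))
        stage_files.append(f)
        finish_stage("transform", scale_a=float(np.atleast_1d(scale)[0]))

        # --- stage1 -------------------------------------------------------
        current_stage = "stage1"
        usable = [g for g in genes.gene_ids if g in set(transformed.gene_ids)]
        T_inf = transformed.subset_genes(usable)
        chosen_k = config.k
        if config.scan is not None:
            report = estimate_stability(
                T_inf,
                range(config.scan[0], config.scan[1] + 1),
                n_reps=config.n_reps,
                subsample_frac=config.subsample_frac,
                alpha=config.alpha,
                seed=config.seed,
                max_iter=config.max_iter,
                rss_tol=config.rss_tol,
            )
            chosen_k = report.chosen_k
            f = outdir / "stability.tsv"
            _write_tsv(
                pd.DataFrame(
                    [
                        {
                            "k": r.k,
                            "all_significant": r.all_significant,
                            "mean_matched_correlation": r.mean_matched_correlation,
                        }
                        for r in report.records
                    ]
                ).set_index("k"),
                f,
            )
            stage_files.append(f)
        result = run_stage1(
            T_inf, chosen_k, max_iter=config.max_iter, rss_tol=config.rss_tol,
            seed=config.seed,
        )
        assignment = assign_cell_types(result, refs, genes)
        comp_labels = assignment.labels()
        f = outdir / "P.tsv"
        _write_tsv(pd.DataFrame(result.P, index=comp_labels, columns=result.sample_ids), f)
        stage_files.append(f)
        f = outdir / "M.tsv"
        _write_tsv(pd.DataFrame(result.M, index=result.gene_ids, columns=comp_labels), f)
        stage_files.append(f)
        finish_stage(
            "stage1",
            k=chosen_k,
            iterations=result.iterations,
            rss=result.rss,
            explained_variance=result.explained_variance,
            explained_variance_uncentered=result.explained_variance_uncentered,
            component_labels=comp_labels,
        )

        # --- stage2 -------------------------------------------------------
        current_stage = "stage2"
        bulk_inf = raw_bulk.subset_genes(usable)
        profiles = run_stage2(bulk_inf, result.P, component_labels=comp_labels)
        f = outdir / "stage2_profiles.tsv"
        _write_tsv(
            pd.DataFrame(profiles.values, index=profiles.gene_ids,
                         columns=profiles.component_labels), f,
        )
        stage_files.append(f)
        finish_stage("stage2", group=profiles.group_id)

        # --- map ----------------------------------------------------------
        current_stage = "map"
        epithelial = [
            i for i, lab in enumerate(comp_labels)
            if "epithelial" in lab.lower() and lab != "unassigned"
        ]
        cancer = []
        for want in PIPELINE_CANCER_TYPES:
            hits = [i for i, lab in enumerate(comp_labels) if lab == want]
            cancer.extend(hits[:1])
        if len(cancer) == 3:
            mappable = filter_mappable_samples(
                result.P, result.sample_ids, epithelial, cancer,
                min_epithelial=config.min_epithelial, min_cancer=config.min_cancer,
            )
            idx = [result.sample_ids.index(s) for s in mappable]
            points = to_simplex_coordinates(
                result.P[:, idx], mappable, tuple(cancer)
            )
            df = pd.DataFrame(
                {
                    "sample_id": [p.sample_id for p in points],
                    "basal": [p.coords[0] for p in points],
                    "her2": [p.coords[1] for p in points],
                    "luminal": [p.coords[2] for p in points],
                    "x": [p.plot_xy[0] for p in points],
                    "y": [p.plot_xy[1] for p in points],
                    "class": [p.vertex_class for p in points],
                    "tie_flag": [p.tie for p in points],
                }
            ).set_index("sample_id")
            f = outdir / "state_map.tsv"
            _write_tsv(df, f)
            stage_files.append(f)
            finish_stage("map", n_mapped=len(points))
        else:
            finish_stage("map", skipped=True,
                         reason="three cancer-epithelial components not identified")

        # --- response (optional) -------------------------------------------
        if config.response:
            current_stage = "response"
            from .core_io import read_sample_annotations
            from .response import fit_response_glm, predict_response, roc_auc

            ann = read_sample_annotations(config.response_path)
            resp = {a.sample_id: a.response for a in ann if a.response is not None}
            common = [s for s in result.sample_ids if s in resp]
            P3 = result.P[np.ix_(cancer, [result.sample_ids.index(s) for s in common])].T
            y = np.array([resp[s] for s in common])
            model = fit_response_glm(P3, y)
            auc = roc_auc(predict_response(model, P3), y)
            f = outdir / "response_model.json"
            f.write_text(
                json.dumps(
                    {
                        "intercept": model.intercept,
                        "coefficients": model.coefficients.tolist(),
                        "n": model.n,
                        "separable": model.separable,
                        "training_auc": auc,
                    }
                )
            )
            stage_files.append(f)
            finish_stage("response", n=model.n, training_auc=auc)
    except Exception as err:
        for f in stage_files:
            if f.exists():
                f.rename(f.with_suffix(f.suffix + ".partial"))
        raise RuntimeError(f"[{current_stage}] {err}") from err

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
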