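# xdecsm

Reference-optional deconvolution of bulk RNA-seq into constituent
cell-type expression profiles and per-sample proportions, with a
breast-cancer **cell state map** built from the result.

Bulk tumor expression profiles mix signals from cancer cells, normal
epithelium, stroma and immune infiltrate in unknown per-sample
proportions. Reference-*based* deconvolution methods force the answer
through profiles of previously isolated cell populations and so cannot
discover recurrent cell states that are missing from the references.
`xdecsm` instead uses references only to pick an informative gene set, and
then factorizes the bulk matrix directly:

    T ≈ M·P      with  0 ≤ M ≤ 1,   P ≥ 0,  1ᵀP = 1,

where `T` is the bulk matrix on a bounded 0–1 scale (`y = 1 − e^{−ax}`,
`a = 1/max{x}`), `M` holds the transformed expression profiles of `k` cell
types and each column of `P` is a sample's composition on the probability
simplex. The factorization alternates exact constrained least-squares
steps (quadratic programs), `k` is chosen by subsample stability, and a
non-negative least-squares pass then recovers each cell type's expression
on the original count scale. Tumors dominated by epithelial signal are
projected onto the 2-simplex spanned by the Basal, HER2 and Luminal
cancer-epithelial proportions — a ternary map on which samples are
classified by nearest vertex, microenvironment associations are read off
as correlations, and therapy response is modelled by a logistic GLM on the
three coordinates.

The package includes a first-class synthetic-data module that reproduces
the method's validation study (a reference panel with planted markers and
realistic type/lineage structure, plus 100 mixtures in four purity
classes), so the entire pipeline is testable without any downloads.

## Worked example

The built-in study generates a four-type reference panel (cancer
epithelial, normal epithelial, immune, stroma), selects informative genes
by the contrast recipe, mixes 100 synthetic tumors in four purity classes
with type-scaled noise, factorizes them at `k = 4`, and scores recovery
against the known truth:

```python
from xdecsm.simulate import run_simulation_study

report, result = run_simulation_study(seed=1)
print({t: round(r, 3) for t, r in report.proportion_r2.items()})
print({t: round(r, 3) for t, r in report.profile_r2.items()})
print(round(result.explained_variance, 3), result.iterations)
```

prints

```
{'cancer_epithelial': 0.995, 'normal_epithelial': 0.993, 'immune': 0.969, 'stroma': 0.958}
{'cancer_epithelial': 0.987, 'normal_epithelial': 0.994, 'immune': 0.985, 'stroma': 0.991}
0.808 926
```

Reading this: per-sample proportions of all four cell types are recovered
with R² ≥ 0.96 except stroma (the four-replicate class) at ≈ 0.96; the
estimated transformed expression profiles correlate with the true
type-mean profiles at R² ≥ 0.98; and the four-component model explains
80.8% of the (centered) variance of the mixtures over the informative
genes after 926 alternating iterations — the rest is the injected
profile noise.

The same flow is available from the shell, stage by stage:

```
xdecsm simulate --n 100 --seed 7 --out sim/
xdecsm stage0 --refs refs.tsv --labels labels.txt --p 1e-4 --top 25 \
              --pairwise cancer_epithelial:stroma --out genes.txt
xdecsm transform --in counts.tsv --out transformed.tsv
xdecsm stage1 --in transformed.tsv --genes genes.txt --scan 3:8 --seed 17 --out dec/
xdecsm stage2 --counts counts.tsv --proportions dec/P.tsv --out profiles/
xdecsm map --proportions dec/P.tsv --basal Basal --her2 HER2 --luminal Luminal \
           --out map.tsv --plot map.png
xdecsm pipeline --config run.toml        # all of the above from one config
```

`stage1 --scan` performs the stability selection (3 replicates of 80% of
samples per candidate `k`; the scan stops at the first `k` whose matched
replicate correlations lose significance). All commands accept `--seed`,
and the pipeline writes a manifest with output hashes so a rerun with the
same config and seed is verifiably identical.

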