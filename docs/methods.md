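# Methods

`xdecsm` estimates the cell-type composition of bulk RNA-seq samples and the
expression profiles of the constituent cell types, without using reference
profiles as part of the solution. References (sorted bulk profiles or
labelled single cells) enter only to choose *which* genes the factorization
is performed over, so recurrent cell states that are absent from the
references can still be discovered. This note records the model, the
numerical choices, and what the built-in synthetic study does and does not
demonstrate.

## Model

### The 0–1 transform

Expression counts `x` are mapped into the unit interval by the
single-parameter negative exponential

    y = 1 − exp(−a·x),   a = 1 / max{x},

with one scalar `a` fit per matrix (the global maximum; per-gene scaling is
available as a non-default option for experimentation). Zeros map to 0 and
the observed maximum maps to 1 − 1/e ≈ 0.632; the image of the fitted
transform on data is therefore `[0, 1 − 1/e]`, not the full unit interval,
and we deliberately do not rescale further. The transform factors out
absolute transcript abundance and emphasizes on/off transcriptional state;
it is strictly monotone (implemented with `expm1` so that very small counts
remain distinct) and has the analytic inverse `x = −ln(1 − y)/a`, which the
package uses to move between scales. When two matrices must be compared
(references vs. bulks) each is transformed with its own fitted scale by
default; a caller can pass a fixed `scale_a` to share one.

### Stage 0 — references and informative genes

Single-cell references are collapsed to pseudo-bulks per cell type: cells
with total counts below 100,000 are dropped, survivors are ranked by depth
and summed in consecutive groups of five, every pseudo-bulk is rescaled to
the depth of the deepest one, and the set is 0–1 transformed. Incomplete
trailing groups are discarded, and a type must yield at least two
pseudo-bulks to be kept (downstream t-tests need within-class replication).

Informative genes are selected from the transformed reference profiles by
one-vs-rest two-sample t-tests per cell-type class, optionally augmented by
direct pairwise contrasts (e.g. epithelial vs. stroma). Within each
contrast, genes passing the p-value gate are ranked and the top `n_top`
up- and down-regulated genes are kept. Two choices here deserve comment
because the generic description "t-test, most up/downregulated" leaves them
open, and both turned out to matter:

* **Pooled-variance (Student) t-tests, not Welch.** Reference classes can
  be as small as four profiles. With Welch's statistic, the degrees of
  freedom for such a class collapse to ~3 and a gate like p < 1e-4 is
  essentially unreachable no matter how clean the separation, silencing the
  class entirely. The pooled form keeps the stated thresholds meaningful
  for small classes; for balanced contrasts the two coincide.
* **Ranking by t-statistic, not by raw mean difference.** For the *down*
  direction of a one-vs-rest contrast, the genes with the most negative
  mean difference are precisely the markers of *other* classes (high in
  exactly one other class). Ranking by mean difference therefore fills
  every down list with foreign markers, and the multiple-appearance
  exclusion rule (below) then deletes the markers the stage exists to find
  — in early experiments this destroyed 80% of planted markers. The
  t-statistic divides by the rest-group spread, so the down lists instead
  favour genes consistently low in the class, which is what should
  represent it.

A gene appearing in more than one contrast's list is **excluded entirely**
(not deduplicated): it cannot serve as an unambiguous signature of a single
cell type. A literature gene list (e.g. PAM50) can be unioned afterwards;
literature genes are intersected with the matrix case-sensitively, are
exempt from the exclusion rule, and a warning is logged when less than 90%
of the requested list is found. Ties in ranking break by absolute mean
difference and then gene id, so selection is deterministic. Named presets
bundle the three recipes used in practice (four-class bulk panel,
seven-class cell-line panel with a deeper epithelial/stroma contrast,
four-class pseudo-bulk panel).

### Stage 1 — constrained factorization

Given the transformed bulk matrix `T` (informative genes × samples) and a
number of cell types `k`, Stage 1 solves

    T ≈ M·P,   0 ≤ M ≤ 1 (genes × k),   P ≥ 0, 1ᵀP = 1 (k × samples),

by alternating exact constrained least squares: all gene rows of `M` under
box constraints, then all sample columns of `P` under the simplex
constraint. Both subproblems are small convex QPs sharing one Gram matrix
per step, solved by monotone first-order methods vectorized over the batch:

* profile step: cyclic coordinate descent on `[0, 1]` (each coordinate
  update is an exact 1-D minimum);
* proportion step: projected gradient with fixed step `1/L` (`L` the
  largest eigenvalue of `MᵀM`) and exact Euclidean projection onto the
  probability simplex.

Both methods descend from any warm start, so the residual sum of squares
(RSS) is non-increasing across outer iterations by construction — the test
suite asserts this on every run. Near-singular Gram matrices receive a
ridge of 1e-10 with a warning. Per outer iteration the inner solvers run a
bounded number of warm-started sweeps; once the outer RSS change falls
below `rss_tol` (default 1e-10, with `max_iter` 2000) a polish phase
re-checks the stopping criterion with fully converged inner solves, so
slack left by the inner caps cannot masquerade as convergence. One caveat
worth knowing: the absolute `|ΔRSS| < 1e-10` rule stops the *exact*
alternating map as well once its per-iteration progress falls below the
threshold, so on noiseless problems the factors are recovered to
correlation ~0.999+ rather than to machine precision.

`M` is initialized by sampling `k` distinct sample columns of `T` and
perturbing with uniform noise of amplitude 0.05 (clipped to `[0, 1]`),
seeded; data-plausible starts converge much faster than uniform random
ones. An optional `anchors` argument appends pure reference profile columns
to the sample set during factorization — this pins weakly represented
components to real cell-type profiles and noticeably stabilizes small
classes — and anchor columns are excluded from all reported outputs and
metrics. Explained variance is reported against both the centered and the
uncentered total sum of squares, since the baseline convention differs
between tools.

The number of cell types is chosen by subsample stability: for each
candidate `k`, three factorizations on independent random 80% subsamples of
the samples (genes are never subsampled; both the subsample and the
initialization are re-randomized), components matched between every
replicate pair by the assignment maximizing total Pearson correlation of
proportions over shared samples, and `k` counted stable while every matched
correlation is significant at α = 0.05 (two-sided test on the correlation).
Scanning upward, the chosen `k` is the largest stable value before
stability is first lost; ties go to the richer model, and the mean matched
correlation is reported per `k` so users can override. Note that
*structureless* data do not generally destabilize small `k`: per-sample
proportion estimates are near-deterministic functions of each sample's own
values, so replicate runs correlate even on pure noise; instability arises
when components become interchangeable. The degenerate error path (no
stable `k`) is exercised with a constant matrix.

Estimated components are anonymous. Identities are assigned post hoc by
correlating each column of `M` against class-mean reference profiles over
the informative genes (best class wins; best correlation below 0.2 leaves
the component "unassigned"), and epithelial components can further be
labelled by the annotated subtype (e.g. PAM50 class) in which their mean
proportion is highest, with components peaking in control samples labelled
"Normal". Tied claims are reported, never silently reassigned.

### Stage 2 — untransformed profiles

With Stage 1 proportions fixed, the untransformed expression of each
component is recovered per gene by non-negative least squares against the
raw (or quantile-normalized but untransformed) counts. The result is the
average expression of that cell type over the sample set used, so Stage 2
is typically run per cohort subgroup — e.g. samples grouped by their
dominant epithelial component, with component proportions optionally
aggregated into super-classes (epithelial / stromal / immune) whose sums
still total 1 per sample. Components whose mean proportion in a subgroup is
below 0.01 are unidentifiable there and reported as NaN columns, not as
zeros, so absence of information never masquerades as biology.

### The cancer cell state map

Samples whose composition is well explained by epithelial components
(summed epithelial proportion strictly > 0.7) and that carry an appreciable
cancer fraction (summed Basal + HER2 + Luminal proportion strictly > 0.1)
are projected onto the 2-simplex spanned by the three cancer-epithelial
components: the three proportions divided by their sum are the barycentric
coordinates. The nearest vertex (argmax coordinate; exact ties resolve
Basal > HER2 > Luminal and are flagged) gives a data-driven subtype call,
which can be cross-tabulated against any other labelling. For rendering,
Basal is the lower-left vertex (0, 0), HER2 lower-right (1, 0), Luminal top
(1/2, √3/2) — a unit-side equilateral triangle; the convention is recorded
here and in output metadata so plots are comparable. Microenvironment
associations are plain Pearson correlations between component proportions
across samples.

### Therapy response

A binomial GLM with logit link (IRLS via statsmodels) models binary
response from the three cancer-subtype proportions, with RECIST labels
binarized either as CR-vs-else or CR/PR-vs-else. Perfect and quasi-perfect
separation is detected (statsmodels' separation warning, exploding
coefficients, or saturated fitted probabilities) and flagged; a lightly
ridge-penalized refit (α = 1e-3) keeps predictions usable. Evaluation uses
the rank (Mann–Whitney) AUC with midranks for ties, which equals the
probability that a random responder outscores a random non-responder plus
half the tie probability; the test suite checks it against exhaustive pair
enumeration, including tied scores. Cross-cohort transfer (fit on one
cohort, score another) is an explicit call, never hidden logic; matching
drug classes between cohorts is the caller's responsibility.

## The synthetic study

The `simulate` module generates the study the pipeline is validated on,
standing in for a panel of experimentally isolated reference profiles.

**Reference panel.** Four cell types with 12/10/10/4 replicate profiles
(cancer epithelial, normal epithelial, immune, stroma). Expression is
multiplicative on the log scale: a per-gene log-normal baseline (log-mean
4, log-sd 1), a genome-wide per-type effect (log-sd 0.5) so types differ
broadly rather than only at markers, a lineage effect (log-sd 0.8) shared
by the two epithelial types, and per-replicate noise (log-sd 0.15, giving
within-type profile correlations of 0.97–0.99 on the transformed scale —
the range sorted replicate profiles show). Each type carries a disjoint
block of 25 planted markers, multiplied 8-fold in that type and drawn
well-expressed (log-mean 5), as true cell-type markers are. The lineage
layer is what makes the pairwise epithelial-vs-stroma contrasts select
shared epithelial-program genes instead of re-selecting type markers; with
it, the four-class recipe yields ≈200–230 informative genes.

**Mixtures.** 100 mixtures in four purity classes (25 each by default):
high purity (cancer fraction ~ Uniform(0.6, 0.9)), impure (0.40), low
purity (0.10, with normal epithelial ~ Uniform(0.5, 0.8)), control (0
cancer, 0.70 normal epithelial). The remaining mass is split between
stroma and immune by a symmetric Dirichlet(1, 1). Per mixture, one
replicate per type is drawn at random and perturbed with additive Gaussian
noise whose variance is 10% (cancer) or 5% (normal types) of that type's
maximum per-gene replicate variance — "maximum variance" is read as the
max over genes of the within-type replicate variance, with the alternative
readable off the code in one line. Noise is applied on the transformed
scale (profiles are transformed before mixing) and clipped back into
[0, 1); the mixture is the proportion-weighted linear combination of the
perturbed profiles, so the linear mixing model holds exactly on the
transformed scale. Upper bounds for the "greater than" purity classes
(0.9, 0.8) keep all four types present.

**Scoring.** Estimated components are matched to truth by the optimal
assignment on proportion correlations; per matched pair the report carries
the squared Pearson correlation of estimated vs. true per-sample
proportions, and of the estimated transformed profile vs. the true
type-mean profile over the informative genes.

**What passing shows, and does not.** The full study
(`simulate.run_simulation_study`: generator → gene selection →
factorization at k = 4 with 4 + 4 + 4 non-cancer anchor profiles, the
anchoring being part of the study design) recovers per-type proportions
with R² ≈ 0.95–0.99 and profiles with R² ≈ 0.97–0.99 across seeds; the
minimum is always stroma, the four-replicate class, and it straddles 0.96
(observed 0.945–0.963). Because mixtures are *linear* on the transformed
scale by construction, the study validates the estimator under its own
model; real bulk data mix on the count scale, carry library-size and
platform effects, and contain cell types outside the reference panel, none
of which the generator emulates. A separate companion generator produces
labelled single-cell counts (multinomial reads over class expression
programs, log-normal depths, deliberately under-sequenced cells) to
exercise pseudo-bulk construction end to end.

## Problem sizes and defaults

The shipped validation uses 1,000 genes, 36 reference profiles, 100
mixtures, and k = 4 for the recovery study; stability selection is
validated on 400-gene panels, 60 samples, scanning k = 3..8 over 10
seeded repetitions. These sizes were chosen so the whole suite documents
the method's behaviour in minutes while keeping every class comfortably
replicated. All generators and the factorization are deterministic given
their seed.

## Known limitations

* The factorization is a non-convex alternating scheme; different seeds
  can reach different local optima on weakly separated data. The stability
  scan and the anchor option are the practical mitigations.
* The absolute RSS stopping rule makes the attainable accuracy depend on
  problem scale (see above); `rss_tol` is exposed for callers who need a
  tighter tail.
* Stability selection indexes model reproducibility, not truth; on data
  whose extra structure is itself reproducible (e.g. batch effects), it
  will favour larger k.
* Stage 2 assumes proportions estimated on the transformed scale transfer
  to the count scale; that approximation is part of the method, not of this
  implementation.
* The response module fits three predictors and an intercept; cohorts of
  PDX scale (tens of models) support at most that, and separation is
  common — hence the flag plus ridge fallback rather than an error.
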