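# Methods

## Input model and conventions

All coordinates are 0-based half-open (BED convention); ABC-style
prediction tables are BED-derived and read as-is. "Overlap" always means
at least one shared base. The ABC score is used purely as a presence
filter — rows are kept when the score is **strictly greater** than the
threshold (default 0.015) — and plays no further role. Enhancer peaks
from all cell types are merged with distance-0 semantics (book-ended
intervals fuse, matching the default of the standard merging tools), and
every original peak is replaced by the unique merged peak containing it,
so the same physical enhancer carries one id across cell types.
Promoters are the regions within ±1 kb of any annotated TSS, symmetric
regardless of strand; peaks overlapping a promoter window by ≥ 1 bp are
removed from the enhancer set. Selection of which cell types enter the
analysis is an explicit allow-list input, not a heuristic.

## Scores

For gene *g* over M cell types with N unified enhancers, the binary
matrix x has column sums m_j (cell types using enhancer j) and row sums
n_i (enhancers used in cell type i):

* per-enhancer specificity `SPE_j = (M − m_j + 1)/M ∈ [1/M, 1]`;
* per-cell selectivity `SEL_i = n_i/N ∈ [0, 1]`, defined over **all** M
  cell types, zeros included — this is what drives the SEL score of
  narrowly regulated genes up;
* `spe_score = mean_j SPE_j`; `sel_score = sd(SEL)/mean(SEL)`.

The standard deviation defaults to the **sample** convention (ddof = 1),
the usual reading of "relative standard deviation"; a population switch
(`sd="population"`) is provided since either convention is defensible.
Under the sample convention `sel_score ∈ [0, √M]`, the upper bound
attained when all interactions fall in a single cell type. Genes with a
single enhancer are excluded before scoring (selectivity of a one-element
set is not meaningful) and reported separately. The exact identity
`spe_score + mean(SEL) = (M+1)/M` (both sides count T = Σm_j = Σn_i)
is asserted to 1e-12 in the tests as a cross-check of both formulas.

## Pattern classification

K-means (k = 3 by default, 25 restarts, fixed seed) runs on z-scored
(spe_score, sel_score) pairs; standardization is on by default because the
SEL score's range grows with √M and would otherwise dominate the
Euclidean metric, and can be switched off. Cluster → name mapping is
deterministic from the centroids on the original scale: the lowest-SPE
centroid is **Con**; of the remaining two, the higher-SEL centroid is
**Spe** and the lower **Var**. Exact centroid ties break on the other
coordinate, then on cluster index, with a warning. The mapping is
invariant to cluster-index permutation.

## Shared enhancers and Var subtypes

An enhancer is Shared for a gene when m_j > M/2 **strictly** — at even M,
exactly M/2 does not qualify. Var genes failing the expression filter are
excluded: a gene fails when absent from the expression table or when its
maximum TPM over all cell types is ≤ 1 (threshold and strictness are
parameters, since "≤ 1 TPM" and "< 1" conventions both circulate).
Remaining Var genes are Var I if they have ≥ 1 Shared enhancer, else
Var II. Expression tables can be quantile-normalized column-wise
(sorted-column means; ties receive the exact mean of their rank range).
Quantile normalization is idempotent on tie-free data; with cross-column
ties the second pass can shift values slightly, an inherent property of
the tie rule rather than an implementation artifact.

## Enrichment statistics

Enhancers are length-unified to 500 bp around the floor midpoint
(`[c − 250, c + 250)`, clipped at 0 without re-expansion) before SNP
counting. Controls are fixed-length regions placed uniformly over the
genome excluding a supplied set (typically promoters); placement is
uniform over valid start positions, chromosomes are not matched, and
regions may overlap one another (sampling with replacement of positions).
The enrichment is

```
fold = (hits_obs / total_obs) / (hits_ctrl / total_ctrl)
```

with hits counted as "region contains ≥ 1 SNP position" (half-open
containment), and the p-value is the exact one-sided upper-tail binomial
probability of ≥ hits_obs successes in total_obs trials at success rate
hits_ctrl/total_ctrl (a two-sided alternative is a flag). When no control
region contains a SNP the fold is reported as NaN with a warning rather
than silently smoothed.

Because the binomial test treats the control rate as known, its
calibration depends on how precisely that rate is estimated: with a
control set the same size as the enhancer set the one-sided type-I error
at nominal 0.05 is inflated to roughly 0.12 (the test statistic's true
variance is ~2× the nominal one), while a control set ~10× larger
restores near-nominal behavior (measured 0.06 over 200 null replicates).
The default control count equals the enhancer count for balanced fold
reporting; for inference we recommend, and the calibration tests use,
10× controls.

Per-interval conservation signal is the mean over **covered** bases only:
bases without a signal record are excluded from numerator and
denominator, and a fully uncovered interval yields NaN, not 0. E-P
distance is |enhancer floor-midpoint − TSS|, defined only within a
chromosome. Super-enhancer overlap shares are per-cell-type per-pattern
counts of SE-overlapping enhancers scaled to 100%; a cell type with zero
overlapping enhancers in every pattern is flagged rather than divided by
zero.

## Synthetic data

The generator plants the four gene classes by construction (rather than
resampling empirical score distributions), so downstream recovery can be
checked against exact truth:

* **Con** — every enhancer active in each cell with probability
  `p_active` (default 0.9);
* **Spe** — a fixed random set of `spe_cell_count` cells (default 3 of
  M = 20, constrained to < M/4 to keep the class geometrically distinct);
  enhancers active only there;
* **Var II** — each enhancer active in 1–3 private cells, so enhancers
  rarely co-occur while their union spans many cells;
* **Var I** — Var II plus one enhancer active in
  `ceil(shared_cell_fraction · M)` cells (default fraction 0.6 > 0.5, so
  it is Shared by construction).

Every presence bit is then flipped with `noise_rate` (default 0.02).
Defaults: 50 genes per class, 8–15 enhancers per gene, a 2 × 10 Mb toy
genome with one gene per 100 kb block (TSS at block + 1 kb, enhancers
from block + 4 kb in 1.2 kb steps, widths 200–800 bp, so peaks never
enter promoter windows or overlap across genes). Expression is log-normal
with class-coupled parameters — Con/Var II exp(N(ln 50, 0.3)) per cell,
Var I exp(N(ln 10, 0.8)) (lower, more variable), Spe nonzero only in its
active cells, exp(N(ln 20, 0.5)) — chosen as typical TPM magnitudes for
stably expressed vs. variable vs. cell-restricted genes. SNP tracks place
Poisson background SNPs genome-wide (`background_rate` per bp) and boost
the rate by `odds_shared` inside planted Shared enhancers. Generation is
a pure function of the spec and its seed.

With noise 0 and `p_active` 1 the planted classes hit closed forms (Con:
sel_score 0, spe_score 1/M; Spe with k active cells: sel_score
√(M(M−k)/(k(M−1)))), which the tests assert exactly.

What the generator does *not* emulate: correlated peak boundaries across
cell types (every cell type sees identical enhancer coordinates, so
coordinate unification is exercised on separate randomized fixtures),
ABC-score magnitudes, linkage between SNP density and sequence context,
chromosome-scale heterogeneity, and realistic gene/enhancer density.
Passing recovery tests therefore demonstrates correctness of the scoring,
clustering and counting machinery under the planted model, not classifier
performance on real epigenomes.

## Problem sizes and numerics

The test-suite and acceptance script run at desk scale: 200-gene
datasets, M = 20 cell types, 1,000-matrix formula sweeps (M ≤ 100,
N ≤ 200), 10,000-matrix Shared-detection sweeps and 200-replicate null
calibrations, sizes at which every brute-force oracle is still exact and
the whole suite completes in seconds. K-means uses 25 restarts with a
fixed seed; all simulation randomness flows through
`numpy.random.default_rng` seeds. Floating-point assertions use 1e-12
for algebraic identities and the printed precision for hand-derived
examples.

## Known limitations

* The cluster-naming rule assumes the three planted geometries are
  present; on degenerate score clouds (e.g. all genes conserved) k-means
  still returns three clusters and the names describe relative, not
  absolute, geometry.
* Quantile-normalization idempotence is exact only without cross-column
  ties (see above).
* Control regions may overlap each other; for very dense exclusion sets
  the effective genome can shrink enough that "uniform over valid starts"
  differs from "uniform over the genome".
* The binomial enrichment p-value conditions on the control rate; see
  the calibration note above for the control-set size this implies.
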