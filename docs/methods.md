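# Methods

This note documents the models and procedures implemented in
`spatannot`, the parameters that matter, the numerical choices, and what
the synthetic benchmarks do and do not demonstrate.

## Normalization

The annotation pipeline operates on `X = unit_normalize(ln(E + 1))`,
where `E` is the raw cells × proteins intensity matrix. The pseudo-count
(default 1, configurable) keeps the log finite at zero intensity; the
natural log compresses the heavy right tail of antibody-channel
intensities. Unit (l2) row normalization projects every cell onto the
unit sphere so that the Euclidean distances used by the clustering stage
are monotone in cosine distance — the angle between proteomic profiles,
which is more informative than magnitude for segmentation-derived
intensities whose scale varies with cell size. The order is enforced:
applying unit normalization to anything but the log-transformed matrix
raises, and all-zero cells (segmentation artifacts) are left as zero
vectors rather than NaN so a run never dies on them; they fall to the
Unknown class downstream.

A separate TF-IDF-style transform serves visualization and benchmarking:
each protein is min–max scaled between its 0.01th and 99.99th
percentiles (clipped to [0, 1]; the percentile bounds make single
outlier pixels irrelevant), then weighted by `ln(p_total / p_sum)`, the
log inverse of the protein's share of total scaled abundance. Proteins
expressed everywhere — sticky, non-specific antibodies — get weights near
zero; a constant column scales to zero with a warning rather than
dividing by zero. When annotations are available `p_sum` aggregates
per-cell-type means so abundant types do not dominate the weighting;
otherwise it sums over cells. Both logs are natural; base only rescales
all weights by a constant and affects no ordering.

## Marker gating and constrained clustering

The marker score multiplies positive-marker intensities with complements
(column max minus value) of negative-marker intensities, so one saturated
negative marker vetoes a cell entirely and an empty negative set leaves
the positive product unchanged. Scores are nonnegative on the unit
sphere.

Gate parameters, all percentiles of the per-type score distribution:

| parameter | default | meaning |
|---|---|---|
| `q_high` | 95 (scalar or per type) | lower gate; representatives score strictly above it |
| `q_max` | 100 | upper gate against assay artifacts; at exactly 100 the maximum is admitted |
| `q_low` | 50 | per-type low-score sets whose intersection seeds Unknown |
| `max_iter` | 100 | K-means iteration cap (change-free early stop) |

`q_high` should reflect expected abundance: for a type expected at
proportion *p*, a gate near `100·(1 − p/2)` targets the top half of the
expected positive population. `pipeline.adaptive_q_high` implements this
rule clipped to [95, 99.9]. Too relaxed a gate admits non-representative
cells (fatal for rare types, whose gate percentile must exceed
`100·(1 − p)`); too strict a gate risks seeding from artifacts.
Percentiles use linear interpolation (numpy default, type 7) and the
inequalities are strict on both sides; both choices are recorded here
because they change which cells pass at small n. Representative sets are
claimed in decreasing order of estimated abundance — the total mean
positive-marker intensity per type — with exact ties broken by
marker-file order, and a cell claimed by an earlier type is removed from
later candidate pools, so the sets are disjoint by construction even
when markers overlap.

The constrained K-means pins every representative to its seeded cluster
at every iteration; free cells go to the nearest centroid (squared
Euclidean, ties to the lowest cluster index — determinism matters for
model reproducibility, and the module contains no randomness at all).
Centroids are recomputed as member means; an emptied cluster keeps its
previous centroid with a warning. When the Unknown intersection is empty
the pipeline drops the Unknown cluster with a warning instead of
seeding it from nothing.

Known limitation: with strongly overlapping types the few pinned
representatives cannot anchor a rare type's centroid against the pull of
an abundant neighbor, and the rare cluster can drift into the abundant
type's cloud over iterations (each iteration absorbs a few more boundary
cells, moving the centroid further). The iteration cap and early stop do
not prevent this — it is a property of Lloyd updates under heavy class
imbalance — so poorly separated panels should be gated more strictly and
inspected, not trusted blindly.

## Classifier

The extreme learning machine draws `W_in` (proteins × hidden) and `b_in`
from standard normals once, seeded, and never updates them; the hidden
layer is `H = φ(X W_in + b_in)` with φ the logistic sigmoid by default
(tanh and relu are available; any bounded/Lipschitz scalar function
works). The output layer is the minimum-norm least-squares solution
`W_out = H† Y` against one-hot labels, with the pseudo-inverse computed
by SVD at a relative singular-value cutoff of 1e-12 — collinear channels
therefore do not destabilize training. Hidden width defaults to
`min(1024, 8P)` for a P-protein panel, enough capacity for tens of
channels while keeping the SVD cheap; widths above the training count
merely trigger an underdetermined-system warning since the pseudo-inverse
is still defined. Prediction is the argmax over the K+1 outputs with
Unknown competing as an ordinary class; an optional score threshold can
relabel low-confidence winners as Unknown but the default is pure
argmax. Splits are always at ROI granularity (cells of one imaged region
never straddle the boundary), default 50/50, optionally stratified by
disease status; a single-ROI stratum goes to training with a warning.

## Mark cross-correlation estimation

For a pattern of n points with categorical marks in a rectangular window
W, the estimator at distance r is the kernel-weighted fraction of
ordered pairs at distance ≈ r carrying marks (a, b), divided by the
independence expectation `p_a · p_b` (the product of marginal mark
fractions):

    k̂(r) = Σ_{i≠j} κ_h(d_ij − r) w_ij 1(m_i=a) 1(m_j=b)
            / ( p_a p_b Σ_{i≠j} κ_h(d_ij − r) w_ij )

with κ the Epanechnikov kernel, bandwidth h = 0.15/√λ by default
(Stoyan's rule of thumb, λ = n/|W|), and w the translation edge
correction `|W| / ((width−|dx|)(height−|dy|))`, which compensates pairs
whose separation vector pushes one end outside the window. The default
r grid is 512 points from h to a quarter of the shorter window side.
All of kernel, bandwidth, correction and grid are configurable and
recorded in the output; published summaries from other estimators are
not bit-reproducible without matching these choices. Bins without
contributing pairs are NaN, and the per-bin contributing-pair count is
reported so downstream consumers can ignore thinly supported bins.
Identities used as tests: a single-mark pattern gives k ≡ 1 exactly;
random relabeling gives mean k → n/(n−1) ≈ 1; the estimator is symmetric
in (a, b); and it agrees with a brute-force double loop to 1e-9.

Pair distances are computed densely (O(n²) memory), which is practical
to a few tens of thousands of points per ROI — typical for IMC fields —
but not beyond. The permutation helper reuses the pair geometry across
permutations, making 500 mark permutations of a 1,000-point pattern a
half-minute computation.

Curve summaries: `argmax_r` (ties to the smallest r; decreases with
tighter aggregation) and `ln(max k / argmax_r)` (increases with it).
Cohort comparison runs Kruskal–Wallis over per-ROI summaries followed by
pairwise two-sided Mann–Whitney U tests; cohorts with fewer than two
ROIs are excluded with a warning and an all-identical input reports
statistic 0, p = 1 rather than erroring on degenerate ties. The
HistoCAT-style baseline counts, among type-a cells, the fraction whose
three nearest neighbors include a type-b cell; it is one number per ROI
with no distance resolution, which is exactly the contrast the
distance-resolved curve is designed to provide.

## Evaluation utilities

Silhouette homogeneity is computed on random subsamples (silhouette is
O(n²)) with per-label means aggregated across sets; a label absent from
a subsample contributes NaN for that set. Composition concordance uses
`min(KL(p‖q), KL(q‖p))` in nats after ε = 1e-6 smoothing and
renormalization (KL is undefined on empty categories otherwise), with
discordance declared above 0.4 nats; the minimum construction makes the
decision symmetric. The natural-log base is a convention the 0.4
threshold inherits. Differential-expression cluster naming scores each
(cluster, protein) by `−log10(p) · log2FC` — Mann–Whitney U p-value of
cluster-vs-rest and fold change of pseudo-count-1 means (p is floored at
the smallest positive double to keep the product finite) — and assigns
the first cell type, in marker-file order, whose positive markers
contain the cluster's top protein, else Unknown.

## Synthetic data

The generator emulates an IMC cell table: per-(type, protein) ln-scale
means with multiplicative lognormal noise (intensities are continuous,
nonnegative, right-skewed), positive markers uplifted by 4.0 ln units
(~55× linear — the contrast of a clean, specific antibody), negative
markers depressed by 1.0, two sticky channels (+2.0 everywhere)
emulating non-specific antibodies, and pure-background channels.
Cell-to-cell ln-scale noise is 0.7 (≈ 80% CV). The default panel has 8
types at proportions 0.30/0.20/0.20/0.12/0.10/0.05/0.025/0.005 over 14
proteins in 10 ROIs of 5,000 cells in a 1,000 × 1,000 window, with a
0.5%-abundance rare type carrying a unique marker. Spatial placement per
type is uniform, Thomas-style cluster (Poisson parents, Gaussian
offspring, clipped to the window) or infiltrate (points seeded at the
positions of an already-placed target type plus Gaussian offsets).
Everything derives from one seed.

What passing on these data shows — and does not. The generator's types
are conditionally independent lognormals with clean markers: no spillover
between channels, no segmentation doublets mixing neighboring cells'
signals, no spatial intensity gradients, no batch effects across ROIs,
and marker uplifts large enough that types are genuinely separable.
Near-perfect recovery here demonstrates that the pipeline's machinery is
correct and unbiased, not that real IMC panels — where antibody
specificity varies widely — will reach the same accuracy. The estimator
calibration and oracle-agreement results, by contrast, are
distribution-free and carry over directly.

One fixture-design note: the infiltration/exclusion spatial benchmark
needs a background type filling the tissue. If *every* cell type lives
in the same clusters, marks are exchangeable at all distances and
k ≡ 1 regardless of infiltration — the short-range enrichment of
(islet, T-cell) pairs only exists relative to a spatially unstructured
matrix, as in real tissue.

## Problem sizes used in the checks

The self-contained checks run the full pipeline on the default 50,000
cell dataset, the permutation calibration on a 1,000-point pattern × 500
permutations, brute-force estimator comparisons at n ≤ 200, and the
spatial discrimination benchmark on 20 simulated ROIs of 900 cells;
these sizes exercise every code path at desk scale while the library
itself handles per-ROI patterns and cohorts one to two orders of
magnitude larger.
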