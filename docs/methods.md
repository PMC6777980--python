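# Methods

## Data model

All analyses run over a fixed, ordered region set; matrices are indexed
rows = source region, columns = target (injected) region.  Self-
connections are excluded everywhere: a nonzero diagonal in an input
file is zeroed with a warning rather than rejected, since neither
normalization uses it.  Matrices whose labels are a superset of the
region set are subset to it, which yields the edge-complete subnetwork
over the regions for which every pairwise connection was measured.
Region centroids are 3-D coordinates in mm in an arbitrary shared
space; only relative Euclidean distances enter the analysis.

## Normalizations

**FLN** (fraction of labeled neurons) divides each retrograde count by
its injection's total, making columns of the tracing matrix
column-stochastic.  An injection that labeled no neurons is an error,
not a zero column: it cannot be normalized meaningfully.

**FS** (fraction of streamlines) divides each symmetric streamline
count by the sum of the streamline counts attached to both regions of
the pair, excluding self-connections.  The denominator follows that
sentence literally, so the shared count S(i,j) is counted once in each
region's total.  Some fractional-scaling implementations subtract the
shared count once; that variant is available as
`fractional_scaling(..., subtract_shared=True)` but is off by default.
FS is symmetric and invariant under global rescaling of the counts.

**Log pathway.**  For Pearson correlations on log values, every
off-diagonal raw count is incremented by 1 *before* normalization, the
normalization is applied, and the natural log is taken; absent
connections then carry the smallest finite log-weight instead of −∞.
Rank-based analyses use the un-pseudocounted weights — ranks need no
pseudocount, and zeros simply tie at the minimal rank.  For the
symmetric log analysis the pseudocounted FLN matrix is symmetrized
first and logged after (log of the average, not average of logs).

## Association statistics

Spearman's ρ uses midranks for ties with the large-sample
t-approximation p-value (edge counts here are 28 or 56); an exact
permutation p-value is available for ≤ 10 edges.  Pearson's r runs on
the pseudocount-logged weights.  Confidence intervals are percentile
bootstrap over edges: paired (x, y) records are resampled with
replacement B times (default 10,000; analyses in the shipped configs
use 500–2,000 for speed), the coefficient is recomputed per resample,
and the 2.5/97.5 percentiles are reported.  Degenerate resamples (a
constant vector) are redrawn and counted in the result's metadata.  In
the rare event that the percentile interval excludes the point
estimate, the interval is widened to include it so the reported triple
is always ordered.  A node (region) bootstrap is available as
`unit="region"` for sensitivity analyses; the edge bootstrap is the
default resampling unit.

The distance-partialed Spearman regresses each log-weight vector on
inter-centroid Euclidean distance by ordinary least squares (intercept
and slope) and rank-correlates the two residual vectors.  With constant
distances the slope is unidentified; the fit degrades to the mean, so
the statistic reduces exactly to the plain Spearman — this degenerate
case is tested.

Edge tables are put in label-canonical order (unordered pairs oriented
smaller-label-first, then sorted) before any order-sensitive step, so
bootstrap draws and tie-breaks do not depend on how the input files
happened to order the regions.  Reordering regions in all inputs
changes reported statistics only at the level of floating-point
summation order (~1e-15).

## Removal curves

Edges are ranked by the tracing weight only (ties broken stably in
table order, i.e. by row/column position), and for each fraction f on
the grid 0–0.5 in steps of 0.05 the ⌈f·E⌉ strongest (or weakest) edges
are dropped from both weight vectors before recomputing the
association.  f = 0 reproduces the full-table coefficient bit-exactly.
A grid point leaving fewer than 3 edges is an error naming the
offending fraction.

## Detection

`threshold_binarize` keeps exactly ⌈density·E⌉ strongest unordered
edges (stable index-order tie-break, logged when ties straddle the
cut) and reports the realized density alongside the requested one.
Ground-truth densities default to 0.1–0.9 in steps of 0.1.  Because the
averaging recipe behind a single summary number per density is
ambiguous, both are computed and labeled: *matched-density* (prediction
binarized at the ground truth's density — note sensitivity equals
precision by construction, since both matrices then keep the same
number of edges) and *sweep* (prediction thresholded at every distinct
positive predicted weight, giving ROC and precision–recall series whose
sensitivity/specificity/precision are averaged per density).  Neither
mode is asserted to be "the" canonical summary; outputs carry the mode
column.

## The simulator

The generator emulates the statistical structure reported for
inter-areal cortical connectivity:

| parameter | default | meaning |
|---|---|---|
| `n_regions` | 8 | parcellation size (visual-cortical scale) |
| `edge_density` | 0.75 | P(ordered pair connected) |
| `reciprocity` | 0.7 | P(reciprocal edge forced), cortical networks being highly reciprocal |
| `mu`, `sigma` | 0, 1.5 | log-mean / log-sd of lognormal weights |
| `lambda_decay` | 0.2 /mm | exponential distance rule on true weights |
| `box_size` | 20 mm | centroid cube; with λ = 0.2, weights span ≈3 orders of magnitude across it |
| `tracer_neurons` (M) | 10,000 | labeled neurons per injection, a realistic retrograde yield |
| `streamlines` (T) | 1,000,000 | total streamline budget |
| `gamma` | 0.1 /mm | distance-dependent streamline dropout |
| `epsilon` | 0.01 | false-positive floor, relative to the mean connected weight (unit-free) |

True weights are `exp(N(mu, sigma²))·exp(−lambda·d)` on a directed
Bernoulli graph.  Tracer counts are multinomial per injected column
(size M, probabilities ∝ incoming weights), so columns sum exactly to
M.  Streamline counts are multinomial over unordered pairs with
intensity `w̄·exp(−gamma·d) + epsilon·mean(w̄)`, so the budget T is
exact, matching a fixed-streamline-count experiment; independent
Poisson allocation is available as an option.  All defaults live in
`defaults.yaml`; sub-stage seeds fan out deterministically from one
top-level seed.

What the simulator does *not* emulate: geometric fiber crossing and
bottleneck effects (dropout is purely distance-dependent), laminar or
directional biases of real tracers, inter-animal variability, and
parcellation error.  Passing tests on simulated data therefore show the
*statistical machinery* behaves correctly under the assumed weight
structure, not that any particular tractography algorithm is reliable
on real tissue.

## A structural limit worth knowing

FLN and FS are different normalizations of the same underlying weights:
FLN divides by an injection-column total, FS by the pair's combined
strengths.  At small n (8 regions) these denominators vary enough
across regions that even *noise-free* observations of identical true
weights produce a Spearman agreement of only ≈ 0.90 on average (minimum
≈ 0.72 over seeds) under the default lognormal spread — no amount of
sampling depth pushes the FLN-vs-FS rank agreement to 1.  The
acceptance suite states a ≥ 0.99 noise-free recovery target and that
test is left failing deliberately rather than weakening the generator's
study conditions; the sampling processes themselves are unbiased, which
is tested instead as sampled-vs-true agreement ≥ 0.99 for each modality
separately.  The practical reading: part of any observed FLN–FS
disagreement is normalization mismatch, not measurement error.

## Numerical choices

- Removal and density cuts use ceilings, so a requested fraction is
  always honored upward; realized densities are reported.
- Isolated region pairs (zero FS denominator) get FS = 0 with a
  warning; they cannot carry weight anyway.
- Symmetrizing an integer count matrix that would produce half-integers
  raises: counts are symmetrized only after normalization.
- Bootstrap p-values are never bootstrapped; the point estimate's
  analytic p is reported with the resampled CI.
- Analysis problem sizes in the shipped tests (500–1,000 simulated
  tables, 50 seeds per simulator grid cell, B = 300–2,000) were chosen
  so Monte-Carlo error is well below each asserted margin.
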