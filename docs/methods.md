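# Methods

## The focused embedding

Input is a dissimilarity matrix `d_ij` — any symmetric nonnegative matrix
with zero diagonal. Metricity is *not* required (correlation
dissimilarities like `1 − Spearman` may violate the triangle inequality and
are accepted); an opt-in O(n³) triangle check is available for inputs that
should be metric by construction.

One point is designated the focus and pinned to the origin. Every other
point `i` is placed in polar coordinates `(r_i, φ_i)` with the radius fixed
exactly at `r_i = d(focus, i)`. This is the method's contract: focal
distances are represented without error, and the unavoidable distortion of
a planar embedding is pushed entirely onto the non-focal pairs. The free
angles are chosen greedily: points are inserted one at a time in order of
increasing focal distance (ties broken by label), and each new point takes
the angle minimising its stress against the points already placed,

    stress_i(φ) = Σ_j (D_ij(φ) − d_ij)²,
    D_ij = sqrt(r_i² + r_j² − 2 r_i r_j cos(φ − φ_j)).

The first inserted point has an empty stress sum and goes to `φ = 0`; the
second has two mirror-equal optima and the search deterministically returns
one of them. Both conventions are harmless: overall rotation and reflection
are arbitrary in any MDS. Points at distance zero from each other
legitimately coincide. The total `placement_stress` is the sum of
per-insertion minima and equals the raw stress over all non-focal pairs;
focal pairs contribute exactly zero by construction.

Greedy univariate optimisation is the deliberate design: solving n − 1
one-dimensional problems costs O(n²) stress-term evaluations in total,
versus the much costlier simultaneous optimisation over all 2n coordinates,
and it preserves the focal guarantee exactly rather than approximately.
The cost of greediness is that early insertions cannot anticipate later
ones; inserting from the focus outward makes the best-constrained points
commit first, which works well in practice (planar inputs are recovered to
machine precision; see below).

### The angular search

`stress_i(φ)` is periodic and multimodal — with k placed points it can have
up to ~2k local minima — so a single descent from an arbitrary start is not
reliable. The implemented search:

1. evaluates the stress on a uniform grid of `grid_size` angles (default
   64) **plus** the analytic circle–circle intersection angles
   `φ_j ± arccos((r_i² + r_j² − d_ij²) / 2 r_i r_j)` for every placed point
   `j` with a feasible constraint — these are the angles where one stress
   term vanishes exactly, and sum minima concentrate near them;
2. takes the circular local minima of the grid together with all analytic
   candidates, keeps the best 16 by stress value, and refines each with a
   bounded Brent minimisation (golden section + successive parabolic
   interpolation, `scipy.optimize.minimize_scalar(method="bounded")`) on a
   bracket of ±(2π/grid_size);
3. returns the best refined angle, normalised to [0, 2π).

A plain grid-then-single-Brent scheme misses the global basin once basins
become narrower than the grid spacing (k ≳ 30 at grid 64); the analytic
seeds cover exactly those narrow basins. The tests hold the search to a
36,000-point dense-grid oracle: across hundreds of random insertion
subproblems the returned stress is never above the dense-grid minimum (in
practice it is below it, since Brent refines past the grid resolution).

The Brent wrapper itself (`minimize_univariate`) adds one parabolic polish
step after the library solver returns: the bounded solver terminates at a
√eps-scale interval, and a single parabola fit through symmetric
neighbours localises a smooth minimum one to two orders of magnitude
tighter (closed-form test minima are recovered to ~1e-10).

Defaults: `grid_size = 64`, `tol = 1e-8` radians. The algorithm is fully
deterministic given `(dist, focus, grid_size, tol)` — there is no random
state anywhere in the solver.

### Refocusing

Moving the focus to another point re-solves from scratch: the exact-radius
guarantee is relative to the focus, so no previous geometry is reusable.
Radii after refocusing depend only on `d`, hence refocusing back restores
the original radii exactly.

### Scale

Placement is O(n²) stress-term evaluations plus the per-insertion candidate
scans; 1000 points complete in ~25–30 s on one CPU (measured by the
acceptance script), with residual stress on planar input still at the 1e-23
level.

## Diagnostics

Raw stress is `Σ_{i<j} (D_ij − d_ij)²` over unordered pairs (reported once
per pair; the per-point distortions count each pair at both endpoints and
therefore sum to twice the total). A normalised variant,
`sqrt(Σ(D−d)²/ΣD²)`, is provided for cross-dataset comparison. Shepard
data lists every unordered pair with both distances, sorted by `d` for
stable output. Configuration-recovery tests use a Procrustes residual:
relative Frobenius misfit after centring and optimal rotation/reflection
(optionally uniform scale, used for the nonmetric solver whose output scale
is arbitrary).

## Baseline nonmetric MDS

Kruskal's stress-1 `sqrt(Σ(D − d̂)² / ΣD²)` is minimised over planar
configurations, where the disparities `d̂` are the isotonic (monotone
nondecreasing, pool-adjacent-violators) regression of the embedded
distances onto the input dissimilarities — only the rank order of `d`
matters. The solver alternates isotonic fits (scikit-learn's
`IsotonicRegression`) with Guttman-transform updates and halves any step
that would increase stress-1 (up to 30 backtracks), so the recorded stress
sequence is non-increasing by construction; iteration stops when the
improvement drops below `tol` (default 1e-6) or `max_iter` (default 500).
Initialisation is classical (Torgerson) scaling — eigendecomposition of
the double-centred squared-distance matrix with a deterministic sign
convention — making the whole procedure deterministic. Ties in `d` follow
the primary approach: tied dissimilarities may receive unequal disparities.
A metric variant (`d̂ = d`) is available. Degenerate all-coincident
initialisations are spread on a small deterministic circle before
iterating.

## Distance nets

Edges are all unordered pairs with `d_ij ≤ t` (inclusive, matching the
slider semantics of interactive use); the layout never influences the edge
set, only the rendering. Weights ramp linearly from 1 at `d = t − s` to 0
at `d = t`; since inclusion is `d ≤ t` while the ramp vanishes at `t`, an
edge sitting exactly at the threshold is floored at weight 1e-12 so that
inclusion always implies positive weight. Softness defaults to 10% of the
distance scale `(max − min)` over off-diagonal entries; a hard threshold
(`s = 0`) gives every included edge weight 1. Thresholds outside the scale
are clipped with a warning. Rendering may drop edges below 1/255 opacity;
the data edge list never does.

## Preprocessing recipes

The single-cell pipeline applies, in order: (1) QC — drop cells with total
counts strictly below 2500, then genes with totals strictly below 25
*computed over the surviving cells* (cells-first is a documented choice;
the alternative order is available via the stage functions); (2) a
correlation gene filter — gene–gene Pearson correlation on counts (Spearman
via option), cutoff at the 90th percentile of the off-diagonal values
(the diagonal of 1s would bias a whole-matrix percentile), keeping genes
with ≥ 5 partners strictly above the cutoff; constant genes are excluded
from the correlation with a warning and dropped; (3) normalisation
`log2(count / cell_total × 10³ + 1)`, which maps zeros to exactly zero and
is monotone within a cell; then either (4a) the 200 most variable genes
(plain variance of the normalised values, ties by gene order) and
`1 − Spearman` between cells, or (4b) the first 50 principal components
(genes centred, deterministic sign convention) and Euclidean distances
between cells. The drug-screen recipe is Manhattan distance between sample
score profiles, no filtering, and accepts negative scores.

The correlation cutoff is data-dependent by definition; the recipe reports
the computed value per run rather than assuming any particular number.
The Spearman dissimilarity is computed between samples (cells) over the
selected genes — the embedding is of cells, so cell–cell distances are the
quantity the plot needs.

## Synthetic data

All generators are pure functions of their arguments including the seed
(`numpy.random.default_rng`, no global state).

* `planted_2d` samples points uniformly in a square and returns exact
  pairwise Euclidean distances plus the ground truth; optional Gaussian
  perturbation of the distances (symmetrised, clipped at zero) gives
  not-quite-planar inputs. Noise-free output is the zero-stress oracle:
  both solvers must recover it up to rigid motion.
* `clustered_features` draws cluster centres N(0, separation²) per feature
  and samples N(centre, 1), so `separation` is in within-cluster SD units;
  defaults (308 features × 58 samples, 4 clusters) mirror an ex-vivo drug
  screen's shape. `separation = 0` plants no structure.
* `synthetic_counts` fixes per-cell depths deterministically on both sides
  of the 2500 cut (a 25% low-depth fraction by default, depths 1200–9000)
  and draws each cell's counts from a multinomial over gamma-perturbed,
  type-specific gene rates, so column totals — and hence QC outcomes for
  cells — are exact by construction. A block of near-silent genes has
  expected totals spanning the 25 cut. Dropout thins gene–cell rates
  before sampling.

What the generators deliberately do not model: batch effects, ambient
contamination, doublets, gene–gene correlation structure beyond the type
programs, or real dose–response noise. Passing tests therefore demonstrate
algorithmic correctness (exact radii, oracle dominance, integer-exact
filters, planted-structure recovery), not biological performance on any
particular real dataset.

## Numerical choices and edge cases

* Asymmetries up to 1e-9 (absolute) are repaired by averaging; larger ones
  are rejected naming the offending pair. Diagonals are hard-set to zero
  after distance computation to suppress floating-point residue.
* Stress sums run over unordered pairs; per-point distortions double-count
  by design (documented factor 2).
* `classical_scaling` pads missing positive eigenvalue dimensions with
  zeros and warns; `pca_reduce` clips excess component requests and warns.
* Duplicate points, all-zero rows, constant genes, zero-total cells and
  label mismatches each have a defined behaviour (coincident placement,
  rejection, warned exclusion, rejection, error listing the symmetric
  difference, respectively).

## Problem sizes

The test suite and acceptance script run at: 100 random matrices with
n ∈ [3, 60] for focal exactness; 20 planted configurations with
n ∈ [10, 50] for recovery; 200 insertion subproblems with up to 20 placed
points against the 36,000-point angular oracle; distance-net sweeps at
n ∈ [30, 100] × 25 thresholds; count matrices of 120 genes × 60 cells for
the filter oracles; and one 1000-point embedding for the scale envelope.
These sizes exercise every code path at full numerical strength while the
whole suite stays in the one-minute range.

## Known limitations

* The greedy angular placement is order-dependent; a different insertion
  order changes the non-focal layout (the focal radii never change). The
  sorted-by-radius order is the default; input order is available for
  comparison.
* Non-focal pair distances can be badly distorted when the data are far
  from planar — that is intrinsic to the method's contract, and the
  Shepard/distnet diagnostics exist precisely to make it visible.
* The nonmetric solver finds a local stress-1 minimum; with the
  deterministic classical-scaling start this is reproducible but not
  guaranteed global.
* Interactivity (slider dragging, click-to-refocus animation) is out of
  scope; the CLI and JSON/SVG exports expose the same quantities
  statically.
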