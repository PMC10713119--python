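# Methods

## Model

Let `D` be an `n x n` symmetric, hollow, nonnegative dissimilarity
matrix over samples. Bounded community measures lose resolution once
samples share few features: all sufficiently separated pairs report
(nearly) the maximal value, so the distribution of pairwise values
left-skews toward the ceiling and PCoA of `D` bends a one-dimensional
gradient into an arch. The adjustment assumes the samples lie on a
low-dimensional manifold along which *short* dissimilarities approximate
true separation, and replaces every pairwise value with a graph
geodesic:

1. **Neighbor graph.** Edge `(i, j)` with weight `D[i][j]` iff
   `D[i][j] < r` (strict; a tie at exactly `r` is excluded). A zero
   off-diagonal entry — exact duplicates — is kept as a weight-0 edge so
   duplicates remain mutually at distance 0.
2. **Connectivity repair.** If the graph fragments, a minimum spanning
   tree of the complete graph on `D` is computed once (Kruskal;
   equal-weight ties broken lexicographically by node pair, so the tree
   is reproducible). Its edges are walked in increasing weight and any
   edge joining two components of the current graph is added and flagged
   *borrowed*; exactly `c - 1` edges are added for `c` components, each
   the minimum-weight original entry across the cut it bridges.
3. **Geodesics.** The adjusted value is the all-pairs shortest-path
   length through the repaired graph (Dijkstra from every node; weights
   are nonnegative, duplicates are free hops). The result is a genuine
   path-length metric: symmetric, hollow, and triangle-inequality-
   consistent. Because the input need only be a semimetric
   (Bray–Curtis is), a geodesic may undercut a *direct* entry that
   violated the triangle inequality; this is accepted — the output must
   be metric.

The transform is monotone in the radius: a larger radius keeps a
superset of edges (threshold edges trivially; every still-needed
borrowed MST edge is re-borrowed by the cut property), so adjusted
entries never increase as `r` grows. With `r` above the maximum
distance of a metric input the transform is the identity.

## Radius selection

Candidate radii are `n_radii` (default 50) evenly spaced values spanning
`(min positive off-diagonal, max distance]`, endpoint included — the
data range is the only scale the problem offers; the largest candidate
reproduces (nearly) no adjustment and the smallest approaches the
connectivity floor.

- **Degree screen (`phi`, default 0.10).** A radius is eligible only if
  the mean number of *trusted* edges per node is at least
  `phi * n`. Borrowed MST edges are not counted: they exist at any
  radius and would mask exactly the sparsity the screen exists to
  detect.
- **Objective.** Each eligible radius is scored by the Pearson
  correlation between its adjusted distances and the Euclidean
  distances among its own PCoA coordinates, using the fewest axes (at
  most `max_dims = 10`) whose cumulative positive-eigenvalue variance
  exceeds `variance_threshold = 0.80`. This measures how faithfully the
  adjusted matrix embeds — an over-aggressive radius distorts the
  geometry and scores poorly.
- **Rule (`epsilon`, default 0.05).** Walking the eligible radii from
  largest to smallest, the first one is the incumbent; a smaller radius
  replaces it only by exceeding the incumbent's score by more than
  `epsilon`. Ties and sub-margin gains keep the larger radius: trusting
  more original data is the default posture. With `epsilon = 0` the
  rule is argmax (largest radius among ties); with `epsilon = inf` the
  largest eligible radius always wins.
- **No eligible radius** (or fewer than 4 samples, where the PCoA
  objective is meaningless): the input is returned unadjusted and the
  chosen radius is reported as none.
- **Smoothing (off by default).** Optionally the adjusted matrices of
  all eligible radii are averaged elementwise with Gaussian weights
  centered at the chosen radius (`sigma` defaulting to one tenth of the
  candidate-grid span). The output is a convex combination, hence
  bounded by the elementwise envelope of its inputs. On mildly
  oversaturated data this barely changes the result; on strongly
  saturated inputs the smaller radii contribute inflated long distances,
  so individual entries can shift noticeably even though the recovered
  gradient is unchanged — the tests assert the mean shift is small and
  the axis-1/gradient correlation survives.

Selection is deterministic given the matrix and the parameters; there is
no randomness anywhere in the adjustment itself.

## Ordination and the oversaturation diagnostic

PCoA is the classical algorithm: double-center `-0.5 * D^2`,
eigendecompose symmetrically, scale eigenvectors by the square roots of
the positive eigenvalues. Negative eigenvalues (non-Euclidean
dissimilarities) are dropped rather than corrected, and variance
fractions are renormalized over the positive spectrum; each axis gets a
deterministic sign (largest-magnitude loading positive) so repeated runs
are bit-identical. Axis–gradient agreement is reported as the absolute
Pearson correlation, since the sign of a principal coordinate is
arbitrary.

Oversaturation is diagnosed from the adjusted Fisher–Pearson sample
skewness of the strict upper-triangle values; the boolean flag fires
below a cutoff of −0.1. The cutoff is a convention — "large left skew"
has no canonical number — so the numeric skewness is always reported
alongside the verdict.

## Synthetic data

The gradient community emulates a gradient-driven ecosystem: feature `k`
has a Gaussian response curve (coenocline) centered at `c_k`, centers
spaced 10 units apart from −650 to 1650 (231 features) around a gradient
of length 1000, all with SD 150. The margin of 650 both yields the
target feature count and keeps edge samples from seeing a truncated
species pool. A sample at position `x` receives each curve's density at
`x` and is closed to relative abundance, so curve heights are
irrelevant. Fifty base samples sit at evenly spaced positions; each
receives one Dirichlet noise replicate whose concentration vector is the
parent composition times `dirichlet_scale = 500` (floored at 1e-12 so
distant features stay legal). The scale controls noise tightness —
draws have mean equal to the parent composition and variance shrinking
as the scale grows; 500 keeps replicates near their parents while
visibly scattering, and at that level the unadjusted axis-1/gradient
correlation lands at ≈0.966, rising to ≈0.9998 after adjustment at
radius 0.4.

What the generator does *not* emulate: sequencing-depth/count noise,
overdispersion beyond the Dirichlet, uneven sampling along the gradient,
multiple or interacting gradients, and non-unimodal species responses.
Passing tests therefore demonstrate correct behavior under idealized
gradient sampling, not performance on real survey data.

The Swiss roll is the standard benchmark parametrization
(`t = 1.5π(1 + 2u)`, point `(t cos t, 21v, t sin t)`, `u, v` uniform).
The unrolling benchmark scales the coordinates by 1/10, where the gap
between adjacent whorls is `2π/10 ≈ 0.6283`; a neighborhood radius of
0.62 then sits just inside the gap, excluding across-whorl shortcuts
while keeping along-sheet edges, and PCoA of the adjusted matrix
recovers the arc parameter with |r| > 0.98 where raw PCoA manages ≈0.2.

## Numerical choices and problem sizes

- Asymmetry up to 1e-8 is symmetrized as `(M + M.T)/2`; worse is an
  error. Serialized matrices carry 17 significant digits, making
  read/write round trips lossless for doubles.
- Geodesic matrices are symmetrized after Dijkstra to erase last-ulp
  asymmetry from summing a path's edges in opposite orders, and
  eigenvalues below `1e-12 * max|λ|` are treated as zero in PCoA.
- Jaccard is the binary (presence/absence) form; abundance-weighted
  variants are out of scope.
- The test suite and the benchmark script run the full pipeline at the
  generator's native sizes (100 gradient samples, 300 Swiss-roll
  points) and property checks on random instances of 4–30 samples;
  everything completes in well under a minute on one core.

## Known limitations

- Radius auto-selection evaluates up to `n_radii` full geodesic
  computations (`O(n^2 log n)` each) and keeps every eligible adjusted
  matrix in memory when smoothing; fine into the hundreds of samples,
  unoptimized beyond that.
- The objective rewards embedding fidelity, not gradient recovery (the
  method is unsupervised); on data that already embeds well the largest
  radius wins and the adjustment is conservative by design. Lowering
  `epsilon` makes the selection more aggressive.
- No out-of-sample extension: like other manifold methods, the
  adjustment is defined for the sample set it was fit on.
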