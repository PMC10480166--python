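# Methods

## The ego-distance family

Two undirected, unweighted graphs are compared without any node alignment
by comparing the distributions, over each network, of three per-node egonet
features. For a node *i* with degree *m_i*, egonet *E_i = {i} ∪ N(i)*, and
*e_i* edges among its neighbors:

- **normalized degree** `d_i = (m_i − m_min)/(m_max − m_min)`, the degree
  rescaled by the graph's degree extremes;
- **clustering coefficient** `c_i = 2 e_i / (m_i (m_i − 1))` for `m_i > 1`,
  else 0;
- **egonet persistence** `p_i = Σ_{j∈E_i} m_j^int / Σ_{j∈E_i} m_j`, the
  probability that a degree-proportional random walker currently in *E_i*
  remains in *E_i* after one step (`m_j^int` counts *j*'s neighbors inside
  *E_i*). Isolated nodes take 0 for all three features.

Each feature (or pair, or triple of features) is histogrammed on a fixed
grid of step Δ over [0,1]^k, bin *h* collecting values in `[(h−1)Δ, hΔ)` and
the value 1 going to the last bin. The distance between two graphs is the
Euclidean (Frobenius) norm of the difference of the cumulative distribution
functions. Available metrics: `d`, `c`, `p`, `sum` (= D_d + D_c + D_p),
`cp`, `dc`, `dp`, `dcp`, plus the scalar baseline `Cglobal = |C′ − C″|` on
the mean clustering coefficients. A *cap value* `T ∈ (0,1]` restricts the
comparison to the first `T/Δ` bins per axis: the retained cdf entries are
cumulative masses of the full distribution (no renormalization), only the
summation range shrinks. Since features rarely sit near 1, capping
concentrates the distance on the informative part of the range.

Implementation notes:

- `e_i` equals the number of triangles through *i*, so both `c_i` and the
  persistence numerator `2(e_i + m_i)` come from one sparse masked
  matrix-product; features on an N=4000, ρ=0.02 graph take well under a
  second.
- Distances are **not** normalized by the bin count; values computed at
  different Δ are not comparable. Default Δ = 0.01 (results are largely
  insensitive to it because cdfs are compared, not pdfs).
- The pairwise engine computes each graph's cdf once, stacks the flattened
  cdfs, and uses vectorized Euclidean distances; very large 3-D stacks fall
  back to a float32 store with blocked float64 accumulation so that peak
  memory scales with the number of graphs, not the number of pairs.
- Degenerate inputs: a regular graph leaves `d_i` undefined (`m_min =
  m_max`); the package returns an all-zero vector with a warning, mirroring
  the isolated-node convention, so every metric stays defined on every
  simple graph. Self-loops and duplicate edges are dropped on input with a
  logged warning.

## Synthetic benchmark models

Seven models, each parameterized by size N and density ρ (η = ρN/2 must be
a positive integer for the preferential-attachment family):

- **ER**: each pair edged independently with probability ρ.
- **SFBA**: seed clique of η+1 nodes; each added node attaches η edges to
  distinct targets chosen proportionally to current degree. Edge count is
  exactly η(η+1)/2 + (N−η−1)η.
- **ERDD**: an SFBA graph randomized by 10·L attempted double-edge swaps
  (attempts creating self-loops or duplicate edges are rejected), keeping
  every node's degree.
- **STICKY**: edges drawn independently with probability
  min(1, m_i m_j / Σm) from a fresh SFBA degree sequence; the clamp guards
  against hub products exceeding 1.
- **SFGD** (duplication–divergence): from a connected 2-node seed, each new
  node copies a uniformly chosen node's neighborhood, connects to the
  template with probability 0.5, then each shared neighbor loses one of its
  two edges (chosen uniformly) with probability q.
- **GEO**: N uniform points in the unit cube, edges strictly below radius r.
- **GEOGD**: geometric growth — each new point lands uniformly in the ball
  of radius 2·r₀ around a uniformly chosen existing point (intersected with
  the cube, by rejection sampling), where r₀ = (3ρ/4π)^{1/3} is the ideal
  geometric radius for the target density; edges are thresholded at a
  calibrated radius r at the end. Pinning the placement radius to r₀ rather
  than to the calibrated threshold is a deliberate choice: if placement
  scales with the threshold, the point cloud is scale-invariant and the
  density becomes nearly independent of r (we measured a floor of ≈0.013 at
  N=1000), leaving low target densities unreachable. With the placement
  scale fixed, density is strictly increasing in r and calibration is
  well-posed on the whole benchmark grid.

**Density calibration.** SFGD's q and GEO/GEOGD's r are found by bisection
so that the *mean* realized density over the replica batch (default 10;
grids may use fewer) is within 3% relative tolerance of ρ. Each candidate
parameter is evaluated with the same per-replica child seeds (derived from
the master seed via a counter-based spawn scheme), making the objective a
deterministic monotone step function — increasing in r, decreasing in q —
so bisection is robust; non-bracketing or non-convergence raises a
calibration error with diagnostics. For the geometric models the point
clouds do not depend on the threshold, so density evaluation reduces to a
quantile lookup on each replica's sorted pairwise distances and calibration
is essentially free. The calibrated replicas are the emitted instances,
which is why the batch-mean density matches ρ by construction.

The generators reproduce the *models*, not any particular program's random
stream: only distributional equivalence is claimed. At ρ = 0.004 most
generated networks are disconnected; all features and distances handle
disconnected graphs and isolated nodes.

## Classification harness

Graph pairs are labeled positive when both graphs come from the same model.
A pair is predicted positive when its distance is below ε; sweeping ε over
the distinct observed distances (ties enter together, so the curve is
deterministic) yields Precision/Recall points, summarized by the area under
the curve. The AUPR estimator is non-interpolated average precision (step
integration of precision over recall increments); a trapezoidal variant is
available for sensitivity checks and differs by < 0.01 at benchmark pair
counts. The restricted evaluation keeps only pairs with equal (N, ρ),
scoring the easier task where size and density are not confounders.

## Benchmark scale and what the tests show

The full published benchmark uses 10 replicas per (model, size, density)
cell — 630 networks over N ∈ {1000, 2000, 4000} and ρ ∈ {0.004, 0.01,
0.02}. The package's acceptance tests run the three-model (ER/GEO/SFBA)
grid at full scale (270 networks) and the seven-model grid at 5 replicas
per cell (315 networks), a scale at which the AUPR estimates are within a
few points of the full-scale values; `scripts/acceptance.py` uses the same
5-replica scale. Because the benchmark is purely synthetic, passing it
demonstrates that the distances discriminate these seven generative
mechanisms under size/density confounding — not that they separate any
particular family of real networks; the features real data add (weights,
direction, degree-dependent noise, community structure not expressible by
these models) are outside what the generators emulate.

## Known limitations

- The normalized degree depends on the realized extremes m_min, m_max, so
  `d`-based distances between same-model replicas jitter with the extremes
  (visible as wide within-model spread for ER under 3-D capped distances).
- Weighted and directed generalizations of the features are not
  implemented.
- Graphlet-based baselines are out of scope; the global-clustering baseline
  `Cglobal` is included.
- The 3-D metric at Δ = 0.01 manipulates 10^6-bin grids per graph; for
  collections of thousands of graphs prefer a cap T < 1 or the 2-D metrics.
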