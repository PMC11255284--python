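# Methods

## The model

A multilayer network couples `N` nodes across `M` layers; its elementary unit
is the node-layer duplet `(i, α)`.  Connectivity lives in a symmetric
supra-adjacency matrix of order `N·M` with zero diagonal.  The same matrix can
be laid out layer-major (duplet `(i, α)` at row `α·N + i`; the *primal*
nodewise view `X`) or node-major (row `i·M + α`; the *dual* layerwise view
`Y`).  The two layouts are related by the commutation (perfect-shuffle)
permutation `P`, `Y = Pᵀ X P`, an involution that swaps the roles of nodes and
layers while preserving every entry: `X_ij^{αβ} = Y_αβ^{ij}`.  Under the
transform, replica links (same node, two layers) become intralayer, intralayer
links become replica, and interlayer links stay interlayer.  A *multiplex* is
the special case whose interlayer links are all replicas; its dual is again a
multiplex.

Multidegree centrality is the literal four-index block sum,
`k_X^i = Σ_{jαβ} X_ij^{αβ}` and `k_Y^α = Σ_{ijβ} Y_αβ^{ij}`.  Consequently a
replica edge contributes twice its weight to its node and an intralayer edge
twice to its layer.  We adopt this convention deliberately: it is the only one
under which the nodewise and layerwise totals coincide (`Σk_X = Σk_Y = 2·W`,
`W` the total weight), the duality is exactly symmetric, and the scaling
constant below equals 1 exactly for self-dual systems.  Counting replica and
intralayer contributions once instead would break all three properties.

## Stochastic rewiring

A perturbation selects `round(r·L)` edges without replacement (`r ∈ [0,1]`,
round-half-to-even) and relocates each to an empty admissible slot.  The slot
is drawn by first sampling a move type from `(p_node, p_layer, p_tel)`
(summing to 1):

* **node move** — keep the unordered layer pair, redraw the node pair;
* **layer move** — keep the node pair, redraw the layer pair;
* **teleportation** — draw uniformly over all admissible slots.

Destinations that are occupied, equal to the source, self-edges, or that would
break a multiplex's nature are rejected and redrawn; after `max_attempts`
(default 1000) failed draws the move type itself is redrawn, and the whole run
aborts after `max_attempts·L` total proposals (only pathologically dense
networks get there).  Moves are processed sequentially against the current
edge set, so a later move may occupy a slot an earlier move vacated.  Two
conventions the description above leaves open were fixed as follows: a node
move on a multiplex replica edge keeps the (interlayer) layer pair and hence
draws another replica; symmetrically, a layer move on an edge with `i ≠ j` in
a multiplex stays intralayer.

Exact conservation laws, enforced and tested: `L`, the nature, and the edge
weights are invariant; `p_node = 1` preserves the layerwise multidegree
sequence exactly; `p_layer = 1` preserves the nodewise sequence.

*Uniform rewiring* draws destinations uniformly over all admissible empty
slots.  `effective_params(N, M, nature)` returns the slot-count mixture
`(p_node, p_layer, p_tel)` this induces: for each source-edge class the
fraction of slots preserving the layer pair (respectively the node pair, with
layer-pair preservation taking priority) is computed exactly, and classes are
weighted by their slot-count share.  Occupancy corrections are neglected
(valid for sparse networks); the mixture matches observed move-class
frequencies within Monte-Carlo error in the tests.

## Closed forms

For sparse, large networks the expected multidegree after rewiring relaxes
linearly towards the mean,

    k(r) = k₀ + r (μ − k₀) (1 − p_layer)        (nodewise)
    k(r) = k₀ + r (μ − k₀) (1 − p_node)         (layerwise)

and the norm of the expected displacement is

    d_X(r) = r √N σ_X (1 − p_layer),   d_Y(r) = r √M σ_Y (1 − p_node),

with **population** (divide-by-n) standard deviations — the convention under
which `d` is *exactly* `‖E[k(r)] − k₀‖₂`, not merely asymptotically.  The two
distances obey `d_Y = c · (1−p_node)/(1−p_layer) · d_X` with
`c = √M σ_Y / (√N σ_X)`; at `p_layer = 1` the ratio is undefined and `d_Y` is
reported from its own formula (slope = NaN).

An important estimation subtlety: the closed forms predict the norm of the
*expected* displacement.  A single realized rewiring adds zero-mean
fluctuations of variance comparable to the squared expected displacement
(multidegrees of sparse random networks are Poisson-like, so σ² ≈ μ), which
inflate single-shot distances by an `O(1)` factor.  The empirical mode of
`dual_distances` therefore averages displacements over `n_rewired`
realizations and subtracts the unbiased per-unit sampling variance from the
squared norm; the acceptance-style Monte-Carlo test uses the equivalent
pair-product U-statistic with a jackknife standard error.  Raw
single-realization distances are still what the sweep table and
`centrality_distance` report, because ratios and orderings of such distances
(the quantities compared across parameter settings) are meaningful without
de-biasing.

## Random-network standard deviations

For Bernoulli slot occupancy (each admissible slot independently occupied with
probability `q`), a unit's multidegree is a weighted sum of independent
Bernoulli variables (weight 2 on replica slots nodewise / intralayer slots
layerwise).  Counting incident slots, and correcting the *population* variance
across exchangeable units for their covariance
(`E[popvar] = (1 − 1/n)(Var k − Cov(k, k'))`, with `Cov` from slots shared by
two units), gives

    multilayer, nodewise :  (1−1/N) q(1−q) [M²(N−2) + 2M(M−1)]
    multilayer, layerwise:  (1−1/M) q(1−q) [N²(M−2) + 2N(N−1)]
    multiplex,  nodewise :  (1−1/N) q(1−q) [M(N−2)  + 2M(M−1)]
    multiplex,  layerwise:  (1−1/M) q(1−q) [2N(N−1) + N(M−2)]

At `N = M` the two multilayer forms coincide, so `c = 1` exactly in
expectation — the basis of the headline acceptance check.  All four forms are
validated against the generator + multidegree simulation oracle within three
standard errors.  Leading-order consequences for complete uniform rewiring:
`d_X ≈ d_Y ∝ NM` for multilayers, and `d_X ∝ √M N`, `d_Y ∝ √(2M) N` for
multiplexes (layerwise variance is dominated by double-counted intralayer
slots, hence the factor 2).  Under `N + M` fixed, the multilayer scale peaks
at `N = M` while the multiplex nodewise scale `√M·N` peaks at `M = (N+M)/3`,
i.e. `N − M = (N+M)/3`; the package finds the optimum numerically
(`optimal_multiplex_split`) rather than hard-coding the closed form.

The `√2` multiplex ratio is an `N ≫ M`, `M ≫ 1` limit.  At the finite sizes
used in the tests (`N = 2000`, `M = 20`) three corrections of a few percent
each remain — the effective `p_node ≈ 1/M` of uniform rewiring, the
`(1 − 1/M)` population-variance factor, and single-realization fluctuation
inflation — which partially cancel; the observed mean ratio sits within 5% of
`√2`, and the test asserts exactly that.

## Generators

* `random_multilayer` / `random_multiplex`: edge count drawn as
  `Binomial(S, q)` (`S` the nature-specific slot count), then a uniform
  `L`-subset of slot indices without replacement.  `q` is defined *relative to
  the nature's own slot space*, so multilayer and multiplex densities are not
  directly comparable.  Slots are encoded as integers and sampled by rejection
  of duplicates — the slot space (≈ 8·10⁸ at `N = M = 200`) is never
  enumerated.  A `fixed_l` option pins `L` exactly for matched-size baselines.
* `powerlaw_multidegree`: intralayer edges drawn with Zipf attachment weights
  `w_i ∝ (i+1)^{−1/(γ−1)}` on nodes (and, by default, the analogous weights on
  layers), giving realized multidegree sequences with rank-size tail slope
  `≈ −1/(γ−1)` (tested within 20%).  Heterogeneous layer weights are the
  default because real multiplexes concentrate links on few layers; that layer
  heterogeneity is what pushes the layerwise normalized distance above the
  random baseline.

What the generators do *not* emulate: degree-degree correlations, community
or spatial structure, weighted links, and the empirical layer-size
distributions of specific real systems.  Tests passing on these fixtures
certify the machinery (duality, rewiring, closed forms), not the behavior of
any particular real network.

## Dual-distance analysis and normalization

`dual_distances` measures how far a network's two multidegree profiles would
drift under rewiring, analytically by default (`n_rewired = 0`: the closed
forms with the network's own sigmas — the route that avoids simulating very
large systems) or empirically with the de-biased estimator.
`normalize_against_random` divides by the distances of a random network of the
same nature, `N`, `M` and `L` (closed-form sigmas at `q = L/S` in analytic
mode; generated and rewired equivalents otherwise), removing network-size
biases so differently sized systems can share one axis.  Uniform-rewiring
`r` defaults to 1 (complete rewiring), configurable.

`aggregate_layers` coarsens layers by an explicit layer→group mapping (e.g.
frequency bins into bands): weights of merged parallel edges are summed, and
replica edges falling inside one group are dropped (logged, with weight
accounting) since they would become self-edges.

## Projection plots

The contribution matrix `C[i, α] = Σ_{j,β} X_ij^{αβ}` counts the links node
`i` shares with layer `α` from duplet `(i, α)`; this reading is chosen because
its marginals are then exactly the two multidegree profiles.  A truncated SVD
`C = U Σ Vᵀ` gives node points at rows of `C·V` (equivalently `σ_k U_{·k}`) so
that point norms carry multidegree magnitude, layer lines along rows of `V`,
and the mirrored construction for the layerwise plot.  Point distance from the
origin is proportional to multidegree only insofar as row norms track row
sums; the shipped property is a Spearman rank correlation > 0.9 on random and
power-law fixtures, and exact proportionality is deliberately not asserted.
Signs follow the first-nonzero-positive convention so output is deterministic.

## Numerical choices and problem sizes

* RNG: every stochastic routine accepts an integer seed or a
  `numpy.random.Generator`; rewiring move loops run on `random.Random` bridged
  deterministically from the supplied source (scalar draws are an order of
  magnitude faster there).  Identical seed + input ⇒ identical output,
  including byte-identical sweep tables.
* Edge selection rounds `r·L` half-to-even; edges are selected from the
  canonically sorted edge list so results do not depend on construction order.
* Simulation-versus-theory tests run at `N = M = 100` with `q = 2·10⁻⁴`
  (about 10⁴ edges) and 40 replicates per grid point, and the symmetric-`c`
  and `√2`-ratio checks at the sizes quoted above — chosen as the smallest
  systems comfortably inside the sparse/large regime the closed forms assume.
* Dense supra matrices are materialized only for small systems (I/O,
  brute-force oracles); all large-scale analysis runs on edge arrays.
* `scaling_constant` raises on `σ_X = 0` (empty or perfectly regular
  networks); `project` raises on an all-zero contribution matrix; degenerate
  geometries with a single layer force `p_node = 1` in the effective uniform
  mixture.

## Known limitations

* Closed forms are first-order in `r` and sparse-limit; dense networks
  (`q` not ≪ 1) rewire correctly but drift from the predictions.
* Directed and temporal semantics are out of scope; directed input rows are
  symmetrized on read.
* The power-law generator targets marginal heterogeneity only; it does not
  realize arbitrary joint node-layer degree sequences, and infeasible
  requests (more than half the intralayer slots) are rejected rather than
  approximated.
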