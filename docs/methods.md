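# Methods

## The two-queue BFS mapping

The mapping is a FIFO breadth-first search with two append-only queues.
QueueT receives each vertex once (on first touch); QueueG receives, when a
vertex is explored, one copy per incident edge endpoint — including
endpoints of self-loops (two copies) and parallel edges (one copy per
copy of the edge) — plus the root's own copy at the very start.  Positions
are normalized by the total vertex count `N`, not by the component size, so
the terminal value of a curve is the explored fraction `S` of the whole
graph.  A vertex's *reference copy* is the QueueG copy through which it was
first touched; the y-coordinate of every copy pushed while exploring vertex
`v` is the position of `v`'s reference copy.  Both conventions were fixed by
replaying a fully worked six-vertex traversal against its printed
coordinates (see `tests/test_bfsmap.py::TestReplayedTraversal`).

The default root is one end of a uniformly chosen edge (size-biased, hence
almost surely inside the giant component of a supercritical graph); an
explicit `root=` overrides it.  Neighbors of each explored vertex are pushed
in a uniformly shuffled order driven by the run seed; a `neighbor_order`
hook replaces the shuffle for deterministic replays.  One integer seed fixes
the root choice and every shuffle, making runs bit-reproducible.

## Mean-field curve theory

For a configuration-model graph with degree pmf `P(k)`, pgf `φ`, mean
`z = φ′(1)`, the derivation tracks the probability `θ(u)` that a given
half-edge is still unmatched after a fraction `u` of vertices has been
explored.  Untouched vertices of degree `k` survive with probability `θ^k`,
so the untouched fraction is `φ(θ)` and the untouched degree distribution is
`P(k)θ^k/φ(θ)`.  Three bookkeeping identities close the system:

* free half-edges: `F(u) = zθ(u)²` (each consumption removes one stub of
  the explored vertex and one partner stub);
* newly touched vertices are size-biased among the untouched, so the vertex
  explored at time `u` has expected degree `1 + βφ″(β)/φ′(β)` with
  `β(u) = φ⁻¹(1−u)` its touch-time survival variable;
* integrating the resulting ODE gives the closed solution
  `θ(u) = φ′(β(u))/z`, touched fraction `T(u) = 1 − φ(θ(u))`, and QueueG
  length `G(u) = z − βφ′(β)`.

The tree curve is `f_T = T⁻¹`; since exploration order equals touch order
(FIFO), the vertex explored at `u` was touched at `v = T⁻¹(u)`, and the
graph curve is the arc `(G(u), G(v(u)))`.  Termination `T(u) = u` reduces to
`β* = φ′(β*)/z`, the Molloy–Reed/Newman fixed point, and `S = 1 − φ(β*)`:
the curve's terminal ordinate *is* the giant-component fraction.  The
mean-field solution drops `O(1/N)` terms, so quantitative tests run at
`N ≥ 10⁴`.

Checks built into the suite: the Erdős–Rényi case gives
`T(u) = 1 − e^{−zu}` (the graph-curve inversion passes through the
principal Lambert-W branch, whose argument stays positive on the curve's
domain); the `k`-regular case gives `f_T(x) = 1 − (1−x)^{1/(k−1)}`; the
general solver reproduces both closed forms to ~1e−9; analytic curves stay
within 0.006 of single BFS runs at `N = 10⁵` for regular, Poisson,
lattice-embedded and power-law graphs.

### Numerical choices

The general-`P(k)` curves are computed without inverting `T` numerically:
with `β(x) = φ⁻¹(1−x)`, the tree curve is
`f_T(x) = 1 − φ((φ′)⁻¹(zβ(x)))` and the graph-curve ordinate is
`z − b₂φ′(b₂)` with `b₂ = (φ′)⁻¹(zβ)`.  Only the two monotone polynomial
inverses are tabulated (200,000 cosine-spaced nodes, clustering resolution
at the steep ends); forward evaluations are exact polynomial evaluations,
which damps the table error exactly where the curves steepen.  The
fixed point `β*` is found by scanning 2,000 brackets upward from 0 and
polishing with Brent's method (`xtol = 1e−14`); `β* = 0` is returned
directly when `P(1) = 0` (an edge can then never reach a dead end).
Distributions are finite arrays `P(0..k_max)`, so all moments exist; a
power-law family is specified by `(τ, k_min, k_max)` with the normalization
constant computed numerically.

### Lattice-embedded random regular graphs

A `d`-dimensional periodic torus superposed with an independent `r`-regular
configuration-model overlay.  Its curves keep the regular-family shape
`f_T(x) = 1 − (1−x)^{1/γ}` with `γ` the largest real root of

```
(γ+1)(γ−1)^d = r[(γ−1)^d + 2^d].
```

The polynomial comes from an early-search balance argument: per explored
vertex, long-range touches contribute `r·γ/(γ+1)` children while lattice
fronts contribute through shells of the torus ball (`~2^d j^{d−1}/(d−1)!`
sites at distance `j`) advancing once per queue-delay period.  For `d = 1`
the root is `2d + r − 1`, i.e. the ring adds nothing beyond a regular graph
of the same total degree; for `d ≥ 2` the root drops below `2d + r − 1`
(e.g. γ = 3 instead of 5 at `d = 2, r = 2`) because lattice edges
increasingly point back into the explored ball.  The exponent was validated
against simulation: the family curve with the polynomial root tracks a
single run at `N = 10⁵` to < 0.001 over the curve bulk.

### Traceroute density

Within the one-parameter family the expected number of children at position
`x` is `d_T(x) = γ(1−x)^{γ−1}`.  Treating tree degrees by their expected
values only, the density of tree degrees `m` (children + 1 for the parent
link) is the push-forward of the uniform position measure:
`ρ(m) ∝ (m−1)^{−(γ−2)/(γ−1)}` on `1 < m ≤ 1+γ` — an apparent power law with
exponent approaching 1 for large `γ`, with a hard cutoff at `1+γ` and a
finite-size floor at position `1 − 1/N`.  This expected-value estimate
ignores the fluctuation of children counts around their mean, so the
comparison against simulated histograms is made on the log–log slope of the
body (`2 ≤ m ≤ γ`), where the two agree within ~0.05–0.15.

## Curve deviation statistic

Empirical-versus-analytic agreement is measured as the *directed* sup
deviation: the maximum over BFS cloud points of the Euclidean distance to
the analytic polyline.  A vertical sup-norm is ill-posed at the curve
endpoint, where the analytic slope diverges and the placement of the last
few vertices fluctuates by `O(N^{−1/γ})` (≈ 0.18 for γ = 7 at `N = 10⁵`)
without carrying any information about shape agreement; the directed
statistic operationalizes the claim actually being tested — that the point
cloud lies *on* the curve — and is < 0.006 for every family at `N = 10⁵`.

## Graph distance and alignment

The distance between two networks is the area between their characteristic
curves after alignment.  Each curve's x *and* y are divided by that graph's
giant-component average degree `z_gc = 2M_gc/N_gc`; because the raw curve
terminates at `(x_end, x_end)` with `x_end = (2M_gc+1)/N`, the normalized
curve maps onto `[0, S]²` and ends at `(S, S)`.  Both curves are then
resampled on a common uniform grid over `[0, max(S₁, S₂)]`, each continued
past its own end at its terminal value `S`, and `D` is the trapezoidal
integral of `|y₁ − y₂|`.  `D` is a pseudometric surrogate: nonnegative,
symmetric, zero on identical curves; no triangle inequality is claimed.
Normalizing *both* axes (rather than x only) is the single most
result-sensitive convention in the package; it is forced by the padding
semantics (padding with `S` is only coherent on the `/z` ordinate scale)
and it reproduces the expected distance magnitudes (10⁻²–10⁻¹) between
model networks and sparse interaction networks.

Graphs whose giant component holds less than 5 % of the vertices no longer
have a curve that represents their significant structure; distances
involving them carry a `flagged` marker rather than raising.

## Search efficiency and the clustering measure Λ

The efficiency of an explored vertex is `children / (graph degree − 1)`
(share of non-parent edges reaching untouched vertices), set to 0 for
degree-≤1 vertices; the root, having no parent edge, uses
`children / degree`.  Profiles are binned means over queue position
(50 bins, 10 runs by default).  Λ is the integral of the absolute
difference between a network's profile and that of its degree-matched
configuration-model counterpart, normalized by the sum of the two profile
integrals — a ratio in `[0, 1]`, ≈ 0.01 for a random regular graph and
≈ 0.33 for a 2-d torus whose triangle-based clustering coefficient is
exactly zero.  The absolute value is used because the profiles cross:
clustered networks explore less efficiently early and more efficiently
late.

## Growth models and the classification experiment

DMC duplicates a uniformly chosen anchor's links, deletes one link of each
duplicate pair with probability `q_del` (choosing the side uniformly), and
connects the duplicate pair with probability `q_con`.  DMR deletes each
inherited link independently with probability `q_del` and adds links from
the new vertex to each existing vertex with probability `q_new/n_existing`
(≈ `q_new` new links per step regardless of size).  LPA attaches `m = 1`
edge per new vertex proportionally to degree.  All three start from a
single-edge seed (the smallest nondegenerate choice, configurable).

Duplication models have a sharp density phase boundary at `q_del = 1/2`:
below it the edge count grows super-linearly (`M ~ t^{2(1−q_del)}`) and the
mean degree diverges with size, which no sparse interaction network
resembles; above it the mean degree converges to the stationary value
`z* = 2q/(2q_del − 1)` (with `q` the model's growth parameter).  Ensemble
instances therefore draw `q_del ~ U(1/2, 1)` and set the growth parameter
from the stationary relation so the expected edge count matches the target
density — the models still dictate the realized `M`, and the vertex count
is matched exactly.  At the high-confidence fly scale (`N = 3279`,
`M ≈ 2728`, `z ≈ 1.66`) this yields DMC ensembles whose giant components
hold ~3–15 % of the vertices and DMR ensembles around 50–65 %, matching
the qualitative picture of the published ensembles.  Keeping both DMC/DMR
parameters free on `U(0,1)²` instead provably collapses the experiment
(half of all draws sit in the densifying phase and the DMR class spans all
other classes; its recovery accuracy drops to ~0).

The classifier assigns a query curve to the class minimizing the median of
its distances to the class ensemble (even counts: mean of the central
pair; ties broken by class order and logged).  Each network contributes a
single BFS run — curves of networks this size are already tightly
concentrated, and one run per instance keeps the experiment at ~800 BFS
runs.  Known residual: with all parameters redrawn per instance, DMR
networks drawn near the pure-duplication corner (`q_new ≈ 0`) are
structurally indistinguishable from DMC networks, and the DMR recovery
rate settles near ~80 % instead of the mid-90s; the other three classes
recover at 97–100 %.  The sampling interval of the original experiment is
not recoverable, so this corner-mass discrepancy is documented rather than
tuned away.

Noise sweeps perturb a target by `noise1` (delete `round(f·M)` uniform
edges, add the same number of uniform non-duplicate, non-loop pairs;
collisions resampled with bounded retries) or `noise2` (degree-preserving
double-edge swaps until `round(f·M)` edges are rewired).  Full `noise1`
turns any target into an Erdős–Rényi graph at the same density, so a
library containing a PoissonRG class at that density absorbs the label;
`noise2` preserves the degree sequence and is tolerated at larger
fractions.

## The synthetic interaction fixture

`make_fixture("ppi-like", ...)` stands in for a confidence-scored
two-hybrid screen: a DMR-grown network at the fly density whose edges get
scores from a mixture (75 % core drawn from `U(0.65, 1)`, 25 % noise from
`U(0, 0.65)`), plus injected duplicate records, self-loop records, and
vertices that appear only in sub-threshold records (isolated after
filtering).  It emulates the *filtering workload* — duplicates, loops,
isolated vertices, a threshold-dependent size — and the broad confidence
mixture of a real screen.  It does **not** emulate protein-specific
features (bait/prey asymmetries, score correlations along hubs, false
negatives), so pipeline tests certify the machinery and the self-recovery
property of the ranking, not biological fidelity.  The quartet fixture
writes four reference families at matched mean degree 6 (regular, Poisson,
lattice-embedded with `d=2, r=2`, and a power-law graph whose exponent is
tuned numerically to hit the target mean).

## Problem sizes used by the test suite

Analytic-agreement runs use one network of `N = 10⁵` per family and seed
(median of 3 seeds); the quartet ordering uses `N = 2·10⁴` over 10 seeds;
the classification experiment uses the full 100 library + 100 test
instances per class at `N = 3279`; rewiring-family validation uses rings of
`N = 10³` over 11 rewiring probabilities × 20 realizations.  These sizes
keep every statistic comfortably inside its tolerance while the whole
suite stays desk-scale.

## Known limitations

* The mean-field curves are exact only in the `N → ∞` limit of
  configuration-model-like ensembles; strongly assortative or clustered
  real networks have no analytic curve here (their empirical curves and
  distances remain well-defined).
* The lattice-embedded exponent polynomial comes from an early-stage
  balance; its agreement with simulation is empirical beyond that regime.
* The traceroute density uses expected tree degrees only; it predicts the
  body slope, not the far tail or the degree-1 mass.
* The distance is not a metric (no triangle inequality) and is flagged,
  not computed meaningfully, for graphs without a giant component.
* Directed and weighted-growth models are out of scope; confidence scores
  are used only for thresholding.
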