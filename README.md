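# netcurve

**Characteristic curves of large networks from breadth-first search —
curve theory, a graph distance, a clustering measure, and model evaluation
for protein-interaction networks.**

## The idea

Run a FIFO breadth-first search on a network of `N` vertices.  Two queues
record the traversal:

* **QueueT** receives every vertex once, when it is first touched.  Plotting
  each vertex at `(own position / N, parent's position / N)` embeds the BFS
  tree in the plane.
* **QueueG** starts with the root's own copy and, whenever a vertex is
  explored, receives one copy per incident edge endpoint — touched or not —
  so the full linking information is preserved.  Each copy is plotted at
  `(own position / N, position of the parent's reference copy / N)`.

For a large network the QueueG cloud concentrates on a nondecreasing curve,
the **characteristic curve**: a single planar fingerprint that carries the
giant-component fraction `S` (its terminal value), the average degree (its
span), the exploration speed (its shape) and the local clustering (through
the search efficiency) all at once.

For configuration-model graphs with degree distribution `P(k)` (pgf
`φ(θ)`, mean degree `z = φ′(1)`) the curve has an exact mean-field form.
With `β(u) = φ⁻¹(1−u)`:

```
θ(u) = φ′(β(u))/z          stub survival probability
T(u) = 1 − φ(θ(u))          touched fraction after exploring a fraction u
G(u) = z − β(u) φ′(β(u))    QueueG length
```

The tree curve is `T⁻¹`; the graph curve is the arc `(G(u), G(T⁻¹(u)))`.
Exploration stops at the smallest positive root of `T(u) = u`, which is
exactly the Molloy–Reed / Newman giant-component equation.  Closed forms:

* random `k`-regular graphs: `f_T(x) = 1 − (1−x)^{1/(k−1)}`,
  `f_G(x) = k f_T(x/k)`;
* Poisson (Erdős–Rényi) graphs: `f_T(x) = −ln(1−x)/z`, with the graph-curve
  inversion through the principal Lambert-W branch;
* lattice-embedded random regular graphs (torus ⊕ r-regular overlay): the
  same one-parameter shape with exponent `γ` the largest real root of
  `(γ+1)(γ−1)^d = r[(γ−1)^d + 2^d]`.

Derived quantities: the **graph distance** `D` (area between two curves
after rescaling both axes of each by its giant component's average degree),
the **clustering measure** `Λ` (normalized area between a network's
search-efficiency profile and that of a degree-matched random counterpart
— nonzero even for triangle-free lattices), the **traceroute density**
(BFS-tree degrees follow `ρ(m) ∝ (m−1)^{−(γ−2)/(γ−1)}`, an apparent power
law on perfectly homogeneous networks), and a **median-distance
classifier** over model classes.

## Worked example

```python
import netcurve as nc

# analytic vs simulated curve of a random 3-regular graph
g = nc.rrg(100_000, 3, seed=0)
m = nc.bfs_map(g, seed=1)
tree, graph = nc.rrg_curves(3)
print(round(nc.curve_deviation(m.graph_x, m.graph_y, graph), 4))
# 0.0035   <- sup deviation of 300,001 QueueG points from the analytic curve

# giant component of a Poisson graph with mean degree 2
print(round(nc.giant_component_size(nc.DegreeDist.poisson(2.0)), 4))
# 0.7968   <- smallest positive root of the curve's terminal equation

# clustering: a periodic 2-d lattice has zero triangles, yet Lambda sees it
print(round(nc.clustering_measure(nc.lattice(2, 40), runs=10, seed=2), 3),
      round(nc.clustering_measure(nc.rrg(1600, 4, seed=3), runs=10, seed=4), 3))
# 0.339 0.02
```

The first number says a single BFS run at `N = 10^5` stays within 0.004 of
the parameter-free analytic curve; the second is the classical giant
component fraction of an Erdős–Rényi graph at `z = 2`; the pair at the end
shows `Λ` separating a clustered lattice from a random graph of identical
degrees even though both have average clustering coefficient ≈ 0.

A command-line interface mirrors the library:

```bash
netcurve generate --model dmr --n 3279 --seed 7 --out g.edgelist
netcurve map --in g.edgelist --seed 1 --curve graph --out curve.tsv
netcurve theory --family poisson --z 4 --out poisson.tsv
netcurve distance --a a.edgelist --b b.edgelist --seed 1 --json d.json
netcurve evaluate --target fly.tsv --pcut 0.65 --models dmc,dmr,lpa \
                  --n 100 --seed 1 --out report/
```

`netcurve evaluate` reads a confidence-scored interaction list (tab-separated
`protein  protein  score`), keeps edges with score ≥ `pcut`, removes
self-loops, duplicate records and isolated vertices, and ranks the
duplication–mutation models (DMC, DMR) and preferential attachment (LPA)
by their median curve distance to the target's giant component.

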