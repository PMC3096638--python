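"""The two-queue BFS mapping of a network into the plane.

A FIFO breadth-first search drives two queues.  *QueueT* receives each vertex
once, when it is first touched; plotting every vertex at
``(own QueueT position / N, parent's QueueT position / N)`` embeds the BFS
tree in the plane.  *QueueG* starts with the root's own copy and, each time a
vertex is explored, receives one copy per incident edge endpoint (touched or
not), so no link is lost; plotting every copy at
``(own QueueG position / N, position of the parent's reference copy / N)``
embeds the whole graph.  The *reference copy* of a vertex is the QueueG copy
through which it was first touched (the root's is its initial copy).

For a large network the QueueG point cloud concentrates on a nondecreasing
curve — the characteristic curve — which is the object the rest of the
package measures, compares and classifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .curves import Curve, step_resample

__all__ = [
    "BFSMapping",
    "EfficiencyProfile",
    "adjacency_arrays",
    "bfs_map",
    "empirical_curve",
    "graph_curve",
    "efficiency_profile",
    "tree_degree_distribution",
    "giant_component",
]


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class BFSMapping:
    """Coordinates and per-vertex records of one BFS run.

    ``tree_x[i] = (i+1)/N`` is the i-th touched vertex's QueueT position and
    ``tree_y[i]`` its parent's position (0 for the root).  ``graph_x/graph_y``
    are the QueueG copies' coordinates, starting with the root copy at
    ``(1/N, 0)``.  ``children[i]`` and ``graph_degree[i]`` record the i-th
    explored vertex's newly-touched-neighbor count and full degree (loops
    count twice).
    """

    tree_x: np.ndarray
    tree_y: np.ndarray
    graph_x: np.ndarray
    graph_y: np.ndarray
    children: np.ndarray
    graph_degree: np.ndarray
    N: int
    root: int
    seed: int | None = None
    order: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def explored_fraction(self) -> float:
        return len(self.tree_x) / self.N

    @property
    def edges_explored(self) -> int:
        """Edges inside the reached component: QueueG holds 2M+1 copies."""
        return (len(self.graph_x) - 1) // 2

    @property
    def z_explored(self) -> float:
        """Average degree of the reached component."""
        return (len(self.graph_x) - 1) / len(self.tree_x)


def adjacency_arrays(g: nx.Graph, n: int | None = None):
    """Flat CSR-style adjacency (neighbor list with multiplicities).

    A self-loop contributes its vertex twice, a parallel edge one entry per
    copy, so ``len(neigh[v]) == degree(v)`` in the multigraph sense.
    Vertices must be labelled 0..n-1.
    """
    if n is None:
        n = g.number_of_nodes()
    rows = np.empty(2 * g.number_of_edges(), dtype=np.int64)
    cols = np.empty_like(rows)
    i = 0
    for u, v in g.edges():
        rows[i], cols[i] = u, v
        rows[i + 1], cols[i + 1] = v, u
        i += 2
    order = np.argsort(rows, kind="stable")
    rows, cols = rows[order], cols[order]
    ptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(ptr[1:], rows, 1)
    return cols, np.cumsum(ptr)


def _pick_root(g: nx.Graph, rng: np.random.Generator) -> int:
    """Default root scheme: one end of a uniformly chosen edge."""
    m = g.number_of_edges()
    if m == 0:
        root = int(rng.integers(g.number_of_nodes()))
        return root
    edges = list(g.edges())
    e = edges[int(rng.integers(m))]
    return int(e[int(rng.integers(2))])


def bfs_map(g: nx.Graph, seed=None, root: int | None = None,
            neighbor_order=None) -> BFSMapping:
    """Run the two-queue BFS and return the planar mapping.

    Parameters
    ----------
    g
        (Multi)Graph with integer labels 0..n-1.
    seed
        Drives both the root choice (one end of a random edge) and the
        uniform shuffle of each explored vertex's neighbors.
    root
        Optional explicit root (overrides the random-edge scheme).
    neighbor_order
        Optional callable ``f(v, neighbors) -> sequence`` replacing the
        uniform shuffle; used to replay a prescribed traversal.
    """
    rng = _rng(seed)
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    adj, ptr = adjacency_arrays(g, n)
    if root is None:
        root = _pick_root(g, rng)
    elif not 0 <= root < n:
        raise ValueError(f"root {root} outside vertex range [0, {n})")

    touched = np.zeros(n, dtype=bool)
    parent_pos = np.zeros(n, dtype=np.int64)
    refcopy = np.zeros(n, dtype=np.int64)
    order: list[int] = [root]
    touched[root] = True
    refcopy[root] = 1

    gq = 1  # QueueG length: the root's own copy enters first
    gx = [1]
    gy = [0]
    children = []
    gdeg = []

    i = 0
    while i < len(order):
        v = order[i]
        i += 1
        vpos = i  # 1-based QueueT position of v
        nbrs = adj[ptr[v]:ptr[v + 1]]
        if neighbor_order is not None:
            nbrs = np.asarray(neighbor_order(v, nbrs.copy()), dtype=np.int64)
        else:
            nbrs = nbrs.copy()
            rng.shuffle(nbrs)
        ref_v = refcopy[v]
        c = 0
        for w in nbrs:
            gq += 1
            gx.append(gq)
            gy.append(ref_v)
            if not touched[w]:
                touched[w] = True
                order.append(w)
                parent_pos[w] = vpos
                refcopy[w] = gq
                c += 1
        children.append(c)
        gdeg.append(len(nbrs))

    order = np.asarray(order, dtype=np.int64)
    return BFSMapping(
        tree_x=np.arange(1, len(order) + 1) / n,
        tree_y=parent_pos[order] / n,
        graph_x=np.asarray(gx) / n,
        graph_y=np.asarray(gy) / n,
        children=np.asarray(children),
        graph_degree=np.asarray(gdeg),
        N=n,
        root=int(root),
        seed=seed if isinstance(seed, int) else None,
    )


def empirical_curve(mapping: BFSMapping, which: str = "graph",
                    grid_size: int = 1000) -> Curve:
    """Resample one run's point cloud onto a uniform x grid (last value)."""
    if which == "graph":
        xs, ys = mapping.graph_x, mapping.graph_y
        z = mapping.z_explored
    elif which == "tree":
        xs, ys = mapping.tree_x, mapping.tree_y
        z = mapping.z_explored
    else:
        raise ValueError("which must be 'tree' or 'graph'")
    if len(xs) == 0:
        raise ValueError("empty mapping")
    grid = np.linspace(0.0, xs[-1], grid_size)
    y = step_resample(xs, ys, grid)
    return Curve(grid, y, S=mapping.explored_fraction, z=z, N=mapping.N,
                 kind=which, provenance="empirical-run",
                 meta={"root": mapping.root})


def giant_component(g: nx.Graph):
    """Largest connected component as an induced subgraph, plus its fraction."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comp = max(nx.connected_components(g), key=len)
    sub = g.subgraph(comp).copy()
    return sub, len(comp) / g.number_of_nodes()


def graph_curve(g: nx.Graph, seed=None, grid_size: int = 1000) -> Curve:
    """Characteristic (graph) curve of a network's giant component.

    The BFS is rooted at one end of a random edge of the giant component, so
    the curve's terminal value is the giant-component fraction S of the whole
    graph; positions stay normalized by the full vertex count.  Vertices may
    carry arbitrary labels.
    """
    rng = _rng(seed)
    n = g.number_of_nodes()
    sub, S = giant_component(g)
    relabel = {v: i for i, v in enumerate(g.nodes())}
    h = nx.relabel_nodes(g, relabel, copy=True)
    gc_nodes = [relabel[v] for v in sub.nodes()]
    edges = list(nx.relabel_nodes(sub, relabel, copy=True).edges())
    if edges:
        e = edges[int(rng.integers(len(edges)))]
        root = int(e[int(rng.integers(2))])
    else:
        root = int(gc_nodes[0])
    mapping = bfs_map(h, seed=rng, root=root)
    return empirical_curve(mapping, "graph", grid_size)


@dataclass
class EfficiencyProfile:
    """Binned expected degrees and search efficiency versus queue position.

    ``d_T`` is the mean BFS-tree degree (children + 1 for the parent link),
    ``d_G`` the mean graph degree, and ``eta`` the mean search efficiency:
    the fraction of a vertex's non-parent edges that reach untouched
    vertices, set to 0 for vertices of graph degree <= 1.
    """

    x: np.ndarray
    d_G: np.ndarray
    d_T: np.ndarray
    eta: np.ndarray
    runs: int
    counts: np.ndarray | None = None


def efficiency_profile(g: nx.Graph, runs: int = 10, grid_size: int = 50,
                       seed=None) -> EfficiencyProfile:
    """Accumulate per-vertex (position, degrees, efficiency) over BFS runs."""
    if runs < 1:
        raise ValueError("runs must be >= 1")
    rng = _rng(seed)
    n = g.number_of_nodes()
    acc = np.zeros((3, grid_size))
    cnt = np.zeros(grid_size)
    for _ in range(runs):
        m = bfs_map(g, seed=rng)
        gd = m.graph_degree.astype(float)
        ch = m.children.astype(float)
        eta = np.where(gd > 1, ch / np.maximum(gd - 1, 1.0), 0.0)
        # the root has no parent link: all its edges can explore
        eta[0] = ch[0] / gd[0] if gd[0] > 0 else 0.0
        d_T = ch + 1.0
        d_T[0] = max(ch[0], 1.0)
        pos = np.arange(1, len(ch) + 1) / n
        b = np.minimum((pos * grid_size).astype(int), grid_size - 1)
        np.add.at(acc[0], b, gd)
        np.add.at(acc[1], b, d_T)
        np.add.at(acc[2], b, eta)
        np.add.at(cnt, b, 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
    x = (np.arange(grid_size) + 0.5) / grid_size
    return EfficiencyProfile(x=x, d_G=mean[0], d_T=mean[1], eta=mean[2],
                             runs=runs, counts=cnt)


def tree_degree_distribution(g: nx.Graph, runs: int = 1, seed=None) -> np.ndarray:
    """Normalized histogram of BFS-tree degrees pooled over runs.

    The tree degree of a non-root vertex is its children count plus one for
    the edge to its parent (the root's is its children count).  This is the
    degree distribution an observer sees under path sampling (traceroute),
    which is heavily biased toward apparent power laws.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    rng = _rng(seed)
    pooled = []
    for _ in range(runs):
        m = bfs_map(g, seed=rng)
        deg = m.children + 1
        deg[0] = max(m.children[0], 1)
        pooled.append(deg)
    deg = np.concatenate(pooled)
    hist = np.bincount(deg)
    return hist / hist.sum()
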