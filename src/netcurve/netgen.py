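"""Network generators: random-graph families, growth models and noise.

Everything the curve machinery is exercised on is generated here:

* configuration-model multigraphs with arbitrary degree sequences (the
  substrate of the analytic theory — self-loops and parallel edges allowed),
* lattice-embedded random regular graphs (a homogeneous small-world-like
  family: a periodic torus superposed with an r-regular random graph),
* Watts–Strogatz rewiring families and plain periodic lattices,
* three protein-interaction growth models — duplication–mutation with
  complementarity (DMC), duplication–mutation with random mutations (DMR)
  and linear preferential attachment (LPA),
* two edge-noise perturbations: uniform replacement (destroys the degree
  distribution) and degree-preserving double-edge-swap rewiring.

All generators take an explicit integer ``seed``; one seed gives one
bit-identical graph.  Graphs are returned as networkx (Multi)Graphs with
integer labels ``0..n-1``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DegreeDist",
    "ModelParams",
    "configuration_model",
    "sample_degrees",
    "rrg",
    "poisson_rg",
    "plrg",
    "lattice",
    "lerrg",
    "ws_ring",
    "dmc",
    "dmr",
    "lpa",
    "noise_replace",
    "noise_rewire",
    "density_matched_params",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _nx_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31))


# ---------------------------------------------------------------------------
# degree distributions
# ---------------------------------------------------------------------------


@dataclass
class DegreeDist:
    """A finite degree distribution P(k), k = 0..k_max.

    Provides the probability generating function phi(theta) = sum P(k) theta^k
    and its derivatives, which drive the whole analytic curve theory.
    """

    pk: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pk, dtype=float)
        if p.ndim != 1 or len(p) == 0:
            raise ValueError("P(k) must be a non-empty 1-d array")
        if np.any(p < 0):
            raise ValueError("P(k) entries must be >= 0")
        tot = p.sum()
        if tot <= 0:
            raise ValueError("P(k) must have positive mass")
        if abs(tot - 1.0) > 1e-8:
            p = p / tot
        self.pk = p

    @property
    def k_max(self) -> int:
        return len(self.pk) - 1

    @property
    def ks(self) -> np.ndarray:
        return np.arange(len(self.pk))

    @property
    def z(self) -> float:
        """Average degree."""
        return float(self.ks @ self.pk)

    def phi(self, theta):
        return np.polynomial.polynomial.polyval(theta, self.pk)

    def dphi(self, theta):
        c = self.pk[1:] * np.arange(1, len(self.pk))
        return np.polynomial.polynomial.polyval(theta, c)

    def ddphi(self, theta):
        if len(self.pk) < 3:
            return np.zeros_like(np.asarray(theta, dtype=float))
        k = np.arange(2, len(self.pk))
        c = self.pk[2:] * k * (k - 1)
        return np.polynomial.polynomial.polyval(theta, c)

    # -- constructors -------------------------------------------------------

    @classmethod
    def point_mass(cls, k: int) -> "DegreeDist":
        p = np.zeros(k + 1)
        p[k] = 1.0
        return cls(p)

    @classmethod
    def poisson(cls, z: float, k_max: int | None = None) -> "DegreeDist":
        from scipy.stats import poisson as _pois

        if z < 0:
            raise ValueError("z must be >= 0")
        if k_max is None:
            k_max = int(max(30, z + 12 * np.sqrt(max(z, 1.0))))
        return cls(_pois.pmf(np.arange(k_max + 1), z))

    @classmethod
    def power_law(cls, tau: float, k_min: int, k_max: int) -> "DegreeDist":
        """P(k) = c k^-tau on [k_min, k_max], c fixed by normalization."""
        if tau <= 1:
            raise ValueError("power-law exponent tau must be > 1")
        if not (1 <= k_min <= k_max):
            raise ValueError("need 1 <= k_min <= k_max")
        p = np.zeros(k_max + 1)
        ks = np.arange(k_min, k_max + 1, dtype=float)
        p[k_min:] = ks**-tau
        return cls(p)

    @classmethod
    def from_sequence(cls, degrees) -> "DegreeDist":
        """Empirical distribution of an observed degree sequence."""
        degrees = np.asarray(degrees, dtype=int)
        return cls(np.bincount(degrees) / len(degrees))


@dataclass
class ModelParams:
    """Generation recipe for one network instance (kept for reproducibility)."""

    model: str
    n: int
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def generate(self) -> nx.Graph:
        model = self.model.lower()
        p, n, seed = self.params, self.n, self.seed
        if model == "dmc":
            return dmc(n, p["q_del"], p["q_con"], seed=seed)
        if model == "dmr":
            return dmr(n, p["q_del"], p["q_new"], seed=seed)
        if model == "lpa":
            return lpa(n, p.get("m", 1), seed=seed)
        if model == "poissonrg":
            return poisson_rg(n, m_edges=p.get("m_edges"), z=p.get("z"), seed=seed)
        if model == "rrg":
            return rrg(n, p["k"], seed=seed)
        if model == "plrg":
            return plrg(n, p["tau"], p.get("k_min", 2), p.get("k_max"), seed=seed)
        if model == "lerrg":
            return lerrg(p["dim"], p["side"], p["r"], seed=seed)
        if model == "ws":
            return ws_ring(n, p["k_half"], p["p"], seed=seed)
        if model == "lattice":
            return lattice(p["dim"], p["side"])
        raise ValueError(f"unknown model {self.model!r}")


# ---------------------------------------------------------------------------
# configuration-model family
# ---------------------------------------------------------------------------


def configuration_model(degrees, seed=None) -> nx.MultiGraph:
    """Uniform stub-matching multigraph with the given degree sequence.

    Every vertex of degree k contributes k half-edge copies; the copies are
    paired uniformly at random.  Self-loops and parallel edges are kept (a
    loop contributes 2 to its vertex's degree).
    """
    degrees = [int(d) for d in degrees]
    if any(d < 0 for d in degrees):
        raise ValueError("degrees must be >= 0")
    if sum(degrees) % 2:
        raise ValueError(
            "degree sequence has odd sum; half-edge copies cannot be paired"
        )
    return nx.configuration_model(degrees, seed=_nx_seed(_rng(seed)))


def sample_degrees(dist: DegreeDist, n: int, seed=None) -> np.ndarray:
    """n i.i.d. draws from P(k); one entry is redrawn if the sum is odd."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    degs = rng.choice(len(dist.pk), size=n, p=dist.pk)
    tries = 0
    while degs.sum() % 2:
        i = int(rng.integers(n))
        degs[i] = rng.choice(len(dist.pk), p=dist.pk)
        tries += 1
        if tries > 1000:
            # all-odd support (e.g. point mass at odd k with odd n)
            degs[i] += 1
            logger.info("odd degree sum unfixable by resampling; bumped one entry")
            break
    if tries:
        logger.info("resampled %d entr%s to make the degree sum even", tries,
                    "y" if tries == 1 else "ies")
    return degs


def rrg(n: int, k: int, seed=None) -> nx.MultiGraph:
    """Random k-regular multigraph (configuration model on a constant sequence)."""
    if (n * k) % 2:
        raise ValueError("n*k must be even for a k-regular graph")
    return configuration_model([k] * n, seed=seed)


def poisson_rg(n: int, m_edges: int | None = None, z: float | None = None,
               seed=None) -> nx.Graph:
    """Erdős–Rényi G(n, m) graph (Poisson degrees in the sparse limit)."""
    if m_edges is None:
        if z is None:
            raise ValueError("give either m_edges or z")
        m_edges = int(round(z * n / 2))
    return nx.gnm_random_graph(n, m_edges, seed=_nx_seed(_rng(seed)))


def plrg(n: int, tau: float, k_min: int = 2, k_max: int | None = None,
         seed=None) -> nx.MultiGraph:
    """Power-law random graph: configuration model on degrees ~ k^-tau."""
    rng = _rng(seed)
    if k_max is None:
        k_max = max(k_min, int(np.sqrt(n)))
    dist = DegreeDist.power_law(tau, k_min, k_max)
    degs = sample_degrees(dist, n, seed=rng)
    return configuration_model(degs, seed=rng)


def lattice(dim: int, side: int) -> nx.Graph:
    """d-dimensional periodic lattice (torus); every vertex has degree 2d."""
    if side < 3:
        raise ValueError("side must be >= 3 for a sensible torus")
    g = nx.grid_graph(dim * [side], periodic=True)
    return nx.convert_node_labels_to_integers(g, ordering="sorted")


def lerrg(dim: int, side: int, r: int, seed=None) -> nx.MultiGraph:
    """Lattice-embedded random regular graph.

    Superposition of a d-dimensional periodic lattice (2d nearest neighbors)
    and an independent r-regular configuration-model graph on the same vertex
    set; every vertex has degree 2d + r counting multiplicities.
    """
    if r < 0:
        raise ValueError("r must be >= 0")
    n = side**dim
    if (r * n) % 2:
        raise ValueError("r * n must be even to pair the long-range half-edges")
    g = nx.MultiGraph(lattice(dim, side))
    if r > 0:
        g.add_edges_from(configuration_model([r] * n, seed=seed).edges())
    return g


def ws_ring(n: int, k_half: int, p: float, seed=None) -> nx.Graph:
    """Watts–Strogatz ring: k_half neighbors per side, each edge rewired w.p. p."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if n <= 2 * k_half:
        raise ValueError("need n > 2*k_half")
    return nx.watts_strogatz_graph(n, 2 * k_half, p, seed=_nx_seed(_rng(seed)))


# ---------------------------------------------------------------------------
# PPI growth models
# ---------------------------------------------------------------------------


def _seed_adjacency(n: int, seed_graph: nx.Graph | None) -> tuple[list[set], int]:
    """Adjacency sets for the seed; default seed is a single edge 0-1."""
    adj = [set() for _ in range(n)]
    if seed_graph is None:
        if n < 2:
            raise ValueError("n must be >= 2")
        adj[0].add(1)
        adj[1].add(0)
        return adj, 2
    n0 = seed_graph.number_of_nodes()
    if n0 == 0 or n0 > n:
        raise ValueError("seed graph must be non-empty and no larger than n")
    relabel = {v: i for i, v in enumerate(seed_graph.nodes())}
    for u, v in seed_graph.edges():
        if u == v:
            continue
        adj[relabel[u]].add(relabel[v])
        adj[relabel[v]].add(relabel[u])
    return adj, n0


def _to_graph(adj: list[set]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(len(adj)))
    g.add_edges_from((u, w) for u in range(len(adj)) for w in adj[u] if u < w)
    return g


def dmc(n: int, q_del: float, q_con: float, seed=None,
        seed_graph: nx.Graph | None = None) -> nx.Graph:
    """Duplication–mutation model preserving functional complementarity.

    Each step adds a duplicate v of a uniformly chosen anchor a, copying all
    of a's links.  For every shared neighbor w, one of the two parallel links
    (v,w)/(a,w) is selected uniformly and deleted with probability q_del —
    if one copy of the gene loses a function, the other keeps it.  The
    duplicate pair v–a itself is connected with probability q_con.
    """
    if not (0 <= q_del <= 1 and 0 <= q_con <= 1):
        raise ValueError("q_del and q_con must be probabilities")
    rng = _rng(seed)
    adj, n0 = _seed_adjacency(n, seed_graph)
    for v in range(n0, n):
        a = int(rng.integers(v))
        nbrs = list(adj[a])
        for w in nbrs:
            adj[v].add(w)
            adj[w].add(v)
        for w in nbrs:
            if rng.random() < q_del:
                if rng.random() < 0.5:
                    adj[v].discard(w)
                    adj[w].discard(v)
                else:
                    adj[a].discard(w)
                    adj[w].discard(a)
        if rng.random() < q_con:
            adj[v].add(a)
            adj[a].add(v)
    return _to_graph(adj)


def dmr(n: int, q_del: float, q_new: float, seed=None,
        seed_graph: nx.Graph | None = None) -> nx.Graph:
    """Duplication–mutation model with random mutations.

    Each step adds a duplicate v of a uniform anchor, deletes each inherited
    link independently with probability q_del, and creates a link from v to
    every other existing vertex independently with probability
    q_new / n_existing (about q_new new random links per step, independent of
    network size).  No duplicate–anchor mechanism.
    """
    if not (0 <= q_del <= 1 and 0 <= q_new <= 1):
        raise ValueError("q_del and q_new must be probabilities")
    rng = _rng(seed)
    adj, n0 = _seed_adjacency(n, seed_graph)
    for v in range(n0, n):
        a = int(rng.integers(v))
        for w in adj[a]:
            if rng.random() >= q_del:
                adj[v].add(w)
                adj[w].add(v)
        n_existing = v
        k = rng.binomial(n_existing, q_new / n_existing) if q_new > 0 else 0
        if k:
            for w in rng.choice(n_existing, size=k, replace=False):
                w = int(w)
                adj[v].add(w)
                adj[w].add(v)
    return _to_graph(adj)


def lpa(n: int, m: int = 1, seed=None,
        seed_graph: nx.Graph | None = None) -> nx.Graph:
    """Linear preferential attachment: m edges per new vertex, ~ degree."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if seed_graph is None:
        seed_graph = nx.Graph([(0, 1)])
    if seed_graph.number_of_nodes() < m or seed_graph.number_of_edges() < 1:
        raise ValueError("seed graph needs >= m vertices and >= 1 edge")
    return nx.barabasi_albert_graph(
        n, m, seed=_nx_seed(_rng(seed)), initial_graph=seed_graph
    )


def density_matched_params(model: str, n: int, m_edges: int, seed=None) -> ModelParams:
    """Draw per-instance growth parameters matched to a target density.

    Duplication models have a phase boundary at q_del = 1/2: below it the
    edge count grows super-linearly (M ~ t^{2(1-q_del)}) and the average
    degree diverges, which no sparse interaction network resembles.  The
    deletion probability is therefore drawn uniformly from the sparse phase
    [1/2, 1), and the growth parameter (q_con for DMC, q_new for DMR) is set
    by the stationary mean-degree relation z* = 2 q / (2 q_del - 1) so that
    the expected edge count matches the target (the models still dictate the
    realized M).  LPA and PoissonRG take their parameters directly from the
    target size.
    """
    rng = _rng(seed)
    z_target = 2 * m_edges / n
    model = model.lower()
    if model in ("dmc", "dmr"):
        q_del = 0.5 + 0.5 * rng.random()
        q = min(1.0, z_target * (2 * q_del - 1) / 2)
        key = "q_con" if model == "dmc" else "q_new"
        return ModelParams(model, n, {"q_del": q_del, key: q},
                           seed=int(rng.integers(2**31)))
    if model == "lpa":
        return ModelParams(model, n, {"m": 1}, seed=int(rng.integers(2**31)))
    if model == "poissonrg":
        return ModelParams(model, n, {"m_edges": m_edges},
                           seed=int(rng.integers(2**31)))
    raise ValueError(f"no density-matched recipe for model {model!r}")


# ---------------------------------------------------------------------------
# noise models
# ---------------------------------------------------------------------------


def noise_replace(g: nx.Graph, fraction: float, seed=None) -> nx.Graph:
    """noise1: replace a fraction of edges by uniform random vertex pairs.

    round(fraction*M) uniformly chosen edges are deleted and the same number
    of uniform random pairs (no loops, no duplicates of surviving edges) are
    added; the edge count is preserved exactly.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = _rng(seed)
    h = nx.Graph(g)
    edges = list(h.edges())
    m = len(edges)
    k = int(round(fraction * m))
    if k == 0:
        return h
    idx = rng.choice(m, size=k, replace=False)
    h.remove_edges_from([edges[i] for i in idx])
    nodes = list(h.nodes())
    added = 0
    tries = 0
    while added < k:
        u, v = rng.choice(len(nodes), size=2, replace=False)
        u, v = nodes[int(u)], nodes[int(v)]
        if not h.has_edge(u, v):
            h.add_edge(u, v)
            added += 1
        else:
            tries += 1
            if tries > 1000 * k:
                raise RuntimeError("could not place replacement edges (graph too dense)")
    return h


def noise_rewire(g: nx.Graph, fraction: float, seed=None) -> nx.Graph:
    """noise2: degree-preserving double-edge swaps until round(fraction*M)
    edges have been rewired (each successful swap rewires two edges)."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    h = nx.Graph(g)
    m = h.number_of_edges()
    if m < 2:
        warnings.warn("fewer than 2 edges; returning the graph unchanged")
        return h
    k = int(round(fraction * m))
    nswap = k // 2 + (k % 2)
    if nswap == 0:
        return h
    nx.double_edge_swap(h, nswap=nswap, max_tries=max(1000, 200 * nswap),
                        seed=_nx_seed(_rng(seed)))
    return h
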