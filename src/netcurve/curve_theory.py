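"""Analytic characteristic curves for random-graph families.

Mean-field theory of the two-queue BFS on a configuration-model graph with
degree distribution P(k).  Everything follows from the stub-survival
transform: let phi(theta) be the probability generating function of P(k) and
z = phi'(1) the mean degree, and write theta(u) for the probability that a
given half-edge is still unmatched after a fraction u of the vertices has
been explored.  A vertex of degree k is then still untouched with
probability theta^k, so the untouched degree distribution is
P(k) theta^k / phi(theta).  Self-consistency of the stub accounting gives a
closed solution in terms of beta(u) = phi^{-1}(1 - u):

    theta(u)   = phi'(beta(u)) / z                (stub survival)
    T(u)       = 1 - phi(theta(u))                (touched fraction, QueueT)
    G(u)       = z - beta(u) phi'(beta(u))        (QueueG length)
    d_G(u)     = 1 + beta phi''(beta)/phi'(beta)  (expected graph degree)

The tree curve is the inverse of T; the graph curve is the parametric arc
(G(u), G(v(u))) where v(u) = T^{-1}(u) is the time the u-th explored vertex
was touched.  Exploration terminates at the smallest positive root of
T(u) = u, which reduces exactly to the Molloy–Reed / Newman
generating-function equation for the giant-component size S.

Closed forms fall out for three families:

* random k-regular graphs:  f_T(x) = 1 - (1-x)^{1/(k-1)},
  f_G(x) = k f_T(x/k);
* Poisson (Erdős–Rényi) graphs: theta(u) = 1-u, T(u) = 1 - e^{-z u}, and
  inverting G requires the principal branch of Lambert's W function;
* lattice-embedded random regular graphs: same one-parameter shape as the
  regular family, with exponent gamma the largest real root of
  (gamma+1)(gamma-1)^d = r [ (gamma-1)^d + 2^d ].

The one-parameter curve family f_T(x) = 1 - (1-x)^{1/gamma} also yields the
tree-degree (traceroute) density by inverting the expected tree degree
d_T(x) = gamma (1-x)^{gamma-1}: a power law with exponent
(gamma-2)/(gamma-1), approaching 1/d for large gamma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import lambertw

from .curves import Curve
from .netgen import DegreeDist

__all__ = [
    "CurveFamilyParams",
    "giant_component_size",
    "exploration_schedule",
    "tree_curve_fn",
    "graph_curve_fn",
    "rrg_curves",
    "poisson_curves",
    "lerrg_exponent",
    "lerrg_curves",
    "family_curves",
    "traceroute_density",
    "powerlaw_slope",
]

_EPS = 1e-12


@dataclass
class CurveFamilyParams:
    """Parameters of the one-parameter curve family f_T = 1 - (1-x)^{1/gamma}.

    ``z`` is the (constant) graph degree of the family member and ``gamma``
    the exploration exponent: gamma = k - 1 for a random k-regular graph,
    and the lattice-embedded root for LERRGs.
    """

    z: float
    gamma: float
    tag: str = "family"

    @classmethod
    def from_rrg(cls, k: int) -> "CurveFamilyParams":
        if k < 3:
            raise ValueError("need k >= 3 (connected regular regime)")
        return cls(z=float(k), gamma=float(k - 1), tag=f"rrg-k{k}")

    @classmethod
    def from_lerrg(cls, d: int, r: int) -> "CurveFamilyParams":
        return cls(z=float(2 * d + r), gamma=lerrg_exponent(d, r),
                   tag=f"lerrg-d{d}-r{r}")


# ---------------------------------------------------------------------------
# giant component
# ---------------------------------------------------------------------------


def _beta_star(dist: DegreeDist) -> float:
    """Smallest fixed point of beta = phi'(beta)/z (edge-following recursion).

    Found by bracketed root finding of f(b) = b - phi'(b)/z, scanning
    brackets upward from 0.  f(0) = -P(1)/z <= 0 and f is eventually
    positive below 1 in the supercritical regime, so the smallest
    sign-change bracket contains the smallest fixed point.  If no bracket
    exists the process is subcritical and beta* = 1 (so S = 0).
    """
    z = dist.z
    if z <= 0:
        return 1.0
    f = lambda b: b - dist.dphi(b) / z
    if dist.dphi(0.0) == 0.0:
        # beta = 0 is itself the smallest fixed point (no degree-1 vertices:
        # following an edge never reaches a dead end)
        return 0.0
    bs = np.linspace(_EPS, 1.0 - 1e-9, 2000)
    vals = f(bs)
    idx = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(idx) == 0:
        return 1.0
    i = idx[0]
    return float(brentq(f, bs[i], bs[i + 1], xtol=1e-14))


def giant_component_size(dist: DegreeDist) -> float:
    """Giant-component fraction S from the curve's terminal equation.

    S is the smallest positive root of T(u) = u.  Writing the terminal
    condition through the transform variable reduces it to the fixed point
    beta* = phi'(beta*)/z, and S = 1 - phi(beta*) — the classical
    Molloy–Reed / Newman result.
    """
    if dist.z <= 0:
        return 0.0
    bstar = _beta_star(dist)
    if bstar >= 1.0 - 1e-9:
        return 0.0
    return float(1.0 - dist.phi(bstar))


# ---------------------------------------------------------------------------
# general P(k) solution
# ---------------------------------------------------------------------------


def exploration_schedule(dist: DegreeDist, ngrid: int = 40000):
    """Parametric solution arrays (u, T(u), G(u)) and the terminal S.

    Parameterized by beta descending from 1 to the fixed point beta*, which
    maps exploration time u = 1 - phi(beta) over [0, S].
    """
    z = dist.z
    if z <= 0:
        raise ValueError("need average degree z > 0")
    bstar = _beta_star(dist)
    S = 0.0 if bstar >= 1.0 - 1e-9 else float(1.0 - dist.phi(bstar))
    # cosine (Chebyshev-like) spacing: the curves are steep where beta
    # approaches its endpoints, so cluster the parametric samples there
    t = 0.5 * (1.0 - np.cos(np.linspace(0.0, np.pi, ngrid)))
    beta = 1.0 - (1.0 - bstar) * t
    phib = dist.phi(beta)
    dphib = dist.dphi(beta)
    u = 1.0 - phib
    theta = dphib / z
    T = 1.0 - dist.phi(theta)
    G = z - beta * dphib
    # enforce exact endpoints against round-off
    u[0] = T[0] = G[0] = 0.0
    return u, T, G, S


def _curves_from_schedule(dist, bstar, S, z_gc, grid_size, tag,
                          ntable: int = 200000):
    """Build tree and graph Curves by inverting phi and phi' directly.

    Everything reduces to two monotone polynomial inversions: with
    beta(x) = phi^{-1}(1-x) the tree curve is

        f_T(x) = 1 - phi( (phi')^{-1}( z * beta(x) ) ),

    and the graph curve, parameterized by x = G = z - b phi'(b), has
    y = z - b2 phi'(b2) with b2 = (phi')^{-1}(z * b).  Inverses are read off
    dense cosine-spaced tables; forward evaluations are exact polynomials,
    which damps the table error where the curves get steep.
    """
    z = dist.z
    t = 0.5 * (1.0 - np.cos(np.linspace(0.0, np.pi, ntable)))
    b = bstar + (1.0 - bstar) * t          # ascending table in beta
    phib = dist.phi(b)
    dphib = dist.dphi(b)

    def inv_phi(q):
        return np.interp(q, phib, b)

    def inv_dphi(q):
        return np.interp(q, dphib, b)

    # tree curve on a uniform x grid over [0, S]
    xt = np.linspace(0.0, S, grid_size)
    beta_x = inv_phi(1.0 - xt)
    bu = inv_dphi(z * beta_x)
    yt = 1.0 - dist.phi(bu)
    yt[0] = 0.0
    tree = Curve(xt, np.minimum(yt, xt), S=S, z=z_gc, kind="tree",
                 provenance="analytic-family", meta={"family": tag})

    # graph curve on a uniform x grid over [0, x_end]
    Gtab = z - b * dphib                   # descending in b
    x_end = float(Gtab[0])
    xg = np.linspace(0.0, x_end, grid_size)
    bx = np.interp(xg, Gtab[::-1], b[::-1])
    b2 = inv_dphi(z * bx)
    yg = z - b2 * dist.dphi(b2)
    yg[0] = 0.0
    graph = Curve(xg, np.minimum(yg, xg), S=S, z=z_gc, kind="graph",
                  provenance="analytic-family", meta={"family": tag})
    return tree, graph


def _general_curves(dist: DegreeDist, grid_size: int):
    if dist.z <= 0:
        raise ValueError("need average degree z > 0")
    bstar = _beta_star(dist)
    S = 0.0 if bstar >= 1.0 - 1e-9 else float(1.0 - dist.phi(bstar))
    if S <= 0:
        raise ValueError("subcritical distribution: no giant component")
    x_end = dist.z - bstar * float(dist.dphi(bstar))
    z_gc = x_end / S  # average degree inside the giant component
    return _curves_from_schedule(dist, bstar, S, z_gc, grid_size, "general-P")


def tree_curve_fn(dist: DegreeDist, grid_size: int = 1000) -> Curve:
    """Analytic BFS-tree curve for an arbitrary degree distribution."""
    return _general_curves(dist, grid_size)[0]


def graph_curve_fn(dist: DegreeDist, grid_size: int = 1000) -> Curve:
    """Analytic BFS-graph (characteristic) curve for arbitrary P(k)."""
    return _general_curves(dist, grid_size)[1]


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------


def family_curves(params: CurveFamilyParams, grid_size: int = 1000):
    """Tree and graph curves of the one-parameter family (S = 1).

    f_T(x) = 1 - (1-x)^{1/gamma} on [0, 1];
    f_G(x) = z f_T(x/z) on [0, z].
    """
    z, gam = params.z, params.gamma
    xt = np.linspace(0.0, 1.0, grid_size)
    yt = 1.0 - (1.0 - np.clip(xt, 0, 1)) ** (1.0 / gam)
    tree = Curve(xt, yt, S=1.0, z=z, kind="tree", provenance="analytic-family",
                 meta={"family": params.tag, "gamma": gam})
    xg = np.linspace(0.0, z, grid_size)
    yg = z * (1.0 - (1.0 - np.clip(xg / z, 0, 1)) ** (1.0 / gam))
    graph = Curve(xg, yg, S=1.0, z=z, kind="graph", provenance="analytic-family",
                  meta={"family": params.tag, "gamma": gam})
    return tree, graph


def rrg_curves(k: int, grid_size: int = 1000):
    """Closed-form curves of the random k-regular graph (k >= 3, S = 1)."""
    return family_curves(CurveFamilyParams.from_rrg(k), grid_size)


def poisson_curves(z: float, grid_size: int = 1000):
    """Closed-form curves of the Poisson (Erdős–Rényi) random graph.

    theta(u) = 1 - u, so T(u) = 1 - e^{-z u} and the tree curve is
    f_T(x) = -ln(1-x)/z on [0, S], with S the smallest positive root of
    S = 1 - e^{-z S}.  The graph curve needs u(x) from
    G(u) = z u - (1-u) ln(1-u), whose inversion is
    u(x) = 1 - (z-x)/W0((z-x) e^z) with the principal Lambert branch (the
    argument stays >= z(1-S)^2 e^z > 0 on the curve's domain, where W0 is
    single-valued).
    """
    if z <= 0:
        raise ValueError("need z > 0")
    if z <= 1:
        raise ValueError("subcritical (z <= 1): no giant component")
    S = float(brentq(lambda s: s - (1.0 - math.exp(-z * s)), 1e-9, 1 - 1e-12))

    def G(u):
        u = np.asarray(u, dtype=float)
        return z * u - (1.0 - u) * np.log1p(-u)

    xt = np.linspace(0.0, S, grid_size)
    yt = -np.log1p(-np.clip(xt, 0.0, 1 - 1e-15)) / z
    tree = Curve(xt, yt, S=S, z=G(S) / S, kind="tree",
                 provenance="analytic-family", meta={"family": f"poisson-z{z}"})

    x_end = float(G(S))
    xg = np.linspace(0.0, x_end, grid_size)
    arg = (z - xg) * np.exp(z)
    w = np.real(lambertw(arg, 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(w > 0, 1.0 - (z - xg) / w, 0.0)
    u = np.clip(u, 0.0, S)
    v = -np.log1p(-u) / z  # touch time of the vertex explored at u
    yg = G(v)
    yg[0] = 0.0
    graph = Curve(xg, yg, S=S, z=x_end / S, kind="graph",
                  provenance="analytic-family", meta={"family": f"poisson-z{z}"})
    return tree, graph


def lerrg_exponent(d: int, r: int) -> float:
    """Exploration exponent of the lattice-embedded random regular graph.

    Largest real root of (g+1)(g-1)^d - r (g-1)^d - r 2^d = 0, obtained from
    the early-search balance between long-range touches (the r-regular
    overlay) and lattice-front touches (shells of the d-dimensional torus
    grow like 2^d j^{d-1}/(d-1)! while the pending queue delays front steps).
    For d = 1 the root is r + 1 = 2d + r - 1, i.e. the curve coincides with
    the random regular graph of the same total degree; for d >= 2 the root
    is smaller — the lattice wastes edges on already-covered neighbors.
    """
    if d < 1 or r < 1:
        raise ValueError("need d >= 1 and r >= 1")
    # (c+1)(c-1)^d - r (c-1)^d - r 2^d, coefficients in c
    cm1 = np.zeros(d + 1)
    for j in range(d + 1):
        cm1[j] = math.comb(d, j) * (-1.0) ** (d - j)
    poly = np.polynomial.polynomial.polymul(cm1, [1.0, 1.0])
    poly[: d + 1] -= r * cm1
    poly[0] -= r * 2.0**d
    roots = np.polynomial.polynomial.polyroots(poly)
    real = roots.real[np.abs(roots.imag) < 1e-9]
    real = real[real > 1.0]
    if len(real) == 0:
        raise ArithmeticError("no real exploration exponent > 1 found")
    return float(real.max())


def lerrg_curves(d: int, r: int, grid_size: int = 1000):
    """Closed-form curves of the lattice-embedded random regular graph."""
    return family_curves(CurveFamilyParams.from_lerrg(d, r), grid_size)


# ---------------------------------------------------------------------------
# traceroute (BFS-tree degree) density
# ---------------------------------------------------------------------------


def traceroute_density(family: CurveFamilyParams, n: int):
    """Tree-degree density implied by the expected-tree-degree function.

    Within the one-parameter family the expected number of children of the
    vertex at position x is d_T(x) = gamma (1-x)^{gamma-1}; counting the
    parent link, the expected tree degree is m(x) = 1 + d_T(x).  Since m(x)
    decreases monotonically, the density of tree degrees is the push-forward
    of the uniform position measure: rho(m) = |dx/dm|, i.e.

        rho(m) ∝ (m-1)^{-(gamma-2)/(gamma-1)},   1 < m <= 1 + gamma,

    an apparent power law with a finite cutoff at 1 + gamma even though the
    underlying network is homogeneous.  The finite size n truncates the
    support below at m(x = 1 - 1/n).

    Returns (m, rho): integer tree degrees 2..floor(1+gamma) and the density
    normalized over that support.
    """
    gam = family.gamma
    if gam <= 2:
        raise ValueError("family exponent must exceed 2 for a power-law body")
    if n < 10:
        raise ValueError("n too small")
    # support: the largest expected tree degree is 1 + gamma (at the root end)
    # and positions are resolved only down to x = 1 - 1/n, below which degrees
    # are indistinguishable from 1; both ends truncate the integer support.
    m_max = int(np.floor(1.0 + gam))
    m = np.arange(2, m_max + 1, dtype=float)
    rho = (m - 1.0) ** (-(gam - 2.0) / (gam - 1.0))
    rho = rho / rho.sum()
    return m.astype(int), rho


def powerlaw_slope(m, p, m_lo: int = 2, m_hi: int | None = None) -> float:
    """Log–log slope of a degree histogram body against log(m - 1)."""
    m = np.asarray(m, dtype=float)
    p = np.asarray(p, dtype=float)
    sel = (m >= m_lo) & (p > 0)
    if m_hi is not None:
        sel &= m <= m_hi
    if sel.sum() < 2:
        raise ValueError("not enough points to fit a slope")
    return float(np.polyfit(np.log(m[sel] - 1.0), np.log(p[sel]), 1)[0])
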