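"""The characteristic-curve container and curve geometry utilities.

A breadth-first search maps a network into a planar point cloud whose points
line up along a nondecreasing curve (the *characteristic curve*).  This module
holds the shared :class:`Curve` container used by both the empirical route
(one BFS run on a concrete graph) and the analytic route (mean-field solutions
for random-graph families), together with the geometric operations every
other module builds on: resampling a point cloud onto a grid, and measuring
how far a cloud strays from a reference curve.

Coordinate conventions
----------------------
Raw coordinates are queue positions divided by the number of vertices ``N``.
A tree curve runs from (0, 0) to (S, S) where ``S`` is the explored (giant
component) fraction; a graph curve runs from (0, 0) to (x_end, x_end) with
``x_end = (2 M_gc + 1) / N``.  Dividing both axes of a graph curve by the
giant component's average degree ``z_gc = 2 M_gc / N_gc`` maps it onto
[0, S] x [0, S]; that normalized form is what the graph distance compares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["Curve", "step_resample", "curve_deviation"]


@dataclass
class Curve:
    """A sampled nondecreasing curve y(x) with endpoints and provenance.

    Parameters
    ----------
    x, y
        Sample points on a (uniform) x grid.  ``y`` is nondecreasing.
    S
        Explored fraction (giant-component fraction of the whole graph); the
        terminal value of the *normalized* curve.
    z
        The average-degree scale used for alignment.  For an empirical graph
        curve this is the average degree of the explored component
        ``2 M_gc / N_gc``; for an analytic curve it is ``x_end / S``.
    N
        Number of vertices of the underlying graph (``None`` for analytic
        curves, which live in the large-N limit).
    kind
        ``"tree"`` or ``"graph"``.
    provenance
        ``"empirical-run"`` or ``"analytic-family"``.
    """

    x: np.ndarray
    y: np.ndarray
    S: float
    z: float
    N: int | None = None
    kind: str = "graph"
    provenance: str = "empirical-run"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same shape")

    @property
    def x_end(self) -> float:
        return float(self.x[-1])

    @property
    def y_end(self) -> float:
        return float(self.y[-1])

    def normalized(self) -> "Curve":
        """Rescale both axes by the average-degree scale ``z``.

        The normalized graph curve runs from (0, 0) to roughly (S, S) and is
        the object the graph distance operates on.  Tree curves are already
        on the [0, S] scale and are returned unchanged.
        """
        if self.kind == "tree":
            return self
        return Curve(
            self.x / self.z,
            self.y / self.z,
            S=self.S,
            z=1.0,
            N=self.N,
            kind=self.kind,
            provenance=self.provenance,
            meta=dict(self.meta, normalized=True),
        )

    def __call__(self, xq: np.ndarray) -> np.ndarray:
        """Evaluate on new abscissae (linear between samples, clamped ends).

        The curve's own samples were built from the raw point cloud by
        last-value steps; once on a dense uniform grid, linear interpolation
        between samples is the right evaluator (step evaluation would add a
        grid-resolution bias wherever the curve is steep).
        """
        xq = np.asarray(xq, dtype=float)
        return np.interp(xq, self.x, self.y, left=0.0, right=self.y[-1])


def step_resample(xs: np.ndarray, ys: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Resample a nondecreasing point sequence onto ``grid`` by last value.

    Grid points before the first sample get 0, points after the last sample
    get the terminal value.  This is the natural interpolation for queue data,
    which is a nondecreasing step function of the queue position.
    """
    idx = np.searchsorted(xs, grid, side="right") - 1
    out = np.where(idx >= 0, ys[np.clip(idx, 0, len(ys) - 1)], 0.0)
    return out


def _densify(x: np.ndarray, y: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline uniformly in (|dx|+|dy|) arc parameter."""
    s = np.concatenate([[0.0], np.cumsum(np.abs(np.diff(x)) + np.abs(np.diff(y)))])
    if s[-1] == 0:
        return np.column_stack([x, y])
    s /= s[-1]
    t = np.linspace(0.0, 1.0, n)
    return np.column_stack([np.interp(t, s, x), np.interp(t, s, y)])


def curve_deviation(
    points_x: np.ndarray,
    points_y: np.ndarray,
    reference: Curve,
    n_dense: int = 8000,
    max_points: int = 20000,
) -> float:
    """Sup deviation of a point cloud from a reference curve.

    Returns the largest Euclidean distance from any cloud point to the
    reference polyline.  The deviation is measured point-to-curve rather than
    vertically because characteristic curves end with unbounded slope, where a
    vertical comparison is dominated by the O(N^{-1/gamma}) placement noise of
    the last few vertices instead of by actual disagreement in shape.
    """
    ref = _densify(reference.x, reference.y, n_dense)
    tree = cKDTree(ref)
    px = np.asarray(points_x, dtype=float)
    py = np.asarray(points_y, dtype=float)
    if len(px) > max_points:
        sel = np.unique(np.linspace(0, len(px) - 1, max_points).astype(int))
        px, py = px[sel], py[sel]
    d, _ = tree.query(np.column_stack([px, py]))
    return float(d.max())
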