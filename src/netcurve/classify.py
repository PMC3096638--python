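"""Median-distance network classification over model classes.

A class library holds, for each model class, an ensemble of characteristic
curves of networks generated from that class.  A query network is classified
to the class whose *median* curve distance to the query is smallest — the
median splits the class into a closer and a farther half, which makes the
rule robust to the heavy tails that per-instance parameter draws induce.

The canonical experiment builds four classes (DMC, DMR, LPA, PoissonRG) at
the size of a confidence-filtered protein-interaction network, classifies
fresh instances of each class, and tabulates the accuracy matrix; the noise
sweep perturbs a target network with edge replacement (noise1) or
degree-preserving rewiring (noise2) and tracks how the predicted label
degrades.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .bfsmap import graph_curve
from .compare import curve_distance
from .curves import Curve
from .netgen import density_matched_params, noise_replace, noise_rewire

__all__ = [
    "ClassLibrary",
    "AccuracyMatrix",
    "median_distance",
    "classify",
    "build_library",
    "save_library",
    "load_library",
    "accuracy_matrix",
    "noise_robustness",
    "DEFAULT_MODELS",
]

DEFAULT_MODELS = ("DMC", "DMR", "LPA", "PoissonRG")


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class ClassLibrary:
    """Named classes, each holding an ensemble of graph curves."""

    classes: dict[str, list[Curve]]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        for label, curves in self.classes.items():
            if not curves:
                raise ValueError(f"class {label!r} is empty")

    @property
    def labels(self) -> list[str]:
        return list(self.classes)


@dataclass
class AccuracyMatrix:
    """Row-stochastic table of classification percentages (rows = true)."""

    table: pd.DataFrame   # percentages
    counts: pd.DataFrame  # raw counts

    def diagonal(self) -> dict[str, float]:
        return {m: float(self.table.loc[m, m]) for m in self.table.index}


def median_distance(curve: Curve, class_curves: list[Curve]) -> float:
    """Median of the curve distances to an ensemble (even count: central mean)."""
    if not class_curves:
        raise ValueError("class is empty")
    d = [curve_distance(curve, c) for c in class_curves]
    return float(np.median(d))


def classify(curve: Curve, library: ClassLibrary) -> str:
    """Label of the class with the minimal median distance to the curve."""
    meds = {lab: median_distance(curve, cs) for lab, cs in library.classes.items()}
    best = min(meds.values())
    winners = [lab for lab, m in meds.items() if m == best]
    if len(winners) > 1:
        import logging

        logging.getLogger(__name__).info("median-distance tie between %s", winners)
    return winners[0]


def _generate_instance(model: str, n: int, m_edges: int,
                       rng: np.random.Generator) -> nx.Graph:
    params = density_matched_params(model, n, m_edges, seed=rng)
    return params.generate()


def build_library(models=DEFAULT_MODELS, n_library: int = 100,
                  n: int = 3279, m_edges: int = 2728, seed=None,
                  grid_size: int = 1000) -> ClassLibrary:
    """Generate per-class ensembles and map each instance to one graph curve.

    Model parameters are redrawn per instance (DMC/DMR deletion probability
    uniform in the sparse phase, growth parameter matched to the target
    density — see :func:`netcurve.netgen.density_matched_params`).
    """
    rng = _rng(seed)
    classes: dict[str, list[Curve]] = {}
    for model in models:
        curves = []
        for _ in range(n_library):
            g = _generate_instance(model, n, m_edges, rng)
            curves.append(graph_curve(g, seed=rng, grid_size=grid_size))
        classes[model] = curves
    return ClassLibrary(classes, meta={"n": n, "m_edges": m_edges,
                                       "n_library": n_library})


def save_library(library: ClassLibrary, path) -> None:
    """Serialize a class library (curves on their grids) to JSON."""
    import json

    payload = {"meta": library.meta, "classes": {}}
    for label, curves in library.classes.items():
        payload["classes"][label] = [
            {"x": c.x.tolist(), "y": c.y.tolist(), "S": c.S, "z": c.z,
             "N": c.N} for c in curves]
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_library(path) -> ClassLibrary:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    classes = {
        label: [Curve(np.asarray(c["x"]), np.asarray(c["y"]), S=c["S"],
                      z=c["z"], N=c.get("N"), kind="graph")
                for c in curves]
        for label, curves in payload["classes"].items()
    }
    return ClassLibrary(classes, meta=payload.get("meta", {}))


def accuracy_matrix(models=DEFAULT_MODELS, n_library: int = 100,
                    n_test: int = 100, n: int = 3279, m_edges: int = 2728,
                    seed=None, library: ClassLibrary | None = None,
                    grid_size: int = 1000) -> AccuracyMatrix:
    """Classification accuracy table: generate, classify, tabulate.

    Fresh test instances (with freshly drawn parameters) are generated per
    class and classified against the library; entry (i, j) is the percentage
    of class-i networks labelled j.  Rows sum to 100.
    """
    if n_library < 1 or n_test < 1:
        raise ValueError("n_library and n_test must be >= 1")
    rng = _rng(seed)
    if library is None:
        library = build_library(models, n_library, n, m_edges, seed=rng,
                                grid_size=grid_size)
    labels = list(models)
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for model in labels:
        for _ in range(n_test):
            g = _generate_instance(model, n, m_edges, rng)
            c = graph_curve(g, seed=rng, grid_size=grid_size)
            counts.loc[model, classify(c, library)] += 1
    table = 100.0 * counts.div(counts.sum(axis=1), axis=0)
    return AccuracyMatrix(table=table, counts=counts)


def noise_robustness(g: nx.Graph, library: ClassLibrary, noise: str,
                     fractions, reps: int = 5, seed=None,
                     grid_size: int = 1000) -> pd.DataFrame:
    """Label frequencies of a perturbed network per noise fraction.

    ``noise`` is ``"replace"`` (noise1: uniform edge replacement) or
    ``"rewire"`` (noise2: degree-preserving double-edge swaps).  For each
    fraction, ``reps`` independent perturbations are mapped and classified;
    the returned frame holds the label frequency per fraction.
    """
    if noise not in ("replace", "rewire"):
        raise ValueError("noise must be 'replace' or 'rewire'")
    rng = _rng(seed)
    perturb = noise_replace if noise == "replace" else noise_rewire
    rows = {}
    for f in fractions:
        if not 0 <= f <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        freq = {lab: 0 for lab in library.labels}
        for _ in range(reps):
            h = perturb(g, f, seed=int(rng.integers(2**31)))
            c = graph_curve(h, seed=rng, grid_size=grid_size)
            freq[classify(c, library)] += 1
        rows[f] = {lab: cnt / reps for lab, cnt in freq.items()}
    return pd.DataFrame(rows).T
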