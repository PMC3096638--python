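"""Readers and writers for plain edge lists, GraphML and curve tables."""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np

from .curves import Curve

__all__ = ["write_edgelist", "read_edgelist", "read_graph", "write_graph",
           "write_curve_tsv", "read_curve_tsv"]


def write_edgelist(g: nx.Graph, path) -> None:
    """Two whitespace-separated integer columns, one line per edge copy."""
    with open(path, "w") as fh:
        for u, v in g.edges():
            fh.write(f"{u}\t{v}\n")


def write_graph(g: nx.Graph, path) -> None:
    """Dispatch on extension: .graphml via networkx, else plain edge list."""
    if Path(path).suffix == ".graphml":
        nx.write_graphml(g, path)
    else:
        write_edgelist(g, path)


def read_edgelist(path, multigraph: bool = True) -> nx.Graph:
    """Plain edge list (two columns) as a (Multi)Graph with int labels."""
    g = nx.MultiGraph() if multigraph else nx.Graph()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected two columns")
            g.add_edge(int(parts[0]), int(parts[1]))
    g.add_nodes_from(range(max(g.nodes, default=-1) + 1))
    return g


def read_graph(path) -> nx.Graph:
    """Dispatch on extension: .graphml via networkx, anything else edge list."""
    path = Path(path)
    if path.suffix == ".graphml":
        g = nx.read_graphml(path)
        return nx.convert_node_labels_to_integers(g)
    return read_edgelist(path)


def write_curve_tsv(curve: Curve, path) -> None:
    np.savetxt(path, np.column_stack([curve.x, curve.y]), delimiter="\t",
               header="x\ty", comments="")


def read_curve_tsv(path, **kwargs) -> Curve:
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    S = kwargs.pop("S", float(data[-1, 1]))
    z = kwargs.pop("z", 1.0)
    return Curve(data[:, 0], data[:, 1], S=S, z=z, **kwargs)
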