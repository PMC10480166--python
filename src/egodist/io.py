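"""File formats and toy-graph fixtures.

Graphs travel as plain-text edge lists (one edge per line, two
whitespace-separated node labels, ``#`` comments). Node identifiers are
opaque strings; feature vectors are indexed by sorted node order. Isolated
nodes cannot be expressed by an edge list alone, so the reader accepts a
sidecar node list or an explicit node count.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .distances import DistanceMatrix, DistanceSpec
from .features import FeatureSet

logger = logging.getLogger("egodist")

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "fixtures",
    "FIXTURE_NAMES",
    "write_features",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_distribution",
]


def read_edge_list(path, nodes_path=None, n_nodes: int | None = None) -> nx.Graph:
    """Read a simple undirected graph from a whitespace-separated edge list.

    Self-loops and duplicate edges are dropped with a warning (the ego
    features are defined on simple graphs only). Isolated nodes can be
    supplied through ``nodes_path`` (one label per line) or ``n_nodes``
    (labels assumed to be 0..n-1).
    """
    g = nx.Graph()
    dropped_loops = dropped_dups = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two tokens, got {len(parts)}: {line!r}")
            u, v = parts
            if u == v:
                dropped_loops += 1
                continue
            if g.has_edge(u, v):
                dropped_dups += 1
                continue
            g.add_edge(u, v)
    if dropped_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, dropped_loops)
    if dropped_dups:
        logger.warning("%s: dropped %d duplicate edge(s)", path, dropped_dups)
    if nodes_path is not None:
        with open(nodes_path) as fh:
            for line in fh:
                label = line.strip()
                if label and not label.startswith("#"):
                    g.add_node(label)
    if n_nodes is not None:
        for i in range(n_nodes):
            g.add_node(str(i))
    return g


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted((sorted((str(u), str(v))) for u, v in graph.edges)):
            fh.write(f"{u} {v}\n")


FIXTURE_NAMES = ("triangle", "path3", "star4", "cycle4", "paw", "k4", "isolated")


def fixtures(name: str) -> nx.Graph:
    """Named toy graphs used across examples and tests."""
    if name == "triangle":
        return nx.cycle_graph(3)
    if name == "path3":
        return nx.path_graph(3)
    if name == "star4":
        return nx.star_graph(3)  # center + 3 leaves
    if name == "cycle4":
        return nx.cycle_graph(4)
    if name == "paw":
        g = nx.cycle_graph(3)
        g.add_edge(0, 3)
        return g
    if name == "k4":
        return nx.complete_graph(4)
    if name == "isolated":
        g = nx.Graph()
        g.add_node(0)
        return g
    raise ValueError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")


def write_features(features: FeatureSet, path) -> None:
    """Per-node feature table: TSV with node, degree, d, c, p."""
    pd.DataFrame(
        {
            "node": list(features.nodes),
            "degree": features.degrees,
            "d": features.d,
            "c": features.c,
            "p": features.p,
        }
    ).to_csv(path, sep="\t", index=False)


def write_distance_matrix(dmat: DistanceMatrix, path) -> None:
    pd.DataFrame(dmat.values, index=list(dmat.labels), columns=list(dmat.labels)).to_csv(path)


def read_distance_matrix(path, spec: DistanceSpec | None = None) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    if spec is None:
        spec = DistanceSpec("dcp")
    return DistanceMatrix(labels=tuple(df.index.astype(str)), values=df.to_numpy(), spec=spec)


def write_distribution(dist, path) -> None:
    """Bin-indexed TSV export of a distribution's pdf/cdf for plotting."""
    grid = dist.pdf if dist.pdf is not None else dist.cdf
    idx = np.indices(grid.shape).reshape(dist.dims, -1).T + 1  # 1-based bins
    cols = {f"bin_{a}": idx[:, k] for k, a in enumerate(dist.axes)}
    if dist.pdf is not None:
        cols["pdf"] = dist.pdf.ravel()
    if dist.cdf is not None:
        cols["cdf"] = dist.cdf.ravel()
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def ensure_parent(path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
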