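"""Per-node egonet features: normalized degree, clustering, persistence.

The egonet of node ``i`` is the induced subgraph on ``E_i = {i} ∪ N(i)``.
Three scalar features in [0, 1] summarize each egonet:

* **normalized degree** ``d_i = (m_i - m_min) / (m_max - m_min)``,
* **clustering coefficient** ``c_i = 2 e_i / (m_i (m_i - 1))``, where
  ``e_i`` is the number of edges among the neighbors of ``i``,
* **egonet persistence** ``p_i``, the probability that a degree-proportional
  random walker currently in ``E_i`` is still in ``E_i`` after one step.

For an undirected, unweighted graph the persistence reduces to the ratio of
the internal-degree mass to the total-degree mass of the egonet,

    p_i = Σ_{j∈E_i} m_j^int / Σ_{j∈E_i} m_j .

Since every edge among two neighbors of ``i`` closes a triangle through
``i``, the internal edge count of ``E_i`` is ``e_i + m_i`` (neighbor-neighbor
edges plus the spokes), giving the vectorizable form

    p_i = 2 (t_i + m_i) / (m_i + Σ_{j∈N(i)} m_j),

with ``t_i = e_i`` the number of triangles through ``i``. Isolated nodes
take the value 0 for all three features by convention, and so does ``c_i``
for degree-1 nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "FeatureSet",
    "normalized_degrees",
    "clustering_coefficients",
    "egonet_persistence",
    "global_clustering",
    "compute_features",
]


@dataclass(frozen=True)
class FeatureSet:
    """The three egonet feature vectors of one graph, plus degree metadata.

    Vectors are indexed by the sorted node order of the source graph
    (``sorted(G.nodes, key=str)``).
    """

    nodes: tuple
    degrees: np.ndarray
    d: np.ndarray
    c: np.ndarray
    p: np.ndarray
    C: float
    m_min: int = field(default=0)
    m_max: int = field(default=0)

    def vector(self, axis: str) -> np.ndarray:
        """Return the feature vector named 'd', 'c' or 'p'."""
        try:
            return {"d": self.d, "c": self.c, "p": self.p}[axis]
        except KeyError:
            raise ValueError(f"unknown feature axis {axis!r}") from None


def _sorted_nodes(graph: nx.Graph) -> list:
    return sorted(graph.nodes, key=str)


def _require_nonempty(graph: nx.Graph) -> None:
    if graph.number_of_nodes() == 0:
        raise ValueError("graph has no nodes")


def _adjacency(graph: nx.Graph, nodelist: list) -> sp.csr_array:
    return nx.to_scipy_sparse_array(graph, nodelist=nodelist, format="csr", dtype=np.float64)


def normalized_degrees(graph: nx.Graph) -> np.ndarray:
    """Degrees rescaled to [0, 1] by the graph's degree extremes.

    Regular graphs (``m_min == m_max``) leave the rescaling undefined; the
    convention here is an all-zero vector, mirroring the zero conventions
    for isolated nodes, and a warning is emitted.
    """
    _require_nonempty(graph)
    nodes = _sorted_nodes(graph)
    m = np.array([graph.degree(v) for v in nodes], dtype=np.int64)
    m_min, m_max = int(m.min()), int(m.max())
    if m_min == m_max:
        warnings.warn(
            "regular graph: normalized degree is undefined; returning zeros",
            stacklevel=2,
        )
        return np.zeros(len(nodes))
    return (m - m_min) / (m_max - m_min)


def _triangle_counts(A: sp.csr_array) -> np.ndarray:
    # t_i = (A ∘ A²)_i· summed / 2: each closed wedge i-j-k-i counted twice
    AA = A @ A
    return np.asarray(A.multiply(AA).sum(axis=1)).ravel() / 2.0


def clustering_coefficients(graph: nx.Graph) -> np.ndarray:
    """Local clustering coefficient per node; 0 for nodes of degree <= 1."""
    _require_nonempty(graph)
    nodes = _sorted_nodes(graph)
    A = _adjacency(graph, nodes)
    m = np.asarray(A.sum(axis=1)).ravel()
    t = _triangle_counts(A)
    c = np.zeros(len(nodes))
    mask = m > 1
    c[mask] = 2.0 * t[mask] / (m[mask] * (m[mask] - 1.0))
    return c


def egonet_persistence(graph: nx.Graph) -> np.ndarray:
    """One-step stay probability of a degree-proportional walker in each egonet.

    Equals internal-degree mass over total-degree mass of ``E_i``; 0 for
    isolated nodes by convention.
    """
    _require_nonempty(graph)
    nodes = _sorted_nodes(graph)
    A = _adjacency(graph, nodes)
    m = np.asarray(A.sum(axis=1)).ravel()
    t = _triangle_counts(A)
    neigh_deg_sum = A @ m
    p = np.zeros(len(nodes))
    mask = m > 0
    p[mask] = 2.0 * (t[mask] + m[mask]) / (m[mask] + neigh_deg_sum[mask])
    return p


def global_clustering(graph: nx.Graph) -> float:
    """Mean of the local clustering coefficients over all nodes."""
    return float(clustering_coefficients(graph).mean())


def compute_features(graph: nx.Graph) -> FeatureSet:
    """Compute all three feature vectors and the global clustering at once.

    Shares the sparse adjacency and triangle counts across features, which
    matters when scanning large graph collections.
    """
    _require_nonempty(graph)
    nodes = _sorted_nodes(graph)
    A = _adjacency(graph, nodes)
    m = np.asarray(A.sum(axis=1)).ravel().astype(np.int64)
    m_min, m_max = int(m.min()), int(m.max())
    if m_min == m_max:
        warnings.warn(
            "regular graph: normalized degree is undefined; returning zeros",
            stacklevel=2,
        )
        d = np.zeros(len(nodes))
    else:
        d = (m - m_min) / (m_max - m_min)
    t = _triangle_counts(A)
    c = np.zeros(len(nodes))
    mask = m > 1
    c[mask] = 2.0 * t[mask] / (m[mask] * (m[mask] - 1.0))
    neigh_deg_sum = A @ m.astype(np.float64)
    p = np.zeros(len(nodes))
    nz = m > 0
    p[nz] = 2.0 * (t[nz] + m[nz]) / (m[nz] + neigh_deg_sum[nz])
    return FeatureSet(
        nodes=tuple(nodes),
        degrees=m,
        d=d,
        c=c,
        p=p,
        C=float(c.mean()),
        m_min=m_min,
        m_max=m_max,
    )
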