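"""Ego-distances between graphs: Euclidean norms of cdf differences.

Eight metrics are available, named by the egonet features they combine:
``d``, ``c``, ``p`` (1-D cdf distances), ``sum`` (their sum), ``cp``, ``dc``,
``dp`` (2-D joint cdfs), and ``dcp`` (3-D joint cdf), plus the scalar
baseline ``Cglobal`` = |C' - C''| on the global clustering coefficients.
All cdfs entering one distance share the bin width Δ and cap value T, so
graphs of different size remain comparable. Distances are plain root-sums
of squared cdf differences — they are NOT normalized by the number of bins,
so values computed at different Δ are not mutually comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .distributions import Distribution, cumulative, joint_histogram, truncate
from .features import FeatureSet, compute_features

__all__ = [
    "DistanceSpec",
    "DistanceMatrix",
    "METRIC_AXES",
    "cdf_distance",
    "ego_distance",
    "error_profile",
    "graph_cdf",
    "pairwise_distance_matrix",
]

#: feature axes used by each cdf-based metric name
METRIC_AXES: dict[str, tuple[str, ...]] = {
    "d": ("d",),
    "c": ("c",),
    "p": ("p",),
    "cp": ("c", "p"),
    "dc": ("d", "c"),
    "dp": ("d", "p"),
    "dcp": ("d", "c", "p"),
}

METRIC_NAMES = tuple(METRIC_AXES) + ("sum", "Cglobal")

# above this many float64 cdf entries the pairwise engine switches to a
# float32 cdf store with blocked float64 distance accumulation
_DENSE_LIMIT = 2 * 10**8
_BLOCK = 8


@dataclass(frozen=True)
class DistanceSpec:
    """Which ego-distance to compute, and with what discretization.

    ``weights`` only affects the ``sum`` metric, which is the weighted sum
    of the three 1-D distances (default: plain unweighted sum).
    """

    name: str
    delta: float = 0.01
    cap: float = 1.0
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.name not in METRIC_NAMES:
            raise ValueError(f"unknown metric {self.name!r}; expected one of {METRIC_NAMES}")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise ego-distance matrix over a labeled graph collection."""

    labels: tuple[str, ...]
    values: np.ndarray
    spec: DistanceSpec

    def condensed(self) -> np.ndarray:
        """Upper-triangle pair distances in scipy's condensed order."""
        return squareform(self.values, checks=False)


def graph_cdf(features: FeatureSet, axes: tuple[str, ...], delta: float, cap: float) -> Distribution:
    """Truncated joint cdf of the named feature axes of one graph."""
    vectors = [features.vector(a) for a in axes]
    return truncate(cumulative(joint_histogram(vectors, delta, axes=axes)), cap)


def _check_compatible(q1: Distribution, q2: Distribution) -> None:
    if q1.cdf is None or q2.cdf is None:
        raise ValueError("both distributions need a cdf")
    if q1.cdf.shape != q2.cdf.shape or q1.delta != q2.delta or q1.cap != q2.cap:
        raise ValueError(
            "cdf grids are incompatible: shapes "
            f"{q1.cdf.shape}/{q2.cdf.shape}, delta {q1.delta}/{q2.delta}, "
            f"cap {q1.cap}/{q2.cap}"
        )


def cdf_distance(q1: Distribution, q2: Distribution) -> float:
    """Euclidean (Frobenius) norm of the entrywise cdf difference."""
    _check_compatible(q1, q2)
    return float(np.sqrt(((q1.cdf - q2.cdf) ** 2).sum()))


def error_profile(q1: Distribution, q2: Distribution) -> np.ndarray:
    """Per-bin squared cdf differences (the unaggregated distance terms).

    Useful for diagnosing where along the feature range two graphs actually
    differ, e.g. to choose a cap value; the profile sums to the squared
    cdf distance.
    """
    _check_compatible(q1, q2)
    return (q1.cdf - q2.cdf) ** 2


def _features_of(g) -> FeatureSet:
    if isinstance(g, FeatureSet):
        return g
    if hasattr(g, "graph") and isinstance(g.graph, nx.Graph):  # GeneratedGraph
        g = g.graph
    return compute_features(g)


def ego_distance(g1, g2, spec: DistanceSpec) -> float:
    """Ego-distance between two graphs (or precomputed FeatureSets)."""
    f1, f2 = _features_of(g1), _features_of(g2)
    if spec.name == "Cglobal":
        return abs(f1.C - f2.C)
    if spec.name == "sum":
        return float(
            sum(
                w * cdf_distance(graph_cdf(f1, (a,), spec.delta, spec.cap),
                                 graph_cdf(f2, (a,), spec.delta, spec.cap))
                for w, a in zip(spec.weights, ("d", "c", "p"))
            )
        )
    axes = METRIC_AXES[spec.name]
    return cdf_distance(graph_cdf(f1, axes, spec.delta, spec.cap),
                        graph_cdf(f2, axes, spec.delta, spec.cap))


def _stacked_pdist(features: list[FeatureSet], axes: tuple[str, ...], delta: float, cap: float) -> np.ndarray:
    """Condensed pairwise Euclidean distances between flattened graph cdfs.

    cdfs are computed once per graph. When the dense float64 stack would be
    large (3-D grids over big collections) the stack is held in float32 and
    distances are accumulated blockwise in float64, keeping peak memory
    proportional to the collection size, not the number of pairs.
    """
    n = len(features)
    probe = graph_cdf(features[0], axes, delta, cap).cdf
    n_bins = probe.size
    big = n * n_bins > _DENSE_LIMIT
    stack = np.empty((n, n_bins), dtype=np.float32 if big else np.float64)
    stack[0] = probe.ravel()
    for i in range(1, n):
        stack[i] = graph_cdf(features[i], axes, delta, cap).cdf.ravel()
    if not big:
        return pdist(stack, metric="euclidean")
    out = np.empty(n * (n - 1) // 2)
    pos = 0
    for i0 in range(0, n, _BLOCK):
        a = stack[i0 : i0 + _BLOCK].astype(np.float64)
        for i in range(a.shape[0]):
            row = a[i]
            for j0 in range(i0 + i + 1, n, _BLOCK):
                b = stack[j0 : j0 + _BLOCK].astype(np.float64)
                d = np.sqrt(((b - row) ** 2).sum(axis=1))
                out[pos : pos + d.size] = d
                pos += d.size
    return out


def pairwise_distance_matrix(graphs, spec: DistanceSpec, labels=None) -> DistanceMatrix:
    """Ego-distance matrix over a collection of graphs.

    Features and cdfs are computed once per graph and reused across pairs.
    ``graphs`` may be networkx graphs or precomputed :class:`FeatureSet`s.
    """
    if len(graphs) < 2:
        raise ValueError("need at least two graphs")
    if labels is None:
        labels = tuple(f"G{i}" for i in range(len(graphs)))
    feats = [_features_of(g) for g in graphs]
    if spec.name == "Cglobal":
        cvals = np.array([[f.C] for f in feats])
        condensed = pdist(cvals, metric="euclidean")
    elif spec.name == "sum":
        condensed = sum(
            w * _stacked_pdist(feats, (a,), spec.delta, spec.cap)
            for w, a in zip(spec.weights, ("d", "c", "p"))
        )
    else:
        condensed = _stacked_pdist(feats, METRIC_AXES[spec.name], spec.delta, spec.cap)
    return DistanceMatrix(labels=tuple(labels), values=squareform(condensed), spec=spec)
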