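"""Synthetic network models for benchmarking ego-distances.

Seven randomized models, each parameterized by size ``N`` and density
``rho`` (so mean degree ``rho * (N - 1)``):

* **ER** — Erdős–Rényi: every pair edged independently with probability rho.
* **SFBA** — Barabási–Albert preferential attachment seeded with a clique of
  ``eta + 1`` nodes, ``eta = rho * N / 2`` edges per added node.
* **ERDD** — an SFBA graph randomized by degree-preserving double-edge swaps.
* **STICKY** — stickiness model: edges drawn independently with probability
  ``m_i * m_j / sum(m)`` from an SFBA degree sequence.
* **SFGD** — duplication-divergence growth (a standard protein-interaction
  model): a new node copies a random node's neighborhood, then each shared
  neighbor loses one of its two edges with probability ``q``.
* **GEO** — random geometric graph on uniform points in the unit cube,
  edges strictly below radius ``r``.
* **GEOGD** — geometric graph with duplication-style growth: each new point
  lands uniformly within distance ``2r`` of a random existing point.

SFGD, GEO and GEOGD have a free parameter (``q`` or ``r``) that is
calibrated by bisection so that the mean realized density over a batch of
replicas matches the target rho. Calibration and generation share the same
per-replica child seeds, so the calibrated batch is the reproducible output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "GeneratedGraph",
    "CalibrationError",
    "generate",
    "generate_grid",
    "calibrate_density",
]

MODEL_NAMES = ("ER", "ERDD", "SFBA", "SFGD", "GEO", "GEOGD", "STICKY")

_CALIBRATED = {"SFGD", "GEO", "GEOGD"}
_SQRT3 = float(np.sqrt(3.0))


class CalibrationError(RuntimeError):
    """Density calibration failed to bracket or converge."""


@dataclass(frozen=True)
class ModelSpec:
    """One model/size/density cell, with seeding and calibration settings."""

    model: str
    N: int
    rho: float
    seed: int = 0
    cal_replicas: int = 10
    cal_tol: float = 0.03  # relative tolerance on the batch-mean density
    cal_max_iter: int = 40

    def __post_init__(self):
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODEL_NAMES}")
        if self.N < 2:
            raise ValueError("N must be at least 2")
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (0, 1)")

    @property
    def eta(self) -> int:
        """SFBA attachment parameter eta = rho*N/2 (must be a positive integer)."""
        eta = self.rho * self.N / 2.0
        eta_int = round(eta)
        if abs(eta - eta_int) > 1e-9 or eta_int < 1:
            raise ValueError(f"eta = rho*N/2 = {eta} is not a positive integer")
        return int(eta_int)


@dataclass(frozen=True)
class GeneratedGraph:
    """A generated graph plus its provenance and realized density."""

    graph: nx.Graph
    spec: ModelSpec
    realized_density: float
    aux: float | None = None  # calibrated q or r, when applicable
    label: str = ""


def derive_seed(base: int, *key: int) -> int:
    """Deterministic child seed (< 2^31) from a base seed and a counter key."""
    ss = np.random.SeedSequence(entropy=int(base), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def _density(n_edges: int, N: int) -> float:
    return 2.0 * n_edges / (N * (N - 1))


def _graph_from_edges(N: int, edges) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(N))
    g.add_edges_from(edges)
    return g


# ---------------------------------------------------------------- raw models


def _er_edges(N: int, rho: float, rng: np.random.Generator) -> list[tuple[int, int]]:
    # vectorized Bernoulli over the upper triangle, blockwise to bound memory
    edges: list[tuple[int, int]] = []
    block = max(1, min(N, 10**7 // max(N, 1)))
    for i0 in range(0, N, block):
        rows = np.arange(i0, min(i0 + block, N))
        u = rng.random((rows.size, N))
        ii, jj = np.nonzero(u < rho)
        keep = rows[ii] < jj
        edges.extend(zip(rows[ii[keep]].tolist(), jj[keep].tolist()))
    return edges


def _sfba_edges(N: int, eta: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    if N < eta + 1:
        raise ValueError("SFBA needs N >= eta + 1")
    edges = list(combinations(range(eta + 1), 2))
    # each node appears once per unit of degree: sampling from this list is
    # sampling proportionally to degree
    repeated: list[int] = [v for e in edges for v in e]
    for new in range(eta + 1, N):
        targets: set[int] = set()
        while len(targets) < eta:
            targets.add(repeated[rng.integers(len(repeated))])
        for t in targets:
            edges.append((new, t))
            repeated.append(new)
            repeated.append(t)
    return edges


def _double_edge_swaps(edges: list[tuple[int, int]], n_attempts: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Degree-preserving randomization: n_attempts double-edge swap attempts.

    An attempt picks two distinct edges (a,b), (c,d) and one of the two
    rewirings (a,d)+(c,b) or (a,c)+(b,d); it is rejected if it would create
    a self-loop or a duplicate edge.
    """
    edge_arr = [tuple(sorted(e)) for e in edges]
    edge_set = set(edge_arr)
    L = len(edge_arr)
    if L < 2:
        return edge_arr
    # draw randomness in batches: the loop body is pure bookkeeping
    batch = 1 << 16
    done = 0
    while done < n_attempts:
        k = min(batch, n_attempts - done)
        idx = rng.integers(0, L, size=(k, 2))
        flips = rng.random(k) < 0.5
        for (e1, e2), flip in zip(idx, flips):
            if e1 == e2:
                continue
            a, b = edge_arr[e1]
            c, d = edge_arr[e2]
            if flip:
                new1, new2 = (a, d), (c, b)
            else:
                new1, new2 = (a, c), (b, d)
            if new1[0] == new1[1] or new2[0] == new2[1]:
                continue
            new1 = tuple(sorted(new1))
            new2 = tuple(sorted(new2))
            if new1 == new2 or new1 in edge_set or new2 in edge_set:
                continue
            edge_set.discard(edge_arr[e1])
            edge_set.discard(edge_arr[e2])
            edge_set.add(new1)
            edge_set.add(new2)
            edge_arr[e1] = new1
            edge_arr[e2] = new2
        done += k
    return edge_arr


def _sticky_edges(degrees: np.ndarray, rng: np.random.Generator) -> list[tuple[int, int]]:
    N = degrees.size
    total = float(degrees.sum())
    edges: list[tuple[int, int]] = []
    block = max(1, min(N, 10**7 // max(N, 1)))
    m = degrees.astype(np.float64)
    for i0 in range(0, N, block):
        rows = np.arange(i0, min(i0 + block, N))
        P = np.minimum(np.outer(m[rows], m) / total, 1.0)
        u = rng.random(P.shape)
        ii, jj = np.nonzero(u < P)
        keep = rows[ii] < jj
        edges.extend(zip(rows[ii[keep]].tolist(), jj[keep].tolist()))
    return edges


def _sfgd_adj(N: int, q: float, rng: np.random.Generator) -> list[set[int]]:
    adj: list[set[int]] = [set() for _ in range(N)]
    adj[0].add(1)
    adj[1].add(0)
    for i in range(2, N):
        j = int(rng.integers(i))
        shared = sorted(adj[j])  # common neighbors of (i, j) after duplication
        adj[i] = set(shared)
        for h in shared:
            adj[h].add(i)
        if rng.random() < 0.5:
            adj[i].add(j)
            adj[j].add(i)
        for h in shared:
            if rng.random() < q:
                if rng.random() < 0.5:
                    adj[h].discard(i)
                    adj[i].discard(h)
                else:
                    adj[h].discard(j)
                    adj[j].discard(h)
    return adj


def _geo_points(N: int, rng: np.random.Generator) -> np.ndarray:
    return rng.random((N, 3))


def _geo_radius_for_density(rho: float) -> float:
    """Radius whose ball volume equals the target density (boundary ignored)."""
    return float((3.0 * rho / (4.0 * np.pi)) ** (1.0 / 3.0))


def _geogd_points(N: int, place_radius: float, rng: np.random.Generator) -> np.ndarray:
    """Duplication-style geometric growth: each point lands near a random parent.

    ``place_radius`` is the maximum parent-child distance. It is pinned to
    the target density's ideal geometric radius (2 * r0) rather than to the
    calibrated connection threshold: coupling it to the threshold makes the
    point cloud scale with r, leaving the density nearly r-independent and
    low targets unreachable.
    """
    pts = np.empty((N, 3))
    pts[0] = rng.random(3)
    # seed pair at a much shorter distance than the connection radius
    pts[1] = _place_near(pts[0], place_radius / 20.0, rng, uniform_ball=False)
    for i in range(2, N):
        j = int(rng.integers(i))
        pts[i] = _place_near(pts[j], place_radius, rng, uniform_ball=True)
    return pts


def _place_near(center: np.ndarray, radius: float, rng: np.random.Generator, uniform_ball: bool) -> np.ndarray:
    """Rejection-sample a point of the ball around center intersected with the cube.

    ``uniform_ball`` draws uniformly inside the ball; otherwise the point is
    placed exactly at the given radius (used for the seed pair).
    """
    while True:
        v = rng.standard_normal(3)
        norm = np.linalg.norm(v)
        if norm == 0.0:
            continue
        v /= norm
        rad = radius * rng.random() ** (1.0 / 3.0) if uniform_ball else radius
        cand = center + rad * v
        if np.all((cand >= 0.0) & (cand <= 1.0)):
            return cand


def _radius_edges(points: np.ndarray, r: float) -> np.ndarray:
    """Pairs at Euclidean distance strictly smaller than r."""
    if r <= 0.0:
        return np.empty((0, 2), dtype=np.int64)
    pairs = cKDTree(points).query_pairs(r, output_type="ndarray")
    if pairs.size:
        d = np.linalg.norm(points[pairs[:, 0]] - points[pairs[:, 1]], axis=1)
        pairs = pairs[d < r]
    return pairs


# ----------------------------------------------------------------- per-model


def generate_er(spec: ModelSpec) -> GeneratedGraph:
    rng = np.random.default_rng(spec.seed)
    g = _graph_from_edges(spec.N, _er_edges(spec.N, spec.rho, rng))
    return GeneratedGraph(g, spec, _density(g.number_of_edges(), spec.N))


def generate_sfba(spec: ModelSpec) -> GeneratedGraph:
    rng = np.random.default_rng(spec.seed)
    g = _graph_from_edges(spec.N, _sfba_edges(spec.N, spec.eta, rng))
    return GeneratedGraph(g, spec, _density(g.number_of_edges(), spec.N))


def generate_erdd(spec: ModelSpec, swaps_per_edge: int = 10) -> GeneratedGraph:
    rng = np.random.default_rng(spec.seed)
    edges = _sfba_edges(spec.N, spec.eta, rng)
    shuffled = _double_edge_swaps(edges, swaps_per_edge * len(edges), rng)
    g = _graph_from_edges(spec.N, shuffled)
    return GeneratedGraph(g, spec, _density(g.number_of_edges(), spec.N))


def generate_sticky(spec: ModelSpec) -> GeneratedGraph:
    rng = np.random.default_rng(spec.seed)
    source = _graph_from_edges(spec.N, _sfba_edges(spec.N, spec.eta, rng))
    degrees = np.array([d for _, d in sorted(source.degree)], dtype=np.int64)
    g = _graph_from_edges(spec.N, _sticky_edges(degrees, rng))
    return GeneratedGraph(g, spec, _density(g.number_of_edges(), spec.N))


def generate_sfgd(spec: ModelSpec, q: float | None = None) -> GeneratedGraph:
    if q is None:
        q = calibrate_density("SFGD", spec)
    rng = np.random.default_rng(spec.seed)
    adj = _sfgd_adj(spec.N, q, rng)
    edges = [(i, j) for i in range(spec.N) for j in adj[i] if i < j]
    g = _graph_from_edges(spec.N, edges)
    return GeneratedGraph(g, spec, _density(g.number_of_edges(), spec.N), aux=q)


def generate_geo(spec: ModelSpec, r: float | None = None) -> GeneratedGraph:
    if r is None:
        r = calibrate_density("GEO", spec)
    rng = np.random.default_rng(spec.seed)
    g = _graph_from_edges(spec.N, _radius_edges(_geo_points(spec.N, rng), r))
    return GeneratedGraph(g, spec, _density(g.number_of_edges(), spec.N), aux=r)


def generate_geogd(spec: ModelSpec, r: float | None = None) -> GeneratedGraph:
    if r is None:
        r = calibrate_density("GEOGD", spec)
    rng = np.random.default_rng(spec.seed)
    place_radius = 2.0 * _geo_radius_for_density(spec.rho)
    g = _graph_from_edges(spec.N, _radius_edges(_geogd_points(spec.N, place_radius, rng), r))
    return GeneratedGraph(g, spec, _density(g.number_of_edges(), spec.N), aux=r)


_DISPATCH = {
    "ER": generate_er,
    "ERDD": generate_erdd,
    "SFBA": generate_sfba,
    "STICKY": generate_sticky,
    "SFGD": generate_sfgd,
    "GEO": generate_geo,
    "GEOGD": generate_geogd,
}


def generate(spec: ModelSpec, param: float | None = None) -> GeneratedGraph:
    """Generate one graph from the named model.

    For SFGD/GEO/GEOGD, ``param`` is the divergence probability q or the
    connection radius r; when omitted it is calibrated first (see
    :func:`calibrate_density`).
    """
    fn = _DISPATCH[spec.model]
    if spec.model in _CALIBRATED:
        return fn(spec, param)
    return fn(spec)


# --------------------------------------------------------------- calibration


def _replica_seeds(spec: ModelSpec) -> list[int]:
    return [derive_seed(spec.seed, k) for k in range(spec.cal_replicas)]


def calibrate_density(model: str, spec: ModelSpec, replica_seeds: list[int] | None = None) -> float:
    """Bisection search for the model parameter matching the target density.

    Returns q (SFGD) or r (GEO/GEOGD) such that the mean realized density
    over the replica batch is within relative tolerance ``spec.cal_tol`` of
    ``spec.rho``. The batch uses fixed per-replica child seeds, so the
    objective is a deterministic monotone step function of the parameter:
    increasing in r, decreasing in q.
    """
    if model not in _CALIBRATED:
        raise ValueError(f"model {model!r} needs no calibration")
    seeds = replica_seeds if replica_seeds is not None else _replica_seeds(spec)
    if not seeds:
        raise ValueError("need at least one calibration replica")
    target = spec.rho

    if model in ("GEO", "GEOGD"):
        # fixed point clouds (GEOGD placement does not depend on the
        # connection threshold): density(r) is a quantile lookup on the
        # sorted pairwise distances of each replica
        if model == "GEO":
            clouds = (_geo_points(spec.N, np.random.default_rng(s)) for s in seeds)
        else:
            place_radius = 2.0 * _geo_radius_for_density(target)
            clouds = (
                _geogd_points(spec.N, place_radius, np.random.default_rng(s)) for s in seeds
            )
        sorted_d = [np.sort(pdist(pts).astype(np.float32)) for pts in clouds]
        n_pairs = spec.N * (spec.N - 1) // 2

        def density(r: float) -> float:
            return float(np.mean([np.searchsorted(d, r, side="left") / n_pairs for d in sorted_d]))

        return _bisect(density, target, 0.0, _SQRT3, increasing=True, spec=spec, model=model)

    def density(q: float) -> float:
        vals = []
        for s in seeds:
            adj = _sfgd_adj(spec.N, q, np.random.default_rng(s))
            L = sum(len(a) for a in adj) // 2
            vals.append(_density(L, spec.N))
        return float(np.mean(vals))

    return _bisect(density, target, 0.0, 1.0, increasing=False, spec=spec, model=model)


def _bisect(density, target, lo, hi, increasing, spec, model):
    sign = 1.0 if increasing else -1.0
    d_lo, d_hi = density(lo), density(hi)
    if sign * (d_lo - target) > 0 or sign * (d_hi - target) < 0:
        raise CalibrationError(
            f"{model} N={spec.N} rho={spec.rho}: target not bracketed "
            f"(density({lo:.4g})={d_lo:.4g}, density({hi:.4g})={d_hi:.4g})"
        )
    best, best_err = None, np.inf
    for _ in range(spec.cal_max_iter):
        mid = 0.5 * (lo + hi)
        d_mid = density(mid)
        err = abs(d_mid - target)
        if err < best_err:
            best, best_err = mid, err
        if err <= spec.cal_tol * target:
            return mid
        if sign * (d_mid - target) < 0:
            lo = mid
        else:
            hi = mid
    if best is not None and best_err <= spec.cal_tol * target:
        return best
    raise CalibrationError(
        f"{model} N={spec.N} rho={spec.rho}: no convergence in {spec.cal_max_iter} iterations "
        f"(best |density-target| = {best_err:.4g}, tolerance {spec.cal_tol * target:.4g})"
    )


# ---------------------------------------------------------------------- grid


def generate_grid(
    models: list[str],
    sizes: list[int],
    densities: list[float],
    replicas: int,
    seed: int,
    cal_tol: float = 0.03,
    cal_max_iter: int = 40,
) -> tuple[list[GeneratedGraph], pd.DataFrame]:
    """Generate the full model/size/density benchmark grid.

    For each (model, N, rho) cell, ``replicas`` instances are generated from
    deterministic per-replica child seeds. Calibrated models are calibrated
    once per cell against the batch-mean density of those same replicas,
    which are then the emitted instances. Returns the graphs and a manifest
    with one row per graph (label, model, N, rho, replica, realized density,
    calibrated parameter).
    """
    graphs: list[GeneratedGraph] = []
    rows = []
    cell = 0
    for model in models:
        for N in sizes:
            for rho in densities:
                seeds = [derive_seed(seed, cell, k) for k in range(replicas)]
                param = None
                if model in _CALIBRATED:
                    cal_spec = ModelSpec(
                        model, N, rho, seed=derive_seed(seed, cell),
                        cal_replicas=replicas, cal_tol=cal_tol, cal_max_iter=cal_max_iter,
                    )
                    param = calibrate_density(model, cal_spec, replica_seeds=seeds)
                for k, s in enumerate(seeds):
                    gspec = ModelSpec(model, N, rho, seed=s, cal_tol=cal_tol, cal_max_iter=cal_max_iter)
                    gg = generate(gspec, param)
                    label = f"{model}_N{N}_rho{rho:g}_{k}"
                    gg = GeneratedGraph(gg.graph, gg.spec, gg.realized_density, gg.aux, label)
                    graphs.append(gg)
                    rows.append(
                        {
                            "label": label,
                            "model": model,
                            "N": N,
                            "rho": rho,
                            "replica": k,
                            "realized_density": gg.realized_density,
                            "parameter": gg.aux,
                        }
                    )
                cell += 1
    return graphs, pd.DataFrame(rows)
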