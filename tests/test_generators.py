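"""Synthetic network models: construction invariants and density calibration."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from egodist.generators import (
    CalibrationError,
    ModelSpec,
    calibrate_density,
    derive_seed,
    generate,
    generate_er,
    generate_erdd,
    generate_geo,
    generate_geogd,
    generate_grid,
    generate_sfba,
    generate_sfgd,
    generate_sticky,
)
from egodist.generators import _double_edge_swaps, _geo_radius_for_density, _sfba_edges, _sfgd_adj


def degree_sequence(g):
    return sorted(d for _, d in g.degree)


class TestER:
    def test_edge_count_unbiased(self):
        N, rho = 300, 0.02
        expected = rho * N * (N - 1) / 2
        counts = [generate_er(ModelSpec("ER", N, rho, seed=s)).graph.number_of_edges() for s in range(20)]
        # binomial mean within 3 standard errors
        se = np.sqrt(N * (N - 1) / 2 * rho * (1 - rho) / 20)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_sparse_limit(self):
        g = generate_er(ModelSpec("ER", 100, 1e-9, seed=0)).graph
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 100

    def test_seed_determinism(self):
        g1 = generate_er(ModelSpec("ER", 200, 0.05, seed=7)).graph
        g2 = generate_er(ModelSpec("ER", 200, 0.05, seed=7)).graph
        assert set(g1.edges) == set(g2.edges)


class TestSFBA:
    def test_exact_edge_count(self):
        # eta = 5: clique 15 edges + 994 nodes x 5 edges
        g = generate_sfba(ModelSpec("SFBA", 1000, 0.01, seed=3)).graph
        assert g.number_of_edges() == 15 + 994 * 5

    def test_edge_count_formula_small(self):
        # eta=2 at N=6: clique of 3 nodes plus 3 nodes adding 2 edges each
        g = generate_sfba(ModelSpec("SFBA", 6, 2 / 3, seed=0)).graph
        assert g.number_of_edges() == 3 + 3 * 2

    def test_min_degree_at_least_eta(self):
        gg = generate_sfba(ModelSpec("SFBA", 400, 0.02, seed=1))
        assert min(d for _, d in gg.graph.degree) >= gg.spec.eta

    def test_non_integer_eta_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            ModelSpec("SFBA", 1000, 0.011, seed=0).eta


class TestERDD:
    def test_degree_sequence_preserved(self):
        spec = ModelSpec("ERDD", 500, 0.02, seed=5)
        rng = np.random.default_rng(spec.seed)
        source = _sfba_edges(spec.N, spec.eta, rng)
        out = generate_erdd(spec).graph
        source_deg = np.zeros(spec.N, dtype=int)
        for u, v in source:
            source_deg[u] += 1
            source_deg[v] += 1
        assert degree_sequence(out) == sorted(source_deg)
        assert out.number_of_edges() == len(source)

    def test_zero_swaps_identity(self):
        edges = [(0, 1), (1, 2), (2, 3)]
        assert _double_edge_swaps(edges, 0, np.random.default_rng(0)) == [(0, 1), (1, 2), (2, 3)]

    def test_swaps_stay_simple(self):
        rng = np.random.default_rng(2)
        edges = _sfba_edges(100, 3, rng)
        out = _double_edge_swaps(edges, 10 * len(edges), rng)
        assert len(set(out)) == len(out)
        assert all(u != v for u, v in out)


class TestSticky:
    def test_expected_edge_count(self):
        spec = ModelSpec("STICKY", 300, 0.04, seed=9)
        # realized SFBA degree sequence fixes the Bernoulli means
        source = generate_sfba(spec).graph
        m = np.array(degree_sequence(source), dtype=float)
        # same degree multiset regardless of order; expectation is symmetric
        P = np.minimum(np.outer(m, m) / m.sum(), 1.0)
        expected = P[np.triu_indices(spec.N, k=1)].sum()
        counts = []
        for s in range(20):
            counts.append(generate_sticky(ModelSpec("STICKY", 300, 0.04, seed=s)).graph.number_of_edges())
        se = np.sqrt(expected)  # sum of Bernoullis, variance <= mean
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_node_count_kept_with_isolates(self):
        g = generate_sticky(ModelSpec("STICKY", 200, 0.01, seed=1)).graph
        assert g.number_of_nodes() == 200

    def test_determinism(self):
        g1 = generate_sticky(ModelSpec("STICKY", 200, 0.02, seed=4)).graph
        g2 = generate_sticky(ModelSpec("STICKY", 200, 0.02, seed=4)).graph
        assert set(g1.edges) == set(g2.edges)


class TestSFGD:
    def test_exact_node_count(self):
        for q in (0.0, 0.3, 1.0):
            g = generate_sfgd(ModelSpec("SFGD", 50, 0.1, seed=2), q=q).graph
            assert g.number_of_nodes() == 50

    def test_no_divergence_creates_twins(self):
        # q=0: every added node copies its template's neighborhood exactly
        adj = _sfgd_adj(30, 0.0, np.random.default_rng(1))
        twins = 0
        for i in range(2, 30):
            for j in range(i):
                if adj[i] - {j} == adj[j] - {i}:
                    twins += 1
                    break
        assert twins > 10

    @pytest.mark.parametrize("q", [0.0, 0.5, 1.0])
    def test_matches_stepwise_reference(self, q):
        """Replay oracle: a plain step-by-step simulator consuming the same
        random draws reproduces the graph, and verifies in-flight that at
        q=1 no common neighbor of a duplication pair keeps both edges."""
        for seed in range(6):
            rng = np.random.default_rng(seed)
            N = 10
            ref = [set() for _ in range(N)]
            ref[0].add(1)
            ref[1].add(0)
            for i in range(2, N):
                j = int(rng.integers(i))
                shared = sorted(ref[j])
                ref[i] = set(shared)
                for h in shared:
                    ref[h].add(i)
                if rng.random() < 0.5:
                    ref[i].add(j)
                    ref[j].add(i)
                for h in shared:
                    if rng.random() < q:
                        victim = i if rng.random() < 0.5 else j
                        ref[h].discard(victim)
                        ref[victim].discard(h)
                if q == 1.0:
                    # full divergence: the pair shares no surviving neighbor
                    assert all(not (i in ref[h] and j in ref[h]) for h in shared)
            assert _sfgd_adj(N, q, np.random.default_rng(seed)) == ref

    def test_calibration_hits_target(self):
        spec = ModelSpec("SFGD", 300, 0.02, seed=11, cal_replicas=5)
        q = calibrate_density("SFGD", spec)
        seeds = [derive_seed(spec.seed, k) for k in range(5)]
        dens = [generate_sfgd(ModelSpec("SFGD", 300, 0.02, seed=s), q=q).realized_density for s in seeds]
        assert abs(np.mean(dens) - 0.02) <= 0.03 * 0.02 + 1e-12


class TestGeometric:
    def test_complete_at_diameter(self):
        g = generate_geo(ModelSpec("GEO", 40, 0.5, seed=0), r=np.sqrt(3)).graph
        assert g.number_of_edges() == 40 * 39 / 2

    def test_empty_at_zero_radius(self):
        g = generate_geo(ModelSpec("GEO", 40, 0.5, seed=0), r=0.0).graph
        assert g.number_of_edges() == 0

    @pytest.mark.parametrize("model", ["GEO", "GEOGD"])
    def test_brute_force_edge_oracle(self, model):
        # O(N^2) thresholding of the realized coordinates reproduces the edges
        from egodist.generators import _geo_points, _geogd_points, _radius_edges

        N, rho = 150, 0.05
        rng = np.random.default_rng(42)
        if model == "GEO":
            pts = _geo_points(N, rng)
            r = 0.25
        else:
            r = 0.2
            pts = _geogd_points(N, 2.0 * _geo_radius_for_density(rho), rng)
        edges = {tuple(sorted(e)) for e in _radius_edges(pts, r)}
        dmat = squareform(pdist(pts))
        brute = {
            (i, j) for i in range(N) for j in range(i + 1, N) if dmat[i, j] < r
        }
        assert edges == brute

    def test_geogd_points_inside_cube(self):
        from egodist.generators import _geogd_points

        pts = _geogd_points(200, 0.3, np.random.default_rng(3))
        assert np.all((pts >= 0.0) & (pts <= 1.0))

    def test_geo_calibration_round_trip(self):
        # generate at a known radius, measure the density, re-calibrate to it
        N, r_star = 500, 0.2
        seeds = [derive_seed(77, k) for k in range(5)]
        dens = [generate_geo(ModelSpec("GEO", N, 0.5, seed=s), r=r_star).realized_density for s in seeds]
        rho_star = float(np.mean(dens))
        spec = ModelSpec("GEO", N, rho_star, seed=77, cal_replicas=5)
        r = calibrate_density("GEO", spec, replica_seeds=seeds)
        assert abs(r - r_star) / r_star < 0.05

    def test_calibration_unreachable_density_errors(self):
        spec = ModelSpec("SFGD", 50, 0.9, seed=0, cal_replicas=2, cal_max_iter=5)
        with pytest.raises(CalibrationError):
            calibrate_density("SFGD", spec)


class TestGrid:
    def test_counts_and_labels(self):
        graphs, manifest = generate_grid(["ER", "SFBA"], [100, 200], [0.04], 3, seed=1)
        assert len(graphs) == 2 * 2 * 1 * 3
        assert len(manifest) == len(graphs)
        assert manifest["label"].is_unique
        assert graphs[0].label.startswith("ER_N100_rho0.04_")
        assert set(manifest["model"]) == {"ER", "SFBA"}

    def test_grid_determinism(self):
        g1, m1 = generate_grid(["ER"], [100], [0.04], 2, seed=9)
        g2, m2 = generate_grid(["ER"], [100], [0.04], 2, seed=9)
        for a, b in zip(g1, g2):
            assert set(a.graph.edges) == set(b.graph.edges)

    def test_single_cell_single_replica(self):
        graphs, manifest = generate_grid(["GEO"], [100], [0.1], 1, seed=2)
        assert len(graphs) == 1
        assert manifest.loc[0, "parameter"] is not None

    def test_generate_dispatch_matches_models(self):
        for model in ("ER", "SFBA", "ERDD", "STICKY"):
            gg = generate(ModelSpec(model, 60, 0.1, seed=0))
            assert gg.graph.number_of_nodes() == 60
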