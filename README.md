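# egodist

Alignment-free comparison of undirected, unweighted networks via egonet
feature distributions.

Comparing two networks without matching their nodes is a recurring task in
systems biology and network science: recognizing which generative mechanism
produced a graph, clustering an ensemble of interaction networks, or
spotting structural breaks in a temporal sequence. `egodist` implements a
family of such dissimilarity measures ("ego-distances") built from the
per-node distributions of three egonet features, together with the seven
synthetic network models and the Precision/Recall harness used to validate
them.

## The method

For each node *i* (egonet *E_i = {i} ∪ N(i)*, degree *m_i*, *e_i* edges
among neighbors) three features in [0, 1] are computed:

- normalized degree `d_i = (m_i − m_min)/(m_max − m_min)`
- clustering coefficient `c_i = 2 e_i / (m_i (m_i − 1))`
- egonet persistence `p_i = Σ_{j∈E_i} m_j^int / Σ_{j∈E_i} m_j` — the
  probability that a degree-proportional random walker inside *E_i* stays
  inside after one step.

The features are histogrammed with step Δ (default 0.01) in 1, 2, or 3
dimensions, and the distance between graphs *G′*, *G″* is the Euclidean
norm of the difference of their cdfs, e.g. for the 3-D variant

    D_dcp(G′,G″) = [ Σ_{h,k,n} ( Q′(h,k,n) − Q″(h,k,n) )² ]^(1/2).

Metrics: `d`, `c`, `p`, `sum` (= D_d + D_c + D_p), `cp`, `dc`, `dp`, `dcp`,
and the scalar baseline `Cglobal = |C′ − C″|`. An optional cap value
`T ∈ (0,1]` restricts the sums to the first `T/Δ` bins per axis, focusing
the comparison where the distributions actually differ. Graphs of different
size are comparable as long as Δ and T match. See `docs/methods.md` for the
full model and numerical details.

Benchmark generators: ER, degree-preserving-randomized ERDD, preferential
attachment SFBA, duplication-divergence SFGD, geometric GEO, geometric
gene-duplication GEOGD, and stickiness STICKY — each at prescribed size N
and density ρ, with automatic bisection calibration of the free parameter
(q or r) where the model has one.

## Worked example

```python
from egodist import ModelSpec, generate, compute_features, DistanceSpec, ego_distance

er   = generate(ModelSpec("ER",   1000, 0.01, seed=7))
geo  = generate(ModelSpec("GEO",  1000, 0.01, seed=7))   # radius calibrated to density
sfba = generate(ModelSpec("SFBA", 1000, 0.01, seed=7))

f = compute_features(geo.graph)
print(f"GEO realized density {geo.realized_density:.4f}, radius {geo.aux:.4f}")
print(f"GEO global clustering C = {f.C:.3f}")

spec = DistanceSpec("dcp", delta=0.01, cap=0.5)
print(f"D_dcp(ER, GEO)  = {ego_distance(er.graph, geo.graph, spec):.2f}")
print(f"D_dcp(ER, SFBA) = {ego_distance(er.graph, sfba.graph, spec):.2f}")
er2 = generate(ModelSpec("ER", 1000, 0.01, seed=8))
print(f"D_dcp(ER, ER')  = {ego_distance(er.graph, er2.graph, spec):.2f}")
```

prints

```
GEO realized density 0.0102, radius 0.1421
GEO global clustering C = 0.516
D_dcp(ER, GEO)  = 89.90
D_dcp(ER, SFBA) = 207.08
D_dcp(ER, ER')  = 35.62
```

The geometric model's radius was calibrated so that the realized density
matches the 0.01 target; its clustering mass around 0.5 is what makes it
easy to tell from ER. Two independent ER draws sit much closer to each
other (35.6) than ER sits to GEO (89.9) or to the preferential-attachment
graph (207.1) — the ordering a same-model classifier relies on. Distances
are root-sums over the cdf grid and are only comparable at equal Δ and T.

The same workflow from the shell:

```sh
egodist generate --model GEO --n 1000 --rho 0.01 --seed 7 --out geo.edges
egodist dist er.edges geo.edges --metric dcp --delta 0.01 --cap 0.5
egodist distmat --metric dc --out m.csv *.edges
egodist evaluate --config grid.yaml --metrics d,c,p,sum,dc,dcp,Cglobal --out table.tsv
```

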