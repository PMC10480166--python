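import networkx as nx
import numpy as np
import pytest

from egodist.io import fixtures


@pytest.fixture
def toy(request):
    return fixtures(request.param)


def random_graph(seed: int, n_max: int = 30, p: float | None = None) -> nx.Graph:
    """Small seeded Erdős–Rényi graph for oracle comparisons."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.05, 0.6)) if p is None else p
    return nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))


@pytest.fixture(params=range(12))
def small_random_graph(request):
    return random_graph(request.param)
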