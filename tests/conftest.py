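import numpy as np
import pytest

from actilabel.network import NetworkGraph


def graph(n, edges, k=3):
    """NetworkGraph from an explicit edge list (testing helper)."""
    return NetworkGraph(
        n_vertices=n, edges={(min(u, v), max(u, v)) for u, v in edges}, k=k
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def path4():
    """Path 0-1-2-3."""
    return graph(4, [(0, 1), (1, 2), (2, 3)])


@pytest.fixture
def k4():
    """Complete graph on 4 vertices."""
    return graph(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])


def random_graph(rng, n, n_edges):
    """Simple random graph with exactly n_edges distinct edges."""
    edges = set()
    while len(edges) < n_edges:
        u, v = rng.integers(0, n, size=2)
        if u != v:
            edges.add((min(u, v), max(u, v)))
    return graph(n, edges)


def brute_force_statistics(G, P):
    """Independent edge-enumeration oracle for cut/density/size."""
    K = len(P.clusters)
    assign = {}
    for cid, ms in enumerate(P.clusters):
        for v in ms:
            assign[v] = cid
    cut = np.zeros((K, K))
    delta = np.zeros(K)
    for u, v in G.edges:
        if u not in assign or v not in assign:
            continue
        cu, cv = assign[u], assign[v]
        if cu == cv:
            delta[cu] += 1
        else:
            cut[cu, cv] += 1
            cut[cv, cu] += 1
    sigma = np.array([len(ms) for ms in P.clusters], dtype=float)
    return cut, delta, sigma
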