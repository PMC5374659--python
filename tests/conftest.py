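import networkx as nx
import numpy as np
import pytest

from sequoia import SimilarityTable


def make_connected_er(rng: np.random.Generator, n: int, prefix: str, p: float = 0.5) -> nx.Graph:
    """Small connected Erdős–Rényi graph for oracle-scale tests."""
    nodes = [f"{prefix}{i}" for i in range(n)]
    for _ in range(1000):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    g.add_edge(nodes[i], nodes[j], weight=float(rng.uniform(0.5, 2.0)), pseudo=False)
        if n == 1 or nx.is_connected(g):
            return g
    raise RuntimeError("could not sample a connected graph")


def random_similarity(rng: np.random.Generator, query: nx.Graph, target: nx.Graph, density: float = 0.6) -> SimilarityTable:
    sim = SimilarityTable()
    for q in sorted(query.nodes):
        for t in sorted(target.nodes):
            if rng.random() < density:
                sim.set(q, t, float(rng.uniform(0.5, 2.0)))
    if len(sim) == 0:
        q = sorted(query.nodes)[0]
        t = sorted(target.nodes)[0]
        sim.set(q, t, 1.0)
    return sim


@pytest.fixture
def path_graph() -> nx.Graph:
    g = nx.Graph()
    for a, b in [("a", "b"), ("b", "c"), ("c", "d")]:
        g.add_edge(a, b, weight=1.0, pseudo=False)
    return g
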