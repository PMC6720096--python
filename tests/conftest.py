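import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, max_examples=25, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    """Erdős–Rényi test graph over string protein IDs."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    return nx.relabel_nodes(g, {i: f"P{i:03d}" for i in g.nodes})


@pytest.fixture
def path_p4() -> nx.Graph:
    return nx.path_graph(["A", "B", "C", "D"])


@pytest.fixture
def small_background() -> nx.Graph:
    """500-node scale-free-ish background for oracle comparisons."""
    from netregmir.synthetic import SyntheticConfig, generate_background
    cfg = SyntheticConfig(n_background=500, module_size=40, module_density=0.3,
                          hub_count=3, hub_degree_boost=60, seed_count=40,
                          rng_seed=11)
    net, truth = generate_background(cfg)
    net.graph["truth"] = truth
    return net


def modularity_oracle(net: nx.Graph, labels: dict) -> float:
    """Direct evaluation of the modularity sum, independent of networkx."""
    m = net.number_of_edges()
    if m == 0:
        return 0.0
    q = 0.0
    for c in set(labels.values()):
        members = [v for v in net if labels[v] == c]
        e_c = sum(1 for u, v in net.edges if labels[u] == c and labels[v] == c)
        d_c = sum(net.degree[v] for v in members)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


def transitivity_oracle(net: nx.Graph) -> float:
    """Exhaustive triangle/open-triple scan; intended for graphs ≤ 60 nodes."""
    nodes = sorted(net)
    triangles = 0
    triples = 0
    for i, u in enumerate(nodes):
        for j in range(i + 1, len(nodes)):
            for k in range(j + 1, len(nodes)):
                v, w = nodes[j], nodes[k]
                n_edges = (net.has_edge(u, v) + net.has_edge(v, w)
                           + net.has_edge(u, w))
                if n_edges == 3:
                    triangles += 1
                    triples += 3
                elif n_edges == 2:
                    triples += 1
    return np.nan if triples == 0 else 3 * triangles / triples
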