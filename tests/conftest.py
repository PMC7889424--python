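import numpy as np
import pytest

import medsim as m


class OracleModel:
    """Fold model that simply returns the gold score of each pair."""

    def fit(self, pairs):
        pass

    def predict(self, pairs):
        return [p.score for p in pairs]


@pytest.fixture
def oracle_factory():
    return OracleModel


@pytest.fixture
def small_corpus():
    """A tiny mixed corpus with gold scores."""
    cfg = m.SynthConfig(
        n_agents=8, n_pairs=40, med_fraction=0.5, noise_sd=0.1, seed=42
    )
    corpus, truth = m.generate_corpus(cfg)
    return corpus, truth


@pytest.fixture
def example_records():
    rec_a = m.MedicationRecord("ondansetron", 4.0, "mg", 1.0, "tablet", 3.0)
    rec_b = m.MedicationRecord("amoxicillin", 500.0, "mg", 2.0, "capsule", 3.0)
    return rec_a, rec_b


def random_agent_graph(rng, max_nodes=8, w_low=0.1, w_high=5.0, p_edge=0.5):
    """A random undirected weighted graph for path-oracle checks."""
    n = int(rng.integers(2, max_nodes + 1))
    names = [f"a{i}" for i in range(n)]
    g = m.AgentGraph(nodes=set(names))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                w = float(rng.uniform(w_low, w_high))
                g.edges[(names[i], names[j])] = w
                g.n_obs[(names[i], names[j])] = 1
    return g, names


def brute_force_path(graph, a, b, weight_floor=1e-6):
    """Independent oracle: enumerate all simple paths, pick the one
    minimizing (sum of 1/w, hop count, lexicographic node sequence)."""
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(graph.nodes)
    for (u, v), w in graph.edges.items():
        G.add_edge(u, v, w=w)
    best = None
    for path in nx.all_simple_paths(G, a, b):
        res = 0.0
        for u, v in zip(path, path[1:]):
            res += 1.0 / max(G[u][v]["w"], weight_floor)
        key = (res, len(path) - 1, tuple(path))
        if best is None or key < best:
            best = key
    return best  # None when disconnected
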