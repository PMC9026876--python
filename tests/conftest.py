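import numpy as np
import pytest

import stenoprio as sp


def make_path_graph(names=("A", "B", "C")):
    g = sp.KnowledgeGraph()
    for a, b in zip(names, names[1:]):
        g.add_edge(a, b)
    return g


def random_graph(n_nodes, p_edge, rng):
    """Erdos-Renyi-style random graph for oracle comparisons."""
    g = sp.KnowledgeGraph()
    names = [f"R{i:03d}" for i in range(n_nodes)]
    for name in names:
        g.add_node(name)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                g.add_edge(names[i], names[j])
    return g, names


@pytest.fixture(scope="session")
def default_study():
    study = sp.simulate_study(seed=1)
    study.check_invariants()
    return study


@pytest.fixture(scope="session")
def trained_model(default_study):
    return sp.train_model(default_study.truth_table, default_study.graph,
                          default_study.dmap, seed=7)


@pytest.fixture(scope="session")
def synthetic_matrix(default_study, trained_model):
    return sp.score_all(default_study.graph, trained_model,
                        default_study.dmap, default_study.candidates,
                        sp.NullParams(seed=11))


@pytest.fixture(scope="session")
def published_matrix():
    return sp.ScoreMatrix.from_dataframe(sp.load_published_score_matrix())
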