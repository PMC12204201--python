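"""Shared fixtures: small hand-checkable systems and one mid-size synthetic
study system (session-scoped, generated programmatically)."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import sigentropy as sg


@pytest.fixture
def path_net():
    """Path graph A-B-C."""
    return sg.InteractionNetwork.from_edges([("A", "B"), ("B", "C")], name="path")


@pytest.fixture
def path_system(path_net):
    """Path A-B-C with expression E = (1, 2, 3): the hand-worked example."""
    expr = sg.ExpressionMatrix(pd.DataFrame({"s1": [1.0, 2.0, 3.0]}, index=["A", "B", "C"]))
    return sg.integrate(path_net, expr)


@pytest.fixture
def star5_system():
    """Star with 5 leaves, uniform expression."""
    edges = [("HUB", f"L{i}") for i in range(5)]
    net = sg.InteractionNetwork.from_edges(edges, name="star5")
    genes = sorted(net.nodes)
    expr = sg.ExpressionMatrix(pd.DataFrame({"s1": [1.0] * len(genes)}, index=genes))
    return sg.integrate(net, expr)


def make_uniform_system(graph: nx.Graph, value: float = 1.0) -> sg.IntegratedSystem:
    net = sg.InteractionNetwork(nx.relabel_nodes(graph, {n: f"N{n}" for n in graph.nodes}))
    genes = sorted(net.nodes)
    expr = sg.ExpressionMatrix(pd.DataFrame({"s1": [value] * len(genes)}, index=genes))
    return sg.integrate(net, expr)


def random_connected_system(rng: np.random.Generator, n_min: int = 5, n_max: int = 30):
    """Random connected graph with log-normal expression, for oracle tests."""
    n = int(rng.integers(n_min, n_max + 1))
    while True:
        g = nx.gnp_random_graph(n, min(1.0, 2.5 / n), seed=int(rng.integers(2**31)))
        if g.number_of_edges() >= 2:
            sub = max(nx.connected_components(g), key=len)
            if len(sub) >= 3:
                g = g.subgraph(sub).copy()
                break
    net = sg.InteractionNetwork(nx.relabel_nodes(g, {v: f"N{v}" for v in g.nodes}))
    genes = sorted(net.nodes)
    expr = sg.ExpressionMatrix(
        pd.DataFrame({"s1": rng.lognormal(0.0, 1.0, len(genes))}, index=genes)
    )
    return sg.integrate(net, expr)


@pytest.fixture(scope="session")
def small_study():
    """A 200-node synthetic two-class study system shared across tests."""
    spec = sg.SyntheticSpec(n_nodes=200, n_samples=10, seed=11)
    net = sg.generate_network(spec)
    expr, labels = sg.generate_expression(net, spec)
    return spec, net, expr, labels


@pytest.fixture(scope="session")
def toy_ontology():
    """Deterministic toy DAG with annotations."""
    return sg.generate_ontology(n_terms=25, max_children=3, depth=4, seed=7,
                                genes=[f"G{i:02d}" for i in range(20)])
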