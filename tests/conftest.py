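"""Shared fixtures: small handcrafted graphs and seeded random instances."""

from __future__ import annotations

import numpy as np
import pytest

from ssclpa.graph import Graph


def er_graph(n: int, p: float, seed: int) -> Graph:
    """Erdős–Rényi graph with string node ids '0'..'n-1' (all nodes kept)."""
    rng = np.random.default_rng(seed)
    edges = [
        (str(i), str(j))
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return Graph.from_edges(edges, nodes=(str(i) for i in range(n)))


def clique_graph(sizes) -> tuple[Graph, dict[str, str]]:
    """Disjoint cliques; returns the graph and its planted node->label map."""
    edges, nodes, truth = [], [], {}
    start = 0
    for b, sz in enumerate(sizes):
        for i in range(start, start + sz):
            nodes.append(str(i))
            truth[str(i)] = str(b)
            for j in range(i + 1, start + sz):
                edges.append((str(i), str(j)))
        start += sz
    return Graph.from_edges(edges, nodes=nodes), truth


@pytest.fixture
def triangle() -> Graph:
    return Graph.from_edges([("x", "y"), ("y", "z"), ("z", "x")])


@pytest.fixture
def two_triangles() -> Graph:
    g, _ = clique_graph([3, 3])
    return g


@pytest.fixture
def karate() -> Graph:
    import networkx as nx

    from ssclpa.graph import from_networkx

    return from_networkx(nx.karate_club_graph())
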