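from __future__ import annotations

import pytest

from modenrich.graph_io import WeightedGraph


def make_graph(edges) -> WeightedGraph:
    g = WeightedGraph()
    for u, v, w in edges:
        g.add_edge(u, v, w)
    return g


@pytest.fixture
def two_triangles() -> WeightedGraph:
    """Two disjoint unit-weight triangles: the canonical Q=0.5 toy."""
    return make_graph(
        [
            ("a", "b", 1),
            ("b", "c", 1),
            ("a", "c", 1),
            ("d", "e", 1),
            ("e", "f", 1),
            ("d", "f", 1),
        ]
    )


@pytest.fixture
def triangle_assignment() -> dict:
    return {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 1}


@pytest.fixture
def bridged_cliques() -> WeightedGraph:
    """Two 4-cliques joined by one bridge edge, all weights 1 (W=13)."""
    edges = []
    left = ["l0", "l1", "l2", "l3"]
    right = ["r0", "r1", "r2", "r3"]
    for grp in (left, right):
        for i in range(4):
            for j in range(i + 1, 4):
                edges.append((grp[i], grp[j], 1))
    edges.append(("l0", "r0", 1))
    return make_graph(edges)
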