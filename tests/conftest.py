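"""Shared fixtures: seeded random graphs and small deterministic graphs."""

from __future__ import annotations

import numpy as np
import pytest

from mocliq.graph import SimilarityGraph


def random_weighted_graph(seed: int, n_max: int = 30, p: float = 0.3,
                          w_lo: float = 0.4, w_hi: float = 1.0) -> SimilarityGraph:
    """Erdos-Renyi-style weighted graph with node count drawn from [5, n_max]."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, n_max + 1))
    nodes = [f"n{i:02d}" for i in range(n)]
    g = SimilarityGraph(gamma=0.0)
    for v in nodes:
        g.add_node(v)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(nodes[i], nodes[j], w_lo + (w_hi - w_lo) * rng.random())
    return g


@pytest.fixture
def triangle_graph() -> SimilarityGraph:
    g = SimilarityGraph(gamma=0.0)
    g.add_edge("a", "b", 0.6)
    g.add_edge("b", "c", 0.7)
    g.add_edge("a", "c", 0.8)
    return g


@pytest.fixture
def two_triangles() -> SimilarityGraph:
    g = SimilarityGraph(gamma=0.0)
    for u, v in [("a", "b"), ("b", "c"), ("a", "c")]:
        g.add_edge(u, v, 0.9)
    for u, v in [("x", "y"), ("y", "z"), ("x", "z")]:
        g.add_edge(u, v, 0.8)
    return g
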