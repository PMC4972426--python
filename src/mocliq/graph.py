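"""Weighted undirected similarity graphs.

The graph is the substrate for all clustering steps: nodes are motif (or
arbitrary) identifiers, edges carry similarity weights, and every stored
edge weight is at least the construction cutoff ``gamma``.  Storage is an
adjacency map, which keeps neighbor queries O(degree) on the sparse graphs
this package targets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityGraph",
    "NeighborhoodSubgraph",
    "EdgeListParseError",
    "UnknownNodeError",
    "read_edge_list",
    "write_edge_list",
    "neighborhood",
    "weight_sum",
    "read_clusters",
    "write_clusters",
]


class EdgeListParseError(ValueError):
    """A line of an edge-list file could not be parsed or failed validation."""


class UnknownNodeError(KeyError):
    """A node identifier was queried that is not present in the graph."""


class SimilarityGraph:
    """Undirected weighted graph with a similarity cutoff ``gamma``.

    Invariants: no self-loops, symmetric weights (one logical entry per
    unordered pair), and every stored weight >= ``gamma``.  Node ids are
    opaque strings.
    """

    __slots__ = ("gamma", "_adj")

    def __init__(self, gamma: float = 0.0) -> None:
        if not (0.0 <= gamma <= 1.0):
            raise ValueError(f"gamma must be in [0, 1], got {gamma}")
        self.gamma = float(gamma)
        self._adj: dict[str, dict[str, float]] = {}

    # -- construction -------------------------------------------------

    def add_node(self, v: str) -> None:
        self._adj.setdefault(v, {})

    def add_edge(self, u: str, v: str, weight: float) -> None:
        if u == v:
            raise ValueError(f"self-loop on node {u!r} is not allowed")
        w = float(weight)
        if not math.isfinite(w) or w < 0:
            raise ValueError(f"edge weight must be a finite nonnegative number, got {weight!r}")
        if w < self.gamma:
            raise ValueError(f"edge weight {w} is below the graph cutoff gamma={self.gamma}")
        self._adj.setdefault(u, {})[v] = w
        self._adj.setdefault(v, {})[u] = w

    # -- queries ------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self._adj)

    def __contains__(self, v: str) -> bool:
        return v in self._adj

    def __len__(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def _require(self, v: str) -> None:
        if v not in self._adj:
            raise UnknownNodeError(v)

    def neighbors(self, v: str) -> dict[str, float]:
        """Map neighbor -> edge weight for ``v`` (a copy; safe to mutate)."""
        self._require(v)
        return dict(self._adj[v])

    def degree(self, v: str) -> int:
        self._require(v)
        return len(self._adj[v])

    def has_edge(self, u: str, v: str) -> bool:
        return u in self._adj and v in self._adj[u]

    def weight(self, u: str, v: str) -> float:
        self._require(u)
        self._require(v)
        try:
            return self._adj[u][v]
        except KeyError:
            raise UnknownNodeError(f"no edge between {u!r} and {v!r}") from None

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Iterate unordered edges once each, in sorted (u, v) order."""
        for u in sorted(self._adj):
            for v in sorted(self._adj[u]):
                if u < v:
                    yield u, v, self._adj[u][v]

    def isolated_nodes(self) -> set[str]:
        return {v for v, nbrs in self._adj.items() if not nbrs}

    def weight_sum(self, nodes: Iterable[str]) -> float:
        """Sum of weights of edges with both endpoints in ``nodes``.

        Empty and singleton sets sum to 0.  Raises ``UnknownNodeError`` for
        members absent from the graph.
        """
        ns = set(nodes)
        for v in ns:
            self._require(v)
        total = 0.0
        for u in sorted(ns):
            adj_u = self._adj[u]
            for x in sorted(adj_u):
                if u < x and x in ns:
                    total += adj_u[x]
        return total

    def induced_edges(self, nodes: Iterable[str]) -> dict[tuple[str, str], float]:
        """Edges of the subgraph induced by ``nodes`` keyed by sorted pair."""
        ns = set(nodes)
        for v in ns:
            self._require(v)
        out: dict[tuple[str, str], float] = {}
        for u in ns:
            for x, w in self._adj[u].items():
                if x in ns and u < x:
                    out[(u, x)] = w
        return out


@dataclass(frozen=True)
class NeighborhoodSubgraph:
    """The subgraph induced by a center node and all of its neighbors."""

    center: str
    members: frozenset[str]
    edges: dict[tuple[str, str], float]

    def has_edge(self, u: str, v: str) -> bool:
        return ((u, v) if u < v else (v, u)) in self.edges


def neighborhood(g: SimilarityGraph, v: str) -> NeighborhoodSubgraph:
    """Extract the induced subgraph on ``v`` and its neighbors."""
    g._require(v)
    members = frozenset(g._adj[v]) | {v}
    return NeighborhoodSubgraph(center=v, members=members, edges=g.induced_edges(members))


def weight_sum(g: SimilarityGraph, nodes: Iterable[str]) -> float:
    return g.weight_sum(nodes)


def read_edge_list(
    path: str | Path,
    gamma: float = 0.0,
    keep_isolated: bool = False,
) -> SimilarityGraph:
    """Read a 3-column whitespace-separated edge list (node node weight).

    ``#``-prefixed lines and blank lines are ignored; columns past the third
    are ignored.  Self-loops are dropped.  Duplicate unordered pairs keep the
    maximum weight (a warning is logged).  Only edges with weight >= ``gamma``
    are stored; nodes left with no surviving edge are kept as isolated nodes
    only when ``keep_isolated`` is true.
    """
    raw: dict[tuple[str, str], float] = {}
    seen_nodes: set[str] = set()
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.split()
            if len(parts) < 3:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected 3 columns (node node weight), got {len(parts)}"
                )
            u, v, wtext = parts[0], parts[1], parts[2]
            try:
                w = float(wtext)
            except ValueError:
                raise EdgeListParseError(f"{path}:{lineno}: non-numeric weight {wtext!r}") from None
            if not math.isfinite(w) or w < 0:
                raise EdgeListParseError(f"{path}:{lineno}: invalid weight {wtext!r} (must be finite and >= 0)")
            seen_nodes.add(u)
            seen_nodes.add(v)
            if u == v:
                continue  # self-loops carry no similarity information
            key = (u, v) if u < v else (v, u)
            if key in raw:
                logger.warning(
                    "%s:%d: duplicate edge %s-%s; keeping max weight %g",
                    path, lineno, key[0], key[1], max(raw[key], w),
                )
                raw[key] = max(raw[key], w)
            else:
                raw[key] = w
    g = SimilarityGraph(gamma=gamma)
    for (u, v), w in raw.items():
        if w >= gamma:
            g.add_edge(u, v, w)
    if keep_isolated:
        for v in seen_nodes:
            g.add_node(v)
    return g


def write_edge_list(g: SimilarityGraph, path: str | Path) -> None:
    """Write the graph as a 3-column edge list.

    Weights are printed with ``repr`` so that a read-back round-trips to the
    identical float.
    """
    with Path(path).open("w") as fh:
        for u, v, w in g.edges():
            fh.write(f"{u}\t{v}\t{w!r}\n")


def write_clusters(clusters: Sequence[Iterable[str]], path: str | Path) -> None:
    """One cluster per line in given (rank) order, tab-separated sorted ids."""
    with Path(path).open("w") as fh:
        for members in clusters:
            fh.write("\t".join(sorted(members)) + "\n")


def read_clusters(path: str | Path) -> list[list[str]]:
    out: list[list[str]] = []
    with Path(path).open() as fh:
        for line in fh:
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            out.append(text.split("\t"))
    return out
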