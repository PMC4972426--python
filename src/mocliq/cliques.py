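"""Per-node greedy maximal-clique discovery (pipeline step 1).

For each node ``v`` a single maximal clique of the neighborhood subgraph
N(v) is found by a three-phase greedy procedure:

(a) start from C_v = N(v); if it is already complete, stop.  Otherwise sort
    the neighbors of ``v`` ascending by the weight of their edge to ``v``.
(b) delete neighbors in that order (each deletion removes the node and its
    incident edges) until every remaining node has degree |C_v| - 1, i.e.
    C_v is complete; record the deleted nodes u_1..u_k.
(c) re-examine the deleted nodes in reverse order u_{k-1}..u_1 (the last
    deletion u_k completed the clique and is never reconsidered), adding a
    node back iff it is adjacent to every current member.

The result favors nodes most similar to ``v`` over sheer clique size, runs
in O(degree^2) per node, and is deterministic: sort ties are broken by
ascending node id.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Sequence

from .graph import SimilarityGraph, UnknownNodeError

__all__ = ["Clique", "find_associated_clique", "find_all_cliques", "dedupe_cliques",
           "neighbor_scan_order"]


@dataclass(frozen=True)
class Clique:
    """A complete subgraph found by the greedy search seeded at ``seed``."""

    seed: str
    members: frozenset[str]
    weight_sum: float

    def __len__(self) -> int:
        return len(self.members)


def neighbor_scan_order(g: SimilarityGraph, v: str) -> list[str]:
    """Neighbors of ``v`` ascending by edge weight to ``v``, ties by node id."""
    if v not in g:
        raise UnknownNodeError(v)
    nbrs = g._adj[v]
    return sorted(nbrs, key=lambda u: (nbrs[u], u))


def find_associated_clique(g: SimilarityGraph, v: str) -> Clique:
    """Find the maximal clique associated with ``v`` within N(v)."""
    if v not in g:
        raise UnknownNodeError(v)
    adj = g._adj
    members: set[str] = set(adj[v])
    members.add(v)

    # degree of each member within the current induced subgraph
    deg = {x: sum(1 for y in adj[x] if y in members) for x in members}

    def complete() -> bool:
        target = len(members) - 1
        return all(d == target for d in deg.values())

    if complete():
        return Clique(seed=v, members=frozenset(members), weight_sum=g.weight_sum(members))

    deleted: list[str] = []
    for u in neighbor_scan_order(g, v):
        members.remove(u)
        del deg[u]
        for y in adj[u]:
            if y in deg:
                deg[y] -= 1
        deleted.append(u)
        if complete():
            break

    # phase (c): u_k (the final deletion) is excluded from re-examination
    for u in deleted[-2::-1]:
        adj_u = adj[u]
        if all(x in adj_u for x in members):
            members.add(u)

    return Clique(seed=v, members=frozenset(members), weight_sum=g.weight_sum(members))


def find_all_cliques(g: SimilarityGraph, workers: int = 1) -> list[Clique]:
    """One clique per node, ordered by seed id; identical for any ``workers``.

    Worker count is purely an execution knob: per-node searches are
    independent and results are collected in canonical seed order.
    """
    if workers < 1:
        raise ValueError(f"workers must be >= 1, got {workers}")
    seeds = sorted(g.nodes)
    if workers == 1 or len(seeds) < 2:
        return [find_associated_clique(g, v) for v in seeds]
    with ThreadPoolExecutor(max_workers=workers) as pool:
        return list(pool.map(lambda v: find_associated_clique(g, v), seeds))


def dedupe_cliques(cliques: Sequence[Clique]) -> list[Clique]:
    """Collapse exact-duplicate member sets, keeping the first occurrence.

    Proper subsets are retained: only identical member sets are redundant.
    """
    seen: set[frozenset[str]] = set()
    out: list[Clique] = []
    for c in cliques:
        if c.members not in seen:
            seen.add(c.members)
            out.append(c)
    return out
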