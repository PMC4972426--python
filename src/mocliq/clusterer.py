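"""Clique ranking, merging, redundancy removal and cluster ranking (steps 2-4).

Step 2 ranks the deduplicated cliques by descending internal edge-weight sum
and sweeps the queue: each still-unmerged clique seeds a cluster, and every
later unmerged clique is folded in when it overlaps the cluster enough
(alpha) and enough of its nodes touch the cluster (beta).  Step 3 resolves
nodes landing in several clusters by keeping each node only where its
incident edge-weight sum is largest.  Step 4 re-ranks the now-disjoint
clusters by induced edge-weight sum.

All tie-breaks are explicit and deterministic, and the result is independent
of the worker count used for clique finding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .cliques import Clique, dedupe_cliques, find_all_cliques
from .graph import SimilarityGraph

__all__ = ["Cluster", "ClimpConfig", "sort_cliques", "can_merge", "merge_cliques",
           "remove_redundant_nodes", "rank_clusters", "climp"]


@dataclass(frozen=True)
class Cluster:
    rank: int
    members: frozenset[str]
    source_cliques: tuple[int, ...]
    weight_sum: float

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ClimpConfig:
    """Clustering parameters.

    alpha: minimum fraction of a candidate clique's nodes already inside the
        cluster.  beta: minimum fraction of its nodes inside or adjacent to
        the cluster.  Requires alpha <= beta.  gamma is the similarity cutoff
        used when building graphs.  merge_target selects whether the merge
        test compares against the accumulated cluster (default) or only the
        seed clique.
    """

    alpha: float = 0.5
    beta: float = 0.5
    gamma: float = 0.6
    workers: int = 1
    merge_target: str = "cluster"  # or "seed"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not (0.0 < self.beta <= 1.0):
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")
        if self.alpha > self.beta:
            raise ValueError(f"alpha must be <= beta, got alpha={self.alpha} beta={self.beta}")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.workers < 1:
            raise ValueError(f"workers must be >= 1, got {self.workers}")
        if self.merge_target not in ("cluster", "seed"):
            raise ValueError(f"merge_target must be 'cluster' or 'seed', got {self.merge_target!r}")


def _clique_sort_key(c: Clique):
    # descending weight sum, then larger member count, then smallest member id
    return (-c.weight_sum, -len(c.members), min(c.members))


def sort_cliques(cliques: Sequence[Clique]) -> list[Clique]:
    """Rank cliques descending by edge-weight sum (deterministic tie-breaks)."""
    return sorted(cliques, key=_clique_sort_key)


def can_merge(current: frozenset[str] | set[str], cj: Clique, g: SimilarityGraph,
              cfg: ClimpConfig) -> bool:
    """Overlap and adjacency test for folding clique ``cj`` into a cluster.

    Overlap ratio: |current & cj| / |cj| >= alpha.  Adjacency ratio: the
    fraction of cj's nodes that are inside ``current`` or have at least one
    graph edge into it must be >= beta.  A cj node already inside the cluster
    counts as adjacent, which guarantees the beta ratio is never below the
    alpha ratio (consistent with alpha <= beta).
    """
    size = len(cj.members)
    if size == 0:
        raise ValueError("cannot merge an empty clique")
    overlap = sum(1 for x in cj.members if x in current)
    if overlap / size < cfg.alpha:
        return False
    adj = g._adj
    touching = sum(
        1 for x in cj.members
        if x in current or any(y in current for y in adj.get(x, ()))
    )
    return touching / size >= cfg.beta


def merge_cliques(queue: Sequence[Clique], g: SimilarityGraph, cfg: ClimpConfig) -> list[Cluster]:
    """Sequential queue sweep: every clique ends up in exactly one cluster.

    For ascending i, an unmerged clique seeds a cluster; for ascending
    j > i, an unmerged clique is folded in when :func:`can_merge` passes
    against the cluster's current member set (or the seed clique when
    ``cfg.merge_target == 'seed'``).  This is the reference semantics any
    parallel execution must reproduce bit-identically.
    """
    n = len(queue)
    merged = [False] * n
    clusters: list[Cluster] = []
    for i in range(n):
        if merged[i]:
            continue
        merged[i] = True
        members = set(queue[i].members)
        sources = [i]
        for j in range(i + 1, n):
            if merged[j]:
                continue
            target = members if cfg.merge_target == "cluster" else queue[i].members
            if can_merge(target, queue[j], g, cfg):
                members |= queue[j].members
                sources.append(j)
                merged[j] = True
        clusters.append(
            Cluster(
                rank=len(clusters) + 1,
                members=frozenset(members),
                source_cliques=tuple(sources),
                weight_sum=g.weight_sum(members),
            )
        )
    return clusters


def _incident_sums(cluster: Cluster, g: SimilarityGraph) -> dict[str, float]:
    """Per-node incident edge-weight sum within the cluster's induced subgraph."""
    members = cluster.members
    adj = g._adj
    return {
        x: sum(w for y, w in adj[x].items() if y in members)
        for x in members
    }


def remove_redundant_nodes(clusters: Sequence[Cluster], g: SimilarityGraph) -> list[Cluster]:
    """Keep each multiply-assigned node only in its best cluster (step 3).

    All incident sums are computed on the incoming memberships first; a node
    is then retained in the cluster where its incident edge-weight sum is
    maximal, ties going to the higher-ranked (earlier) cluster.  Clusters
    emptied by the deletions are dropped.  Idempotent on disjoint input.
    """
    sums = [_incident_sums(c, g) for c in clusters]
    owner: dict[str, int] = {}
    best: dict[str, float] = {}
    for idx, s in enumerate(sums):
        for node, val in s.items():
            if node not in owner or val > best[node]:
                owner[node] = idx
                best[node] = val
    out: list[Cluster] = []
    for idx, c in enumerate(clusters):
        kept = frozenset(x for x in c.members if owner[x] == idx)
        if not kept:
            continue
        out.append(
            Cluster(
                rank=len(out) + 1,
                members=kept,
                source_cliques=c.source_cliques,
                weight_sum=g.weight_sum(kept),
            )
        )
    return out


def _cluster_sort_key(c: Cluster):
    return (-c.weight_sum, -len(c.members), min(c.members))


def rank_clusters(clusters: Sequence[Cluster], g: SimilarityGraph) -> list[Cluster]:
    """Recompute induced weight sums and sort descending; ranks become 1..m."""
    rescored = [replace(c, weight_sum=g.weight_sum(c.members)) for c in clusters]
    ordered = sorted(rescored, key=_cluster_sort_key)
    return [replace(c, rank=i + 1) for i, c in enumerate(ordered)]


def climp(g: SimilarityGraph, cfg: ClimpConfig | None = None) -> list[Cluster]:
    """Full pipeline: cliques -> dedupe -> sort -> merge -> dedupe nodes -> rank."""
    cfg = cfg or ClimpConfig()
    cliques = find_all_cliques(g, workers=cfg.workers)
    queue = sort_cliques(dedupe_cliques(cliques))
    clusters = merge_cliques(queue, g, cfg)
    clusters = remove_redundant_nodes(clusters, g)
    return rank_clusters(clusters, g)
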