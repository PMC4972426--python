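"""Seeded generators for end-to-end testing without external data.

Three generators cover the benchmark designs used throughout the package:
random motif families with tunable conservation, the split of a motif's n
sites into complementary sub-motif pairs of sizes k and n-k for every
k = 1..floor(n/2) (yielding exactly 2*floor(n/2) sub-motifs whose truth
label is the parent motif), and planted-partition weighted graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .graph import SimilarityGraph
from .similarity import BASES, Motif, MotifError

__all__ = ["SplitSpec", "PlantedGraphSpec", "split_motif", "random_motif_family",
           "planted_partition_graph"]


@dataclass(frozen=True)
class SplitSpec:
    """Seed for the site-splitting RNG."""

    seed: int = 0


@dataclass(frozen=True)
class PlantedGraphSpec:
    """Block sizes plus intra/inter edge probabilities and weight supports."""

    block_sizes: tuple[int, ...]
    p_intra: float = 0.9
    p_inter: float = 0.02
    w_intra: tuple[float, float] = (0.6, 1.0)
    w_inter: tuple[float, float] = (0.4, 0.6)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.block_sizes or any(s < 1 for s in self.block_sizes):
            raise ValueError("block_sizes must be positive")
        for p in (self.p_intra, self.p_inter):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"edge probability must be in [0, 1], got {p}")
        for lo, hi in (self.w_intra, self.w_inter):
            if not (0.0 < lo <= hi <= 1.0):
                raise ValueError(f"weight support must lie within (0, 1], got ({lo}, {hi})")


def split_motif(m: Motif, spec: SplitSpec | int = 0) -> list[Motif]:
    """All complementary (k, n-k) site splits of a motif, k = 1..floor(n/2).

    Each k yields two disjoint sub-motifs covering the parent's n sites (a
    uniform random k-subset and its complement), so a motif with n sites
    produces exactly 2*floor(n/2) sub-motifs.  Sub-motif ids encode the
    parent and split; ``parent`` carries the truth label.
    """
    if m.sites is None or m.n_sites < 2:
        raise MotifError(f"motif {m.id!r}: need at least 2 sites to split")
    seed = spec.seed if isinstance(spec, SplitSpec) else int(spec)
    rng = np.random.default_rng(seed)
    n = len(m.sites)
    out: list[Motif] = []
    for k in range(1, n // 2 + 1):
        chosen = rng.choice(n, size=k, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[chosen] = True
        part_a = [m.sites[i] for i in range(n) if mask[i]]
        part_b = [m.sites[i] for i in range(n) if not mask[i]]
        out.append(Motif.from_sites(f"{m.id}/k{k}a", part_a, parent=m.id))
        out.append(Motif.from_sites(f"{m.id}/k{k}b", part_b, parent=m.id))
    return out


def random_motif_family(n_motifs: int, length: int, sites_per_motif: int,
                        conservation: float, seed: int = 0) -> list[Motif]:
    """Motifs drawn around independent random consensus sequences.

    Each site copies its consensus base with probability ``conservation`` and
    otherwise picks uniformly among the three other bases.
    """
    if n_motifs < 1 or length < 1 or sites_per_motif < 1:
        raise ValueError("n_motifs, length and sites_per_motif must be positive")
    if not (0.0 < conservation <= 1.0):
        raise ValueError(f"conservation must be in (0, 1], got {conservation}")
    rng = np.random.default_rng(seed)
    width = len(str(n_motifs - 1))
    motifs: list[Motif] = []
    for idx in range(n_motifs):
        consensus = rng.integers(0, 4, size=length)
        sites: list[str] = []
        for _ in range(sites_per_motif):
            bases = consensus.copy()
            flip = rng.random(length) >= conservation
            if flip.any():
                # replacement base drawn uniformly from the three alternatives
                shift = rng.integers(1, 4, size=int(flip.sum()))
                bases[flip] = (bases[flip] + shift) % 4
            sites.append("".join(BASES[b] for b in bases))
        motifs.append(Motif.from_sites(f"M{idx:0{width}d}", sites))
    return motifs


def planted_partition_graph(spec: PlantedGraphSpec) -> tuple[SimilarityGraph, dict[str, str]]:
    """Weighted random graph with known blocks, plus the truth partition.

    Every node is present in the graph (possibly isolated).  Edges are
    sampled independently per unordered pair with the intra/inter
    probability and weight distribution of the spec.
    """
    rng = np.random.default_rng(spec.seed)
    nodes: list[str] = []
    block_of: dict[str, str] = {}
    for b, size in enumerate(spec.block_sizes):
        for i in range(size):
            node = f"b{b}_n{i}"
            nodes.append(node)
            block_of[node] = f"b{b}"
    g = SimilarityGraph(gamma=0.0)
    for node in nodes:
        g.add_node(node)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            intra = block_of[u] == block_of[v]
            p = spec.p_intra if intra else spec.p_inter
            lo, hi = spec.w_intra if intra else spec.w_inter
            if rng.random() < p:
                g.add_edge(u, v, lo + (hi - lo) * rng.random())
    return g, block_of
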