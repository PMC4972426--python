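import pytest

from mocliq.cliques import Clique, dedupe_cliques, find_all_cliques
from mocliq.clusterer import (
    ClimpConfig,
    Cluster,
    can_merge,
    climp,
    merge_cliques,
    rank_clusters,
    remove_redundant_nodes,
    sort_cliques,
)
from mocliq.graph import SimilarityGraph

from conftest import random_weighted_graph


def clique(members, weight_sum=0.0, seed=None):
    return Clique(seed=seed or min(members), members=frozenset(members), weight_sum=weight_sum)


def cluster(members, rank=1, weight_sum=0.0):
    return Cluster(rank=rank, members=frozenset(members), source_cliques=(), weight_sum=weight_sum)


class TestConfig:
    def test_alpha_gt_beta_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            ClimpConfig(alpha=0.9, beta=0.1)

    @pytest.mark.parametrize("kwargs", [
        {"alpha": 0.0}, {"beta": 1.5}, {"gamma": -0.1}, {"workers": 0},
        {"merge_target": "bogus"},
    ])
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ClimpConfig(**kwargs)


class TestSortCliques:
    def test_descending_by_weight_sum(self):
        cliques = [clique({"a", "b"}, 2.1), clique({"c", "d"}, 3.0), clique({"e"}, 0.0)]
        assert [c.weight_sum for c in sort_cliques(cliques)] == [3.0, 2.1, 0.0]

    def test_tie_larger_size_first(self):
        small = clique({"x", "y"}, 1.0)
        big = clique({"a", "b", "c"}, 1.0)
        assert sort_cliques([small, big]) == [big, small]

    def test_tie_smallest_member_id(self):
        c1 = clique({"m", "n"}, 1.0)
        c2 = clique({"a", "z"}, 1.0)
        assert sort_cliques([c1, c2]) == [c2, c1]

    def test_empty(self):
        assert sort_cliques([]) == []


@pytest.fixture
def merge_graph():
    """Cliques {1,2,3,4}, {3,4,5}, {5,6}; extra edge 5-1 for adjacency."""
    g = SimilarityGraph()
    for u, v in [("1", "2"), ("1", "3"), ("1", "4"), ("2", "3"), ("2", "4"), ("3", "4")]:
        g.add_edge(u, v, 0.9)
    g.add_edge("3", "5", 0.8)
    g.add_edge("4", "5", 0.8)
    g.add_edge("5", "6", 0.7)
    g.add_edge("5", "1", 0.65)
    return g


class TestCanMerge:
    def test_overlap_and_adjacency_pass(self, merge_graph):
        cfg = ClimpConfig(alpha=0.5, beta=0.5, gamma=0.0)
        # overlap 2/3, adjacency 3/3 (node 5 reaches the cluster via edge 5-1)
        assert can_merge({"1", "2", "3", "4"}, clique({"3", "4", "5"}), merge_graph, cfg)

    def test_subset_always_merges(self, merge_graph):
        cfg = ClimpConfig(alpha=1.0, beta=1.0, gamma=0.0)
        assert can_merge({"1", "2", "3", "4"}, clique({"3", "4"}), merge_graph, cfg)

    def test_disjoint_without_edges_fails(self):
        g = SimilarityGraph()
        g.add_edge("1", "2", 0.9)
        g.add_edge("8", "9", 0.9)
        cfg = ClimpConfig(alpha=0.5, beta=0.5, gamma=0.0)
        assert not can_merge({"1", "2"}, clique({"8", "9"}), g, cfg)

    def test_empty_clique_rejected(self, merge_graph):
        with pytest.raises(ValueError):
            can_merge({"1"}, Clique(seed="x", members=frozenset(), weight_sum=0.0),
                      merge_graph, ClimpConfig())


class TestMergeCliques:
    def test_manual_queue_trace(self, merge_graph):
        # hand-executed sweep: {3,4,5} folds into {1,2,3,4} (overlap 2/3,
        # adjacency 3/3), then {5,6} folds into the grown cluster (overlap
        # 1/2, node 6 adjacent to 5)
        queue = sort_cliques([
            clique({"1", "2", "3", "4"}, merge_graph.weight_sum({"1", "2", "3", "4"})),
            clique({"3", "4", "5"}, merge_graph.weight_sum({"3", "4", "5"})),
            clique({"5", "6"}, merge_graph.weight_sum({"5", "6"})),
        ])
        cfg = ClimpConfig(alpha=0.5, beta=0.5, gamma=0.0)
        clusters = merge_cliques(queue, merge_graph, cfg)
        assert len(clusters) == 1
        assert clusters[0].members == {"1", "2", "3", "4", "5", "6"}
        assert clusters[0].source_cliques == (0, 1, 2)

    def test_seed_target_variant_stops_growth(self, merge_graph):
        # against the seed clique only, {5,6} overlaps 0/2 and stays separate
        queue = sort_cliques([
            clique({"1", "2", "3", "4"}, merge_graph.weight_sum({"1", "2", "3", "4"})),
            clique({"3", "4", "5"}, merge_graph.weight_sum({"3", "4", "5"})),
            clique({"5", "6"}, merge_graph.weight_sum({"5", "6"})),
        ])
        cfg = ClimpConfig(alpha=0.5, beta=0.5, gamma=0.0, merge_target="seed")
        clusters = merge_cliques(queue, merge_graph, cfg)
        assert [c.members for c in clusters] == [
            frozenset({"1", "2", "3", "4", "5"}), frozenset({"5", "6"})]

    def test_non_mergeable_queue_preserves_order(self, two_triangles):
        queue = sort_cliques(dedupe_cliques(find_all_cliques(two_triangles)))
        clusters = merge_cliques(queue, two_triangles, ClimpConfig(alpha=0.5, beta=0.5))
        assert [c.members for c in clusters] == [q.members for q in queue]

    def test_every_clique_assigned_once(self):
        g = random_weighted_graph(seed=3, n_max=25)
        queue = sort_cliques(dedupe_cliques(find_all_cliques(g)))
        clusters = merge_cliques(queue, g, ClimpConfig(alpha=0.5, beta=0.5))
        assigned = [i for c in clusters for i in c.source_cliques]
        assert sorted(assigned) == list(range(len(queue)))


class TestRemoveRedundantNodes:
    def test_node_kept_where_incident_sum_larger(self):
        g = SimilarityGraph()
        g.add_edge("x", "a1", 0.8)
        g.add_edge("x", "a2", 0.7)
        g.add_edge("a1", "a2", 0.9)
        g.add_edge("x", "b1", 0.9)
        clusters = [cluster({"x", "a1", "a2"}, rank=1), cluster({"x", "b1"}, rank=2)]
        out = remove_redundant_nodes(clusters, g)
        # incident sums: 1.5 in cluster A vs 0.9 in cluster B
        assert out[0].members == {"x", "a1", "a2"}
        assert out[1].members == {"b1"}

    def test_tie_goes_to_higher_ranked_cluster(self):
        g = SimilarityGraph()
        g.add_edge("x", "a", 0.5)
        g.add_edge("x", "b", 0.5)
        clusters = [cluster({"x", "a"}, rank=1), cluster({"x", "b"}, rank=2)]
        out = remove_redundant_nodes(clusters, g)
        assert out[0].members == {"x", "a"}
        assert out[1].members == {"b"}

    def test_disjoint_unchanged(self, two_triangles):
        clusters = [cluster({"a", "b", "c"}, rank=1), cluster({"x", "y", "z"}, rank=2)]
        out = remove_redundant_nodes(clusters, two_triangles)
        assert [c.members for c in out] == [c.members for c in clusters]

    def test_emptied_cluster_dropped(self):
        g = SimilarityGraph()
        g.add_edge("x", "a", 0.9)
        g.add_edge("x", "y", 0.1)
        g.add_edge("y", "a", 0.9)
        clusters = [cluster({"x", "y", "a"}, rank=1), cluster({"x", "y"}, rank=2)]
        out = remove_redundant_nodes(clusters, g)
        assert len(out) == 1
        assert out[0].members == {"x", "y", "a"}

    @pytest.mark.parametrize("seed", range(5))
    def test_result_disjoint_and_idempotent(self, seed):
        g = random_weighted_graph(seed, n_max=25)
        queue = sort_cliques(dedupe_cliques(find_all_cliques(g)))
        merged = merge_cliques(queue, g, ClimpConfig(alpha=0.5, beta=0.5))
        once = remove_redundant_nodes(merged, g)
        seen = set()
        for c in once:
            assert not (c.members & seen)
            seen |= c.members
        twice = remove_redundant_nodes(once, g)
        assert [c.members for c in twice] == [c.members for c in once]
        assert [c.weight_sum for c in twice] == [c.weight_sum for c in once]


class TestRankClusters:
    def test_descending_ranks(self, two_triangles):
        clusters = [cluster({"x", "y"}, rank=1), cluster({"a", "b", "c"}, rank=2)]
        out = rank_clusters(clusters, two_triangles)
        assert [c.rank for c in out] == [1, 2]
        assert out[0].members == {"a", "b", "c"}  # weight 2.7 beats 0.8
        assert out[0].weight_sum == pytest.approx(2.7)

    def test_single_cluster_rank_one(self, triangle_graph):
        out = rank_clusters([cluster({"a", "b", "c"})], triangle_graph)
        assert [c.rank for c in out] == [1]

    def test_tie_larger_cluster_first(self):
        g = SimilarityGraph()
        g.add_edge("a", "b", 0.3)
        g.add_edge("a", "c", 0.3)
        g.add_edge("x", "y", 0.6)
        out = rank_clusters([cluster({"x", "y"}), cluster({"a", "b", "c"})], g)
        assert out[0].members == {"a", "b", "c"}


class TestClimp:
    def test_two_disjoint_triangles(self, two_triangles):
        clusters = climp(two_triangles, ClimpConfig(alpha=0.5, beta=0.5, gamma=0.0))
        assert [c.members for c in clusters] == [
            frozenset({"a", "b", "c"}), frozenset({"x", "y", "z"})]
        assert [c.rank for c in clusters] == [1, 2]

    def test_empty_graph(self):
        assert climp(SimilarityGraph(), ClimpConfig()) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_node_conservation(self, seed):
        g = random_weighted_graph(seed, n_max=25)
        clusters = climp(g, ClimpConfig(alpha=0.5, beta=0.5, gamma=0.0))
        assigned = [x for c in clusters for x in c.members]
        assert sorted(assigned) == sorted(g.nodes)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_ranking(self, seed):
        g = random_weighted_graph(seed, n_max=25)
        clusters = climp(g, ClimpConfig(alpha=0.5, beta=0.5, gamma=0.0))
        sums = [c.weight_sum for c in clusters]
        assert sums == sorted(sums, reverse=True)
        assert [c.rank for c in clusters] == list(range(1, len(clusters) + 1))

    def test_alpha_beta_one_degenerate(self):
        # two triangles sharing an edge: neither clique contains the other,
        # so at alpha=beta=1 nothing merges and the shared nodes go to one side
        g = SimilarityGraph()
        for u, v, w in [("a", "b", 0.9), ("a", "c", 0.9), ("b", "c", 0.9),
                        ("b", "d", 0.5), ("c", "d", 0.5)]:
            g.add_edge(u, v, w)
        clusters = climp(g, ClimpConfig(alpha=1.0, beta=1.0, gamma=0.0))
        assert clusters[0].members == {"a", "b", "c"}
        assert clusters[1].members == {"d"}

    @pytest.mark.parametrize("seed", range(3))
    def test_workers_bit_identical(self, seed):
        g = random_weighted_graph(seed, n_max=25)
        base = climp(g, ClimpConfig(alpha=0.5, beta=0.5, gamma=0.0, workers=1))
        for workers in (2, 4, 8):
            assert climp(g, ClimpConfig(alpha=0.5, beta=0.5, gamma=0.0, workers=workers)) == base
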