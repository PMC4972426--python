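# mocliq

Motif clustering on weighted similarity graphs via per-node greedy maximal
cliques, plus the surrounding toolkit: an information-content-weighted motif
similarity metric, adjusted-Rand-index evaluation, and seeded synthetic
benchmark generators.

## What it does

Given a weighted undirected similarity graph (nodes = motifs, edge weights =
pairwise similarity scores in (0, 1]), the clustering pipeline runs four
steps:

1. **Cliques** — for every node, a greedy search finds one maximal clique of
   its neighborhood subgraph, preferring the neighbors most similar to the
   seed node (O(degree²) per node).
2. **Merge** — deduplicated cliques are ranked by internal edge-weight sum
   and swept in order; a later clique folds into a growing cluster when its
   overlap fraction is ≥ `alpha` and the fraction of its nodes touching the
   cluster is ≥ `beta` (`alpha ≤ beta`).
3. **Redundancy removal** — a node landing in several clusters is kept only
   where its incident edge-weight sum is largest, making clusters disjoint.
4. **Ranking** — clusters are re-scored on their induced subgraphs and
   sorted by descending edge-weight sum.

The result is deterministic: all tie-breaks are explicit and the output is
bit-identical for any worker count.

Motif collections (binding-site FASTA files or 4×L count-matrix files) can
be turned into a similarity graph with the built-in metric: per-column
information-content-weighted cross-likelihoods, maximized over ungapped
offsets and both strands, normalized so self-similarity is exactly 1. The
metric is pluggable — precomputed similarity edge lists from any external
scorer are accepted as-is.

## CLI

```sh
# similarity graph from motif files (FASTA sites or count matrices)
mocliq similarity motifs/*.fa --gamma 0.6 --out edges.abc

# cluster an edge list (3 columns: node node weight)
mocliq cluster edges.abc --alpha 0.5 --beta 0.5 --gamma 0.6 --out clusters.tsv

# evaluate against truth labels (2-column TSV: node, label)
mocliq eval clusters.tsv truth.tsv --known known_ids.txt

# seeded synthetic fixtures: motif families, site splits, planted graphs
mocliq simulate --kind split --n-motifs 10 --sites 20 --seed 1 --outdir fixtures/
mocliq simulate --kind graph --blocks 5 --block-size 20 --seed 1 --outdir fixtures/
```

Defaults are `alpha=0.5`, `beta=0.5`, `gamma=0.6`. Every command writes a
`*.manifest.json` sidecar recording the resolved configuration. Cluster
files contain one cluster per line (tab-separated ids, rank order);
single-node clusters are suppressed unless `--keep-singletons` is given.

## Library

```python
import mocliq as mq

g = mq.read_edge_list("edges.abc", gamma=0.6)
clusters = mq.climp(g, mq.ClimpConfig(alpha=0.5, beta=0.5))
score = mq.ari(truth_labels, {x: c.rank for c in clusters for x in c.members})
```

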