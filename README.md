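# pullnet

Network analysis of affinity-purification mass-spectrometry (IP-MS) hit
lists. An IP-MS pull-down of a bait protein yields a list of candidate
interactors contaminated by nonspecific binders; `pullnet` asks the
standard follow-up questions against a literature-compiled
protein-protein interaction (PPI) background:

1. **Do the hits interact with each other more than chance allows?**
   The hit-list-induced subnetwork's edge count is compared to the
   distribution of edge counts among `n` uniformly drawn random protein
   sets of the same size, giving the empirical p-value
   `p = (1 + #{null ≥ observed}) / (n + 1)`.
2. **Is that density just a few promiscuous hubs?** The degree
   distribution of the hits is compared to the whole background's by a
   two-sample Kolmogorov–Smirnov test.
3. **Which complexes do the hits form?** Communities of the induced
   subnetwork are found by greedy agglomerative modularity maximization:
   starting from singletons, repeatedly merge the connected community
   pair with the largest gain in modularity
   `Q = Σᵢ (eᵢᵢ − aᵢ²)`,
   where `eᵢᵢ` is the fraction of edges inside community *i* and `aᵢ`
   the fraction of edge ends attached to it, and keep the maximum-Q
   partition along the merge path.
4. **What do the list and each community do?** One-sided Fisher exact
   (hypergeometric upper-tail) enrichment against GMT gene-set libraries
   (GO, CORUM-style complexes, pathways), with Benjamini–Hochberg
   adjustment per library, plus a plain disease-gene membership lookup.
5. **Do two screens replicate?** The overlap of two hit lists (after
   optional ortholog mapping) is Fisher-tested against a configurable
   universe (default 20,000, protein-coding genome scale).

Synthetic generators (planted-partition networks, hub-containing
backgrounds, contaminated hit lists, two-screen pairs with a planted
core, decoy GMT libraries) provide ground truth for every stage, so the
whole pipeline is testable without any external database.

Intended users: computational biologists post-processing IP-MS or other
gene-list screens who want a scriptable, reproducible version of this
workup instead of a web tool.

## Worked example

A synthetic study: a 2000-node, hub-containing background interactome
with nine planted 15-node modules (within-module edge probability 0.5,
between-module 0.01) and a hit list holding all 135 module members plus
20 % contaminants:

```python
import pullnet as pn

sc = pn.generate_study_scenario(seed=0, n_background=2000)
sub = pn.induce(sc.background, sc.hit_list)
null = pn.permutation_density_test(
    sc.background, set_size=len(sc.hit_list), observed=sub.m,
    n_samples=10_000, seed=1,
)
part, hist = pn.greedy_modularity(sub.as_network())
tops = pn.top_terms(
    pn.annotate_clusters(part, [sc.library], universe=sc.background.nodes)
)
```

Output (printing the relevant fields):

```
background: 2000 nodes, 6344 edges
induced: 169 nodes, 584 edges
null mean 45.28  p_empirical 0.0001
communities: k=32  Q=0.702
cluster 0: top term MODULE_8  k/K=14/15  p=8.35e-35  p_adj=3.26e-33
cluster 1: top term MODULE_3  k/K=15/15  p=4.21e-38  p_adj=1.64e-36
```

Reading: the 169 hits carry 584 interactions where a random 169-protein
set carries ~45, so the empirical p-value sits at its attainable floor
`1/(n_samples+1) = 10⁻⁴`; the greedy optimizer finds 32 communities
(the nine planted modules plus contaminant singletons) at modularity
0.702, and each large cluster's top enriched term is its planted module.

The same analysis runs from the shell against files (edge lists, gene
lists, GMT) via a YAML config:

```sh
pullnet validate config.yaml
pullnet run config.yaml --out-dir run1
pullnet synth network --n-nodes 1000 --mean-degree 6 --out bg.tsv
pullnet density --network bg.tsv --hits hits.txt --n-samples 100000
```

`pullnet run` writes, under one directory: `report.json` (all numbers
plus input digests and seeds), the induced-subnetwork edge list, the
null counts for plotting the density PDF, the node partition and the
community-ordered adjacency matrix (optionally as a heatmap), per-library
and per-cluster enrichment tables, and a disease membership table.

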