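# Methods

## Background network and identifier handling

The background interactome is the union of edge-list resources
(2-column TSV or SIF), treated as a simple undirected graph: edge
direction is ignored, self-loops are dropped, and an edge reported by
several resources is one edge whose `sources` attribute accumulates the
resource names. Identifiers are plain gene symbols normalized by
trimming, uppercasing and removing internal whitespace, so murine-style
(`Myh9`) and human-style (`MYH9`) symbols share one namespace; an
explicit two-column ortholog map can be applied where that collapse is
not wanted implicitly. Symbol-level union is a deliberate simplification
— reconciling accession-level identifiers across resources is out of
scope, and users are expected to pre-flatten databases to symbol edge
lists.

## Interaction-density test

For a hit list of size `s`, the observed statistic is the number of
background edges with both endpoints in the list. The null is sampling:
`n_samples` uniform draws of `set_size` nodes without replacement from
all background nodes, counting induced edges each time. The empirical
p-value uses the add-one convention
`p = (1 + #{null ≥ observed}) / (n_samples + 1)`, so the smallest
attainable value at `n_samples` draws is `1/(n_samples+1)` and a zero
exceedance count at 10⁵ draws is reported as p < 10⁻⁵ rather than 0.
This convention also makes the p-value super-uniform under the null,
which the test suite checks directly.

Two choices deserve note. Random sets are drawn uniformly, not
degree-matched: hub effects are addressed separately by the
degree-distribution comparison rather than by conditioning the null.
And by default `set_size` is the number of hit symbols *matched* to the
background (configurable to the full list size), since unmatched symbols
cannot contribute edges on either side of the comparison.

The degree comparison is a two-sample Kolmogorov–Smirnov test on the raw
degree sequences of the induced subnetwork and the whole background
(isolated nodes count at degree 0). KS was chosen because it is
distribution-free and directly quantifies "the two distributions look
alike"; p > 0.05 is reported as "hub over-representation not detected".
KS on discrete degree data is conservative, which is the safe direction
for this verdict.

## Community detection

Modularity of a partition into k communities is
`Q = Σᵢ (eᵢᵢ − aᵢ²)`, with `eᵢᵢ` the fraction of edges inside community
i and `aᵢ` the fraction of edge *ends* attached to community i (degree
sum over 2m). This is the classical definition from the agglomerative
modularity literature; a sometimes-seen variant reads `aᵢ` as the
fraction of edges leaving the community, which is not consistent with
the agglomerative algorithm and is not used here. Q is bounded by
−1 ≤ Q < 1; the all-in-one partition always has Q = 0.

The optimizer starts from singleton communities and at each step merges
the connected pair with the largest gain `ΔQ = e_ij − 2 aᵢ aⱼ`
(cross-community edge fractions stored whole). Only connected pairs are
candidates, since merging disconnected communities strictly decreases Q;
consequently components never merge and isolated nodes remain
singletons. Merging continues until no connected pair remains, the full
merge history (pair, ΔQ, Q) is recorded, and the returned partition is
the maximum-Q state along the path. Gain ties are broken on the
lexicographically smallest community-label pair (labels assigned in
sorted node order), which makes the algorithm deterministic and
seed-free. Different but equally valid tie-breaking (e.g. other
implementations' heap order) can diverge the merge path and land on a
slightly different local optimum; the test suite therefore checks the
per-step max-gain contract by independent replay, and checks agreement
with networkx's implementation at the level of attained modularity.

Known limitation: greedy agglomeration cannot un-merge. When two planted
modules are joined early through a handful of between-module edges, the
best-Q cut of the merge path inherits the merge even when the split
partition has higher Q. On the nine-module synthetic benchmark below
this costs roughly one module pair in about half of the random
instances (≈ 86 % of modules recovered at ARI ≥ 0.8 overall). This is a
property of the method itself — the package deliberately implements
plain agglomerative modularity maximization, with no Louvain-style
refinement — and is visible, reproducibly, in the recorded merge
history.

For display, nodes are ordered by (community, degree descending,
symbol) and the adjacency matrix is emitted in that order with community
boundary indices (and optionally a heatmap), so genuine communities
appear as dense diagonal blocks.

## Enrichment

Enrichment of a query of size `s` against a term of size `K` in a
universe of size `N` with overlap `k` uses the hypergeometric upper tail
P(X ≥ k) — the one-sided Fisher exact test. Only enrichment is tested;
depletion is never of interest here. Benjamini–Hochberg adjustment is
applied across the terms of one library at a time (never across
libraries), and raw p-values are always reported alongside. The default
universe is the library's own universe (union of its term sets), the
most defensible choice when no explicit background is given;
out-of-universe query symbols are dropped with a warning and counted.
The cross-screen overlap test uses the same machinery with a default
universe of 20,000 (protein-coding genome scale), explicitly
configurable and always reported with the result. Cluster annotation
runs the same test per community, skipping clusters below a minimum size
(default 3, where a Fisher test is uninformative); the disease lookup is
a pure membership table with no statistic, mirroring how disease-gene
catalogues are usually quoted.

## Synthetic data: what it emulates, and what it does not

The generators are stand-ins for the two inputs a real study cannot
ship: proteomics hit lists and a literature PPI compendium.

* `generate_background_network`: `uniform_random` is G(n, p);
  `configuration_power_law` draws a Chung–Lu graph with expected degrees
  `wᵢ ∝ i^(−1/(γ−1))` (γ = 2.5 by default), giving the heavy, hub-rich
  degree tail of literature interactomes at a matched mean degree.
* `generate_planted_partition`: stochastic block model with equal-size
  independent Bernoulli edges (p_in within, p_out between). Chosen over
  LFR-style benchmarks because every quantity used in testing has a
  closed form or a trivial counting oracle.
* `generate_hit_list`: the full planted module plus uniformly drawn
  contaminants up to the requested list size; errors if the module
  exceeds the non-contaminant budget. Contaminants are degree-uniform by
  default; a degree-biased option exists (weights ∝ degree + 1) but is
  off, matching the working assumption that hit density is not a hub
  artifact.
* `generate_two_species_lists`: two lists sharing exactly a planted
  core, non-core members disjoint — the two-screen replication design.
* `generate_gmt`: planted terms verbatim among uniform decoy terms.
* `generate_study_scenario` composes the above into the package's
  reference benchmark: 2000-node hub-containing background at mean
  degree 6, nine 15-node modules at p_in 0.5 / p_out 0.01 overlaid on
  the background, a 20 %-contaminated hit list (169 symbols), and a
  library with one planted term per module among 30 decoys.

What the synthetic data does **not** capture: correlated false
positives (nonspecific binders in real IP-MS are sticky, abundant
proteins, i.e. degree-biased and correlated across experiments),
study-bias in literature PPI coverage, identifier noise beyond casing,
and any peptide-level error structure. Passing tests therefore
demonstrate the statistical machinery and its calibration on known
truth, not performance on any particular real interactome.

All generators are deterministic in their seed and emit objects that
round-trip exactly through the package's file formats.

## Numerical choices and problem sizes

* Empirical p-values: add-one convention throughout; monotone
  non-increasing in the observed count by construction.
* Modularity bookkeeping uses exact edge-fraction accumulation in
  floats; the Q trace is internally consistent to 1e-9 and the returned
  Q is re-derivable from the returned assignment to the same tolerance.
  Hand-checkable fixtures (two triangles, Q = 1/2; bridged triangles,
  Q = 5/14) reproduce to 1e-12.
* Exhaustive verification of the optimizer's upper bound runs over every
  connected graph on ≤ 7 nodes (the complete graph atlas, 995 graphs
  with at least one edge) against a brute-force maximum over all set
  partitions; seven nodes is the largest size with a readily available
  exhaustive enumeration, and Bell(7) = 877 partitions keep the oracle
  vectorizable.
* Fisher p-values are validated against exact-fraction tail summation
  for a dense sweep of tables up to N = 200; strict monotonicity in the
  overlap holds in exact arithmetic over the feasible range
  [max(0, s+K−N), min(K, s)], while the float path can saturate at 1.0
  below ~1e-16 differences.
* Null-calibration checks on G(200, 0.05) with 30-node samples use
  10⁴ draws; the standard error for the comparison against the design
  expectation 0.05·C(30,2) combines within-null sampling variance with
  the binomial variance of the realized edge count, since the design
  value averages over graph realizations.
* The nine-module recovery benchmark runs ten seeds (~6 s total);
  pipeline-level tests use a 400-node, three-module scaled copy of the
  same scenario with 500-sample nulls.
* Degenerate inputs: modularity and community detection are undefined
  (and error) on edgeless networks; empty hit lists cannot induce a
  subnetwork; a hit list disjoint from the background completes the
  pipeline with empty sections and a prominent warning rather than
  failing.

## Reproducibility

Every stochastic operation takes an explicit seed; identical seeds give
identical networks, samples, merge histories and reports. The pipeline
report embeds its full configuration and SHA-256 digests of all inputs,
and contains no timestamps, so identical runs are byte-identical.
`scripts/acceptance.py --seed S --out f.json` recomputes the headline
quantities from scratch with all randomness derived from `S`.
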