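"""Induced-subnetwork extraction and interaction-density statistics.

An affinity-purification screen yields a hit list; the first network
question is whether the hits interact with each other more than a random
protein set of the same size would. That is answered here by:

1. inducing the hit-list subnetwork on the background interactome
   (:func:`induce`);
2. building a sampling null for the induced edge count — repeatedly
   drawing uniform random node sets and counting the edges among them
   (:func:`permutation_density_test`), with an add-one empirical p-value
   so the smallest attainable value at ``n_samples`` draws is
   ``1/(n_samples+1)``;
3. comparing the degree distribution of the hits against the whole
   background to check whether a few promiscuous hubs, rather than
   genuine co-complex membership, explain the density
   (:func:`degree_distribution`, :func:`compare_degree_distributions`).

Random sets are drawn uniformly from all network nodes, not
degree-matched; hub influence is addressed separately by the degree
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import HitList, InteractionNetwork

__all__ = [
    "InducedSubnetwork",
    "PermutationNull",
    "DegreeDistribution",
    "DegreeComparison",
    "induce",
    "permutation_density_test",
    "degree_distribution",
    "compare_degree_distributions",
]


@dataclass
class InducedSubnetwork:
    """The subgraph of the background spanned by the hit-list members.

    Contains exactly the parent edges with both endpoints in the hit list.
    Hits absent from the background are counted, not errors.
    """

    parent: InteractionNetwork
    network: InteractionNetwork
    n_hits_total: int
    n_hits_in_network: int

    @property
    def nodes(self) -> set[str]:
        return self.network.nodes

    @property
    def edges(self) -> set[frozenset[str]]:
        return self.network.edges

    @property
    def m(self) -> int:
        return self.network.m

    def as_network(self) -> InteractionNetwork:
        return self.network


@dataclass
class PermutationNull:
    """Sampling null for the induced edge count of a random node set.

    ``p_empirical = (1 + #{null counts >= observed}) / (n_samples + 1)``.
    """

    observed: int
    set_size: int
    n_samples: int
    null_counts: np.ndarray
    seed: int
    p_empirical: float = field(init=False)

    def __post_init__(self) -> None:
        self.null_counts = np.asarray(self.null_counts, dtype=np.int64)
        if len(self.null_counts) != self.n_samples:
            raise ValueError("null_counts length must equal n_samples")
        self.p_empirical = empirical_p(self.observed, self.null_counts)

    @property
    def min_attainable_p(self) -> float:
        return 1.0 / (self.n_samples + 1)

    def summary(self) -> dict:
        return {
            "observed": int(self.observed),
            "set_size": int(self.set_size),
            "n_samples": int(self.n_samples),
            "null_mean": float(self.null_counts.mean()),
            "null_sd": float(self.null_counts.std(ddof=1)) if self.n_samples > 1 else 0.0,
            "p_empirical": self.p_empirical,
            "seed": int(self.seed),
        }


def empirical_p(observed: float, null_counts: np.ndarray) -> float:
    """Add-one empirical upper-tail p-value against a sampled null."""
    null_counts = np.asarray(null_counts)
    exceed = int(np.count_nonzero(null_counts >= observed))
    return (1 + exceed) / (len(null_counts) + 1)


@dataclass
class DegreeDistribution:
    """Empirical degree distribution of a network (isolated nodes at degree 0)."""

    degrees: np.ndarray
    n_nodes: int = field(init=False)

    def __post_init__(self) -> None:
        self.degrees = np.asarray(sorted(self.degrees), dtype=np.int64)
        if len(self.degrees) == 0:
            raise ValueError("degree distribution of an empty network is undefined")
        if (self.degrees < 0).any():
            raise ValueError("negative degree")
        self.n_nodes = len(self.degrees)

    @property
    def pdf(self) -> dict[int, float]:
        vals, counts = np.unique(self.degrees, return_counts=True)
        return {int(v): float(c) / self.n_nodes for v, c in zip(vals, counts)}


@dataclass
class DegreeComparison:
    """Two-sample KS comparison of two degree distributions."""

    statistic: float
    p_value: float
    pdf1: dict[int, float]
    pdf2: dict[int, float]
    alpha: float = 0.05

    @property
    def verdict(self) -> str:
        if self.p_value > self.alpha:
            return "hub over-representation not detected"
        return "degree distributions differ"


def induce(network: InteractionNetwork, hits: HitList) -> InducedSubnetwork:
    """Extract all direct interactions among hit-list members.

    Raises ``ValueError`` on an empty hit list; hits missing from the
    background are simply not matched.
    """
    if len(hits) == 0:
        raise ValueError("cannot induce a subnetwork from an empty hit list")
    if network.n == 0:
        raise ValueError("background network is empty")
    matched = hits.as_set() & network.nodes
    sub = network.subgraph(matched)
    return InducedSubnetwork(
        parent=network,
        network=sub,
        n_hits_total=len(hits),
        n_hits_in_network=len(matched),
    )


def permutation_density_test(
    network: InteractionNetwork,
    set_size: int,
    observed: int,
    n_samples: int = 100_000,
    seed: int = 0,
) -> PermutationNull:
    """Sampling null for the number of interactions within a random node set.

    Each sample draws ``set_size`` nodes uniformly without replacement from
    the background and counts the edges among them. ``null_counts`` is
    retained so the probability density function can be plotted.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    n = network.n
    if set_size > n:
        raise ValueError(f"set_size {set_size} exceeds node count {n}")
    if set_size < 0:
        raise ValueError("set_size must be non-negative")
    nodes = sorted(network.graph.nodes)
    index = {node: i for i, node in enumerate(nodes)}
    edge_u = np.fromiter(
        (index[u] for u, _ in network.graph.edges), dtype=np.int64, count=network.m
    )
    edge_v = np.fromiter(
        (index[v] for _, v in network.graph.edges), dtype=np.int64, count=network.m
    )
    rng = np.random.default_rng(seed)
    counts = np.empty(n_samples, dtype=np.int64)
    member = np.zeros(n, dtype=bool)
    for i in range(n_samples):
        chosen = rng.choice(n, size=set_size, replace=False)
        member[chosen] = True
        counts[i] = np.count_nonzero(member[edge_u] & member[edge_v])
        member[chosen] = False
    return PermutationNull(
        observed=observed,
        set_size=set_size,
        n_samples=n_samples,
        null_counts=counts,
        seed=seed,
    )


def degree_distribution(network: InteractionNetwork) -> DegreeDistribution:
    """Degree distribution over all nodes (isolated nodes contribute at 0)."""
    if network.n == 0:
        raise ValueError("degree distribution of an empty network is undefined")
    return DegreeDistribution(np.array([d for _, d in network.graph.degree]))


def compare_degree_distributions(
    d1: DegreeDistribution, d2: DegreeDistribution, alpha: float = 0.05
) -> DegreeComparison:
    """Two-sample Kolmogorov-Smirnov test on the raw degree samples.

    A large p-value supports the reading that the induced subnetwork's
    density is not driven by an over-representation of hub proteins.
    """
    if np.array_equal(d1.degrees, d2.degrees):
        stat, p = 0.0, 1.0
    else:
        res = stats.ks_2samp(d1.degrees, d2.degrees, method="asymp")
        stat, p = float(res.statistic), float(min(res.pvalue, 1.0))
    return DegreeComparison(
        statistic=stat, p_value=p, pdf1=d1.pdf, pdf2=d2.pdf, alpha=alpha
    )
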