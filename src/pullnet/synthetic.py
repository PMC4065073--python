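"""Synthetic benchmarks with known ground truth for every pipeline stage.

Real inputs for this kind of analysis — an affinity-purification hit
list and a literature-compiled interactome — carry no ground truth, so
correctness is exercised on generated data instead:

* a planted-partition (stochastic block) random graph, whose communities
  are the truth for community detection;
* a background interactome, either uniform (Erdős–Rényi) or with a
  heavy-tailed, hub-containing degree distribution (Chung–Lu expected
  degrees ``w_i ∝ i^(-1/(γ-1))``, the scale-free-ish regime of real
  interactomes);
* hit lists made of a planted module plus uniformly drawn contaminants,
  emulating a pull-down of true complex members plus nonspecific binders;
* two-screen hit-list pairs with a planted shared core, emulating a
  cross-species replication design;
* GMT libraries with planted (true) terms among uniform decoy terms.

Every generator is deterministic given its seed and emits objects that
round-trip through the standard file formats of :mod:`pullnet.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import GeneSetLibrary, HitList, InteractionNetwork

__all__ = [
    "PlantedPartitionSpec",
    "SyntheticHitListSpec",
    "symbol_namespace",
    "generate_planted_partition",
    "generate_background_network",
    "generate_hit_list",
    "generate_two_species_lists",
    "generate_gmt",
    "StudyScenario",
    "generate_study_scenario",
]

SYNTH_SOURCE = "synthetic"


def symbol_namespace(n: int, prefix: str = "G") -> list[str]:
    """Deterministic synthetic symbol namespace: PREFIX00001..PREFIXn."""
    width = max(5, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


@dataclass
class PlantedPartitionSpec:
    """Stochastic block model with equal within/between edge probabilities."""

    sizes: list[int]
    p_in: float
    p_out: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sizes or any(s < 1 for s in self.sizes):
            raise ValueError("community sizes must all be >= 1")
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError("require 0 <= p_out < p_in <= 1")

    @property
    def k(self) -> int:
        return len(self.sizes)


@dataclass
class SyntheticHitListSpec:
    """A hit list: true-module members diluted with uniform contaminants."""

    background_network: InteractionNetwork
    true_module_nodes: set[str]
    contamination: float
    list_size: int
    seed: int = 0
    degree_biased_contaminants: bool = False  # off by default

    def __post_init__(self) -> None:
        if not (0.0 <= self.contamination <= 1.0):
            raise ValueError("contamination must be in [0, 1]")
        if self.list_size > self.background_network.n:
            raise ValueError("list_size exceeds background node count")
        if not self.true_module_nodes <= self.background_network.nodes:
            raise ValueError("true module must lie inside the background network")


def generate_planted_partition(
    spec: PlantedPartitionSpec, prefix: str = "P"
) -> tuple[InteractionNetwork, dict[str, int]]:
    """Sample a planted-partition graph and return it with its truth labels.

    Each within-community node pair is edged independently with ``p_in``,
    each between-community pair with ``p_out``.
    """
    rng = np.random.default_rng(spec.seed)
    n = sum(spec.sizes)
    names = symbol_namespace(n, prefix=prefix)
    planted: dict[str, int] = {}
    start = 0
    for cid, size in enumerate(spec.sizes):
        for node in names[start : start + size]:
            planted[node] = cid
        start += size
    net = InteractionNetwork()
    net.graph.add_nodes_from(names)
    comm = np.array([planted[v] for v in names])
    iu, ju = np.triu_indices(n, k=1)
    prob = np.where(comm[iu] == comm[ju], spec.p_in, spec.p_out)
    hit = rng.random(len(prob)) < prob
    for i, j in zip(iu[hit], ju[hit]):
        net.add_edge(names[i], names[j], sources=[SYNTH_SOURCE])
    return net, planted


def generate_background_network(
    n_nodes: int,
    mean_degree: float,
    model: str = "uniform_random",
    seed: int = 0,
    gamma: float = 2.5,
    prefix: str = "B",
) -> InteractionNetwork:
    """Sample a simple background interactome.

    ``uniform_random`` is G(n, p) with p chosen for the requested mean
    degree; ``configuration_power_law`` samples a Chung–Lu graph whose
    expected degrees follow a power law with exponent ``gamma``, giving
    the hub-heavy tail of literature interactomes at a matched mean
    degree. Multi-edges and self-loops never occur; for n >= 500 the
    realized mean degree lands within ~10% of the request.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if not (0 < mean_degree < n_nodes - 1):
        raise ValueError("infeasible mean degree")
    names = symbol_namespace(n_nodes, prefix=prefix)
    if model == "uniform_random":
        p = mean_degree / (n_nodes - 1)
        g = nx.fast_gnp_random_graph(n_nodes, p, seed=int(seed))
    elif model == "configuration_power_law":
        ranks = np.arange(1, n_nodes + 1, dtype=float)
        w = ranks ** (-1.0 / (gamma - 1.0))
        w *= n_nodes * mean_degree / w.sum()
        w = np.minimum(w, np.sqrt(n_nodes * mean_degree))  # keep p_ij <= 1
        g = nx.expected_degree_graph(w.tolist(), seed=int(seed), selfloops=False)
    else:
        raise ValueError(f"unknown background model {model!r}")
    net = InteractionNetwork()
    net.graph.add_nodes_from(names)
    for u, v in g.edges:
        net.add_edge(names[u], names[v], sources=[SYNTH_SOURCE])
    return net


def generate_hit_list(spec: SyntheticHitListSpec) -> tuple[HitList, dict[str, bool]]:
    """Draw a hit list of module members plus contaminants, with truth labels.

    Returns the list (order shuffled, deterministic in the seed) and a map
    symbol -> True for module members, False for contaminants.
    """
    rng = np.random.default_rng(spec.seed)
    module = sorted(spec.true_module_nodes)
    # the whole module goes in; contaminants fill the list up to list_size,
    # so the module must fit the non-contaminant budget
    if len(module) > spec.list_size * (1.0 - spec.contamination) + 1e-9:
        raise ValueError(
            f"module of {len(module)} exceeds the list budget "
            f"{spec.list_size} x (1 - {spec.contamination})"
        )
    picked_module = module
    n_contam = spec.list_size - len(module)
    pool = sorted(spec.background_network.nodes - spec.true_module_nodes)
    if n_contam > len(pool):
        raise ValueError("not enough non-module nodes for the contaminants")
    if spec.degree_biased_contaminants:
        deg = np.array([spec.background_network.degree(v) for v in pool], dtype=float)
        weights = deg + 1.0  # +1 keeps isolated nodes reachable
        weights /= weights.sum()
        contam = sorted(rng.choice(pool, size=n_contam, replace=False, p=weights))
    else:
        contam = sorted(rng.choice(pool, size=n_contam, replace=False))
    symbols = list(picked_module) + list(contam)
    rng.shuffle(symbols)
    truth = {s: (s in spec.true_module_nodes) for s in symbols}
    return HitList(symbols, label="synthetic-hitlist"), truth


def generate_two_species_lists(
    core_size: int,
    size_a: int,
    size_b: int,
    namespace: list[str] | set[str],
    seed: int = 0,
) -> tuple[HitList, HitList, set[str]]:
    """Two screens sharing exactly a planted core.

    Non-core members are drawn disjointly, so |A ∩ B| equals ``core_size``
    by construction — the two-screen replication design in which the
    overlap of independently derived hit lists is the reproducibility
    signal.
    """
    if core_size > min(size_a, size_b):
        raise ValueError("core larger than a list")
    names = sorted(namespace)
    need = size_a + size_b - core_size
    if need > len(names):
        raise ValueError(f"namespace of {len(names)} cannot host {need} distinct symbols")
    rng = np.random.default_rng(seed)
    drawn = rng.choice(names, size=need, replace=False)
    core = set(drawn[:core_size])
    rest_a = drawn[core_size : size_a]
    rest_b = drawn[size_a:]
    list_a = HitList(sorted(core) + sorted(rest_a), label="screenA")
    list_b = HitList(sorted(core) + sorted(rest_b), label="screenB")
    return list_a, list_b, core


def generate_gmt(
    n_decoy_terms: int,
    term_size_range: tuple[int, int],
    planted: dict[str, set[str]],
    namespace: list[str] | set[str],
    seed: int = 0,
    name: str = "synthetic-library",
) -> GeneSetLibrary:
    """A gene-set library of planted (true) terms plus uniform decoy terms.

    Planted terms are inserted verbatim; each decoy draws a uniform size
    from ``term_size_range`` and uniform members from the namespace.
    """
    names = sorted(namespace)
    for term, members in planted.items():
        if not set(members) <= set(names):
            raise ValueError(f"planted term {term!r} does not fit the namespace")
    lo, hi = term_size_range
    if not (1 <= lo <= hi <= len(names)):
        raise ValueError("infeasible term size range")
    rng = np.random.default_rng(seed)
    terms: dict[str, set[str]] = {t: set(m) for t, m in planted.items()}
    width = max(3, len(str(n_decoy_terms)))
    for i in range(1, n_decoy_terms + 1):
        size = int(rng.integers(lo, hi + 1))
        terms[f"DECOY_{i:0{width}d}"] = set(rng.choice(names, size=size, replace=False))
    return GeneSetLibrary(name=name, terms=terms)


@dataclass
class StudyScenario:
    """A full synthetic re-enactment of a pull-down network study.

    A hub-containing background interactome with several densely
    connected planted modules; a hit list that unions the modules with
    nonspecific contaminants; and a gene-set library in which each
    module's node set is a planted term among decoys.
    """

    background: InteractionNetwork
    module_of: dict[str, int]  # planted module id per module node
    hit_list: HitList
    truth: dict[str, bool]  # hit symbol -> is a module member
    library: GeneSetLibrary
    planted_terms: dict[int, str] = field(default_factory=dict)  # module id -> term


def generate_study_scenario(
    seed: int = 0,
    n_background: int = 2000,
    n_modules: int = 9,
    module_size: int = 15,
    p_in: float = 0.5,
    p_out: float = 0.01,
    contamination: float = 0.2,
    mean_degree: float = 6.0,
    background_model: str = "configuration_power_law",
    n_decoy_terms: int = 30,
) -> StudyScenario:
    """Compose background + planted modules + contaminated hit list + library.

    Module nodes are drawn at random from the background; within-module
    pairs gain edges with ``p_in`` and pairs spanning two different
    modules with ``p_out``, on top of whatever background edges exist.
    The hit list holds every module member diluted to the requested
    contamination fraction; the library holds one planted term per module
    (its exact node set) among uniform decoys.
    """
    rng = np.random.default_rng(seed)
    net = generate_background_network(
        n_background, mean_degree, model=background_model, seed=int(seed) % 2**31
    )
    nodes = sorted(net.nodes)
    chosen = rng.choice(nodes, size=n_modules * module_size, replace=False)
    module_of: dict[str, int] = {}
    modules: list[list[str]] = []
    for mid in range(n_modules):
        members = sorted(chosen[mid * module_size : (mid + 1) * module_size])
        modules.append(members)
        for v in members:
            module_of[v] = mid
    module_nodes = sorted(module_of)
    for i, u in enumerate(module_nodes):
        for v in module_nodes[i + 1 :]:
            p = p_in if module_of[u] == module_of[v] else p_out
            if rng.random() < p:
                net.add_edge(u, v, sources=[SYNTH_SOURCE])
    list_size = int(round(len(module_nodes) / (1.0 - contamination)))
    hits, truth = generate_hit_list(
        SyntheticHitListSpec(
            background_network=net,
            true_module_nodes=set(module_nodes),
            contamination=contamination,
            list_size=list_size,
            seed=int(rng.integers(2**31)),
        )
    )
    planted = {f"MODULE_{mid}": set(members) for mid, members in enumerate(modules)}
    library = generate_gmt(
        n_decoy_terms=n_decoy_terms,
        term_size_range=(max(3, module_size - 5), module_size + 5),
        planted=planted,
        namespace=nodes,
        seed=int(rng.integers(2**31)),
    )
    return StudyScenario(
        background=net,
        module_of=module_of,
        hit_list=hits,
        truth=truth,
        library=library,
        planted_terms={mid: f"MODULE_{mid}" for mid in range(n_modules)},
    )
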