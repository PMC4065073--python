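"""Greedy agglomerative modularity maximization (Clauset-Newman-Moore style).

Modularity of a partition of an undirected simple graph into k communities:

    Q = sum_i (e_ii - a_i^2)

where ``e_ii`` is the fraction of all edges that fall inside community i
and ``a_i`` is the fraction of edge *ends* attached to community i
(degree sum of its members divided by 2m). Q measures the excess of
within-community edges over the expectation for a degree-preserving
random rewiring; Q is always < 1 and >= -1.

The optimizer starts from singleton communities and repeatedly merges the
pair of *connected* communities with the largest modularity gain
(merging disconnected communities can only decrease Q), recording the
whole merge path, until no connected pair remains — one community per
connected component. The partition returned is the maximum-Q state along
the path. Ties in the gain are broken on the lexicographically smallest
community-label pair, which makes the algorithm fully deterministic and
seed-free. Isolated nodes stay singleton communities.

With the edge-fraction convention above (cross-community fractions stored
whole, not halved), the gain of merging communities i and j is
``dQ = e_ij - 2 a_i a_j``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import InteractionNetwork

__all__ = [
    "Partition",
    "MergeHistory",
    "MergeStep",
    "modularity",
    "greedy_modularity",
    "order_by_community",
    "community_adjacency",
    "plot_adjacency_heatmap",
]


@dataclass
class Partition:
    """Assignment of every network node to one of k contiguous communities."""

    assignment: dict[str, int]
    k: int
    Q: float

    def communities(self) -> list[set[str]]:
        out: list[set[str]] = [set() for _ in range(self.k)]
        for node, cid in self.assignment.items():
            out[cid].add(node)
        return out

    def sizes(self) -> list[int]:
        return [len(c) for c in self.communities()]


@dataclass
class MergeStep:
    pair: tuple[int, int]  # community labels merged (smaller label survives)
    dQ: float
    Q_after: float


@dataclass
class MergeHistory:
    """The ordered merge path of the greedy optimizer.

    ``Q_trace[t]`` is the modularity after t merges (``Q_trace[0]`` is the
    all-singleton state); ``best_step`` indexes the maximum-Q state.
    """

    steps: list[MergeStep]
    Q_trace: list[float]
    best_step: int


def modularity(network: InteractionNetwork, assignment: dict[str, int]) -> float:
    """Compute Q = sum_i (e_ii - a_i^2) for a full node-to-community mapping."""
    m = network.m
    if m == 0:
        raise ValueError("modularity is undefined for a network with no edges")
    missing = network.nodes - set(assignment)
    if missing:
        raise ValueError(f"assignment misses {len(missing)} nodes (e.g. {sorted(missing)[:3]})")
    comms = set(assignment[v] for v in network.graph.nodes)
    e_in = dict.fromkeys(comms, 0.0)
    deg = dict.fromkeys(comms, 0.0)
    for u, v in network.graph.edges:
        if assignment[u] == assignment[v]:
            e_in[assignment[u]] += 1.0
    for node, d in network.graph.degree:
        deg[assignment[node]] += d
    return sum(e_in[c] / m - (deg[c] / (2.0 * m)) ** 2 for c in comms)


def greedy_modularity(network: InteractionNetwork) -> tuple[Partition, MergeHistory]:
    """Agglomerative modularity maximization from singleton communities.

    Returns the maximum-Q partition along the merge path together with the
    full merge history. Deterministic: gain ties break on the smallest
    community-label pair, labels being assigned in sorted node order.
    """
    m = network.m
    if m == 0:
        raise ValueError("greedy modularity is undefined for a network with no edges")
    nodes = sorted(network.graph.nodes)
    label_of = {node: i for i, node in enumerate(nodes)}

    # e[i][j]: fraction of edges between communities i and j (j != i),
    # e[i][i]: fraction within. a[i]: fraction of edge ends in i.
    e: dict[int, dict[int, float]] = {i: {} for i in range(len(nodes))}
    a = {i: network.graph.degree[node] / (2.0 * m) for node, i in label_of.items()}
    for u, v in network.graph.edges:
        i, j = label_of[u], label_of[v]
        e[i][j] = e[i].get(j, 0.0) + 1.0 / m
        e[j][i] = e[j].get(i, 0.0) + 1.0 / m

    Q = -sum(ai * ai for ai in a.values())  # singleton state: all e_ii = 0
    trace = [Q]
    steps: list[MergeStep] = []
    merges: list[tuple[int, int]] = []
    within = dict.fromkeys(a, 0.0)  # e_ii per live community

    while True:
        best: tuple[float, int, int] | None = None
        for i in sorted(e):
            row = e[i]
            for j in sorted(row):
                if j <= i:
                    continue
                dq = row[j] - 2.0 * a[i] * a[j]
                if best is None or dq > best[0] + 1e-15 or (
                    abs(dq - best[0]) <= 1e-15 and (i, j) < (best[1], best[2])
                ):
                    best = (dq, i, j)
        if best is None:
            break
        dq, i, j = best
        # merge j into i (smaller label survives)
        within[i] += within[j] + e[i].pop(j)
        del within[j]
        a[i] += a.pop(j)
        del e[j][i]
        for k, w in e.pop(j).items():
            e[i][k] = e[i].get(k, 0.0) + w
            row_k = e[k]
            del row_k[j]
            row_k[i] = row_k.get(i, 0.0) + w
        Q += dq
        merges.append((i, j))
        steps.append(MergeStep(pair=(i, j), dQ=dq, Q_after=Q))
        trace.append(Q)

    best_step = int(np.argmax(trace))

    # replay the first best_step merges to recover the maximum-Q assignment
    parent = list(range(len(nodes)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in merges[:best_step]:
        parent[find(j)] = find(i)

    roots = sorted({find(i) for i in range(len(nodes))})
    compact = {r: c for c, r in enumerate(roots)}
    assignment = {node: compact[find(label_of[node])] for node in nodes}
    part = Partition(assignment=assignment, k=len(roots), Q=trace[best_step])
    hist = MergeHistory(steps=steps, Q_trace=trace, best_step=best_step)
    return part, hist


def order_by_community(
    network: InteractionNetwork, partition: Partition
) -> tuple[list[str], list[int]]:
    """Node ordering for a community-blocked adjacency matrix.

    Nodes are sorted by (community id, degree descending, symbol); the
    returned boundary indices mark the end of each community block, so a
    heatmap can draw cluster boundaries between the dense diagonal blocks.
    """
    missing = network.nodes - set(partition.assignment)
    if missing:
        raise ValueError("partition does not cover the network")
    ordering = sorted(
        network.graph.nodes,
        key=lambda v: (partition.assignment[v], -network.graph.degree[v], v),
    )
    boundaries: list[int] = []
    sizes = partition.sizes()
    total = 0
    for size in sizes:
        if size == 0:
            continue
        total += size
        boundaries.append(total)
    return ordering, boundaries


def community_adjacency(
    network: InteractionNetwork, partition: Partition
) -> tuple[np.ndarray, list[str], list[int]]:
    """Dense 0/1 adjacency matrix in community order, with block boundaries."""
    ordering, boundaries = order_by_community(network, partition)
    index = {node: i for i, node in enumerate(ordering)}
    mat = np.zeros((len(ordering), len(ordering)), dtype=np.int8)
    for u, v in network.graph.edges:
        i, j = index[u], index[v]
        mat[i, j] = mat[j, i] = 1
    return mat, ordering, boundaries


def plot_adjacency_heatmap(
    network: InteractionNetwork, partition: Partition, path: str
) -> None:
    """Write the community-ordered adjacency matrix as a heatmap image.

    Community boundaries are drawn as lines, so densely connected blocks
    appear along the diagonal.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat, ordering, boundaries = community_adjacency(network, partition)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(mat, cmap="Greys", interpolation="nearest")
    for b in boundaries[:-1]:
        ax.axhline(b - 0.5, color="orange", linewidth=0.6)
        ax.axvline(b - 0.5, color="orange", linewidth=0.6)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(f"{len(ordering)} nodes, {partition.k} communities, Q={partition.Q:.3f}")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
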