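"""Independent oracles used across the test suite.

Everything here is deliberately simple and independent of the package's
own code paths: explicit set-partition enumeration for modularity
maxima, double loops for induced edge counts, and exact-fraction
hypergeometric tails.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache
from math import comb

import numpy as np


def set_partitions(n: int) -> list[tuple[int, ...]]:
    """All partitions of {0..n-1} as canonical label tuples (restricted growth)."""
    out: list[tuple[int, ...]] = []

    def grow(labels: list[int], next_label: int) -> None:
        if len(labels) == n:
            out.append(tuple(labels))
            return
        for lab in range(next_label + 1):
            grow(labels + [lab], max(next_label, lab + 1))

    grow([0], 1)
    return out


def modularity_oracle(edges: list[tuple[int, int]], labels: tuple[int, ...]) -> float:
    """Q by direct application of the definition (fraction arithmetic in float)."""
    m = len(edges)
    k = max(labels) + 1
    e_in = [0] * k
    deg = [0] * k
    for u, v in edges:
        if labels[u] == labels[v]:
            e_in[labels[u]] += 1
        deg[labels[u]] += 1
        deg[labels[v]] += 1
    return sum(e_in[c] / m - (deg[c] / (2 * m)) ** 2 for c in range(k))


@lru_cache(maxsize=None)
def _partition_tensors(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized partition machinery for n-node graphs.

    Returns (labels (P,n), same (P, n*(n-1)/2) pair-same-community mask,
    onehot (P, n, n) community membership padded to n columns).
    """
    parts = np.array(set_partitions(n), dtype=np.int64)
    iu, ju = np.triu_indices(n, k=1)
    same = parts[:, iu] == parts[:, ju]
    onehot = np.zeros((len(parts), n, n))
    for p, labels in enumerate(parts):
        for node, lab in enumerate(labels):
            onehot[p, node, lab] = 1.0
    return parts, same, onehot


def brute_force_max_modularity(edges: list[tuple[int, int]], n: int) -> float:
    """Maximum modularity over every partition of an n-node graph (n <= 8)."""
    m = len(edges)
    assert m >= 1
    _, same, onehot = _partition_tensors(n)
    iu, ju = np.triu_indices(n, k=1)
    pair_index = {(int(a), int(b)): idx for idx, (a, b) in enumerate(zip(iu, ju))}
    edge_mask = np.zeros(len(iu))
    deg = np.zeros(n)
    for u, v in edges:
        a, b = min(u, v), max(u, v)
        edge_mask[pair_index[(a, b)]] = 1.0
        deg[u] += 1
        deg[v] += 1
    e_in = same @ edge_mask / m  # (P,)
    degsums = np.einsum("j,pjk->pk", deg, onehot) / (2.0 * m)
    q = e_in - (degsums**2).sum(axis=1)
    return float(q.max())


def induced_edge_count_oracle(edges: set[frozenset[str]], nodes: set[str]) -> int:
    """Double-loop count of edges with both endpoints in `nodes`."""
    count = 0
    node_list = sorted(nodes)
    for i, u in enumerate(node_list):
        for v in node_list[i + 1 :]:
            if frozenset((u, v)) in edges:
                count += 1
    return count


def hypergeom_tail_fraction(k: int, K: int, s: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(N, K, s), in exact rational arithmetic."""
    total = Fraction(0)
    denom = comb(N, s)
    for j in range(k, min(K, s) + 1):
        total += Fraction(comb(K, j) * comb(N - K, s - j), denom)
    return total


def hypergeom_tail_oracle(k: int, K: int, s: int, N: int) -> float:
    return float(hypergeom_tail_fraction(k, K, s, N))
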