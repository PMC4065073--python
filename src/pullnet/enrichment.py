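"""Fisher-exact gene-set enrichment, overlap testing and disease lookup.

A query set of ``s`` proteins drawn from a universe of ``N`` is tested
against each library term of size ``K``; the overlap ``k`` follows a
hypergeometric distribution under the null, and the one-sided
(enrichment) p-value is the upper tail P(X >= k) — identical to the
one-sided Fisher exact test on the 2x2 contingency table. Only
enrichment is tested, never depletion. Raw p-values are always emitted;
Benjamini-Hochberg adjustment is applied across the terms of one library
at a time.

The default universe for library enrichment is the library's own
universe (the union of its term sets); the cross-screen overlap test
defaults to a protein-coding genome-scale universe of 20,000. Both are
explicitly configurable and reported with each result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .community import Partition
from .io import GeneSetLibrary, HitList

__all__ = [
    "DEFAULT_OVERLAP_UNIVERSE",
    "ContingencyTable",
    "EnrichmentResult",
    "fisher_pvalue",
    "fisher_enrichment",
    "overlap_test",
    "annotate_clusters",
    "disease_lookup",
]

DEFAULT_OVERLAP_UNIVERSE = 20_000


@dataclass
class ContingencyTable:
    """Overlap counts for one term: k of s query members hit a term of size K in N."""

    k: int
    K: int
    s: int
    N: int

    def __post_init__(self) -> None:
        if min(self.k, self.K, self.s, self.N) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.k > min(self.K, self.s):
            raise ValueError(f"overlap k={self.k} exceeds min(K={self.K}, s={self.s})")
        if max(self.K, self.s) > self.N:
            raise ValueError("term or query larger than universe")

    def odds_ratio(self) -> float:
        """Sample odds ratio of the 2x2 table; inf when a null cell vanishes."""
        a = self.k
        b = self.s - self.k
        c = self.K - self.k
        d = self.N - self.s - self.K + self.k
        if b * c == 0:
            return float("inf") if a * d > 0 else 0.0
        return (a * d) / (b * c)


@dataclass
class EnrichmentResult:
    term: str
    table: ContingencyTable
    p: float
    overlap_symbols: set[str]
    p_adj: float = field(default=float("nan"))

    @property
    def odds_ratio(self) -> float:
        return self.table.odds_ratio()

    def sort_key(self) -> tuple[float, str]:
        return (self.p, self.term)


def fisher_pvalue(k: int, K: int, s: int, N: int) -> float:
    """One-sided enrichment p-value P(X >= k), X ~ Hypergeom(N, K, s)."""
    ContingencyTable(k=k, K=K, s=s, N=N)  # validate
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, s))


def fisher_enrichment(
    query: HitList,
    library: GeneSetLibrary,
    universe: set[str] | None = None,
) -> list[EnrichmentResult]:
    """Rank every library term by its overlap with the query.

    The query is restricted to the universe before testing; out-of-universe
    symbols are counted and reported via a warning. Terms are likewise
    intersected with the universe. Results come back sorted ascending by
    (p, term), with BH-adjusted p-values computed across all terms of this
    library.
    """
    uni = set(universe) if universe is not None else library.universe
    if not uni:
        raise ValueError("empty universe")
    qset = query.as_set()
    q_in = qset & uni
    n_out = len(qset) - len(q_in)
    if not q_in:
        raise ValueError(
            f"no query symbol is in the universe ({len(qset)} symbols, "
            f"universe size {len(uni)}); check namespaces"
        )
    if n_out:
        warnings.warn(
            f"{n_out} of {len(qset)} query symbols outside the universe were dropped"
        )
    N, s = len(uni), len(q_in)
    results: list[EnrichmentResult] = []
    for term, members in library.terms.items():
        t_in = members & uni
        if not t_in:
            continue
        overlap = t_in & q_in
        table = ContingencyTable(k=len(overlap), K=len(t_in), s=s, N=N)
        results.append(
            EnrichmentResult(
                term=term,
                table=table,
                p=fisher_pvalue(table.k, table.K, table.s, table.N),
                overlap_symbols=overlap,
            )
        )
    if results:
        _, p_adj, _, _ = multipletests([r.p for r in results], method="fdr_bh")
        for r, pa in zip(results, p_adj):
            r.p_adj = float(pa)
    results.sort(key=EnrichmentResult.sort_key)
    return results


def overlap_test(
    list_a: HitList,
    list_b: HitList,
    universe_size: int = DEFAULT_OVERLAP_UNIVERSE,
) -> EnrichmentResult:
    """Fisher exact test for the overlap of two screens' hit lists.

    Both lists must already share one namespace (apply an ortholog map
    first for cross-species pairs). The contingency table is
    (k = |A∩B|, s = |A|, K = |B|) against ``universe_size``.
    """
    a, b = list_a.as_set(), list_b.as_set()
    if universe_size < len(a | b):
        raise ValueError(
            f"universe_size {universe_size} smaller than |A ∪ B| = {len(a | b)}"
        )
    overlap = a & b
    table = ContingencyTable(k=len(overlap), K=len(b), s=len(a), N=universe_size)
    res = EnrichmentResult(
        term=f"{list_a.label or 'A'}∩{list_b.label or 'B'}",
        table=table,
        p=fisher_pvalue(table.k, table.K, table.s, table.N),
        overlap_symbols=overlap,
    )
    res.p_adj = res.p  # single test
    return res


def annotate_clusters(
    partition: Partition,
    libraries: list[GeneSetLibrary],
    universe: set[str] | None = None,
    min_cluster_size: int = 3,
) -> dict[int, dict[str, list[EnrichmentResult]]]:
    """Per-cluster enrichment against each library (protein-complex annotation).

    Clusters below ``min_cluster_size`` are skipped with a notice. Returns
    ``{cluster id: {library name: ranked results}}``; the first entry of a
    ranked list is the cluster's top term for that library.
    """
    out: dict[int, dict[str, list[EnrichmentResult]]] = {}
    for cid, members in enumerate(partition.communities()):
        if len(members) < min_cluster_size:
            warnings.warn(
                f"cluster {cid} has {len(members)} members "
                f"(< {min_cluster_size}); skipped"
            )
            continue
        query = HitList(sorted(members), label=f"cluster{cid}")
        per_lib: dict[str, list[EnrichmentResult]] = {}
        for lib in libraries:
            try:
                per_lib[lib.name] = fisher_enrichment(query, lib, universe=universe)
            except ValueError:
                per_lib[lib.name] = []  # no member in this library's universe
        out[cid] = per_lib
    return out


def top_terms(
    annotations: dict[int, dict[str, list[EnrichmentResult]]],
) -> dict[int, dict[str, EnrichmentResult]]:
    """Summary table: the single top term per cluster per library."""
    return {
        cid: {lib: res[0] for lib, res in per_lib.items() if res}
        for cid, per_lib in annotations.items()
    }


def disease_lookup(
    hits: HitList, disease_library: GeneSetLibrary
) -> dict[str, list[str]]:
    """Pure membership lookup: which hits appear under each disease term.

    No statistic is computed — this mirrors a disease-gene table listing
    screen members found under each disease heading. Terms with an empty
    intersection are omitted.
    """
    hit_set = hits.as_set()
    table: dict[str, list[str]] = {}
    for term in sorted(disease_library.terms):
        found = sorted(disease_library.terms[term] & hit_set)
        if found:
            table[term] = found
    return table
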