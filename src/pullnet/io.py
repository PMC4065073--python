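"""Readers, writers and core containers for interaction-network analysis.

External formats handled here:

* edge lists — 2-column TSV (``#`` comment lines skipped) or SIF
  (``nodeA<TAB>relation<TAB>nodeB``, relation ignored);
* gene lists — one symbol per line;
* gene-set libraries — standard GMT (``term<TAB>description<TAB>gene...``);
* ortholog maps — 2-column TSV (source symbol, target symbol).

All symbols pass through :func:`normalize_symbol` so that murine-style
(``Myh9``) and human-style (``MYH9``) identifiers collapse into one
namespace. Networks are simple undirected graphs: direction in source
files is ignored, self-loops are dropped and duplicate rows collapse onto
one edge whose ``sources`` attribute accumulates every contributing
resource name.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "normalize_symbol",
    "InteractionNetwork",
    "HitList",
    "GeneSetLibrary",
    "OrthologMap",
    "ParseError",
    "read_edge_list",
    "write_edge_list",
    "merge_networks",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "write_gmt",
    "read_ortholog_map",
]


class ParseError(ValueError):
    """Malformed row in an input file; message carries the 1-based line number."""


def normalize_symbol(raw: str) -> str:
    """Normalize a protein/gene symbol: trim, uppercase, remove internal whitespace.

    Idempotent by construction. Raises ``ValueError`` if nothing remains.
    """
    sym = "".join(str(raw).split()).upper()
    if not sym:
        raise ValueError(f"symbol {raw!r} is empty after normalization")
    return sym


@dataclass
class InteractionNetwork:
    """A simple undirected protein-protein interaction graph.

    Wraps a :class:`networkx.Graph` whose nodes are normalized symbols and
    whose edges carry a ``sources`` set naming the resources that reported
    the interaction.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    @property
    def m(self) -> int:
        """Number of (unique, undirected) edges."""
        return self.graph.number_of_edges()

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    def add_edge(self, a: str, b: str, sources: Iterable[str] = ()) -> bool:
        """Add one undirected edge between normalized symbols.

        Self-loops are rejected (returns ``False``); re-adding an edge merges
        the ``sources`` labels instead of duplicating it.
        """
        a, b = normalize_symbol(a), normalize_symbol(b)
        if a == b:
            return False
        if self.graph.has_edge(a, b):
            self.graph[a][b]["sources"] |= set(sources)
        else:
            self.graph.add_edge(a, b, sources=set(sources))
        return True

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def subgraph(self, nodes: Iterable[str]) -> "InteractionNetwork":
        return InteractionNetwork(nx.Graph(self.graph.subgraph(nodes)))

    def copy(self) -> "InteractionNetwork":
        return InteractionNetwork(self.graph.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"InteractionNetwork(n={self.n}, m={self.m})"


@dataclass
class HitList:
    """Ordered, deduplicated list of normalized symbols with a provenance label.

    The stand-in for an IP-MS hit list: the proteins pulled down with a bait.
    """

    symbols: list[str]
    label: str = ""

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for s in self.symbols:
            seen.setdefault(normalize_symbol(s), None)
        self.symbols = list(seen)

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def __contains__(self, sym: str) -> bool:
        return sym in set(self.symbols)

    def as_set(self) -> set[str]:
        return set(self.symbols)

    def map_orthologs(self, ortho: "OrthologMap") -> "HitList":
        """Translate symbols through an ortholog map; unmapped symbols pass through."""
        return HitList(
            [ortho.pairs.get(s, s) for s in self.symbols],
            label=f"{self.label}|mapped" if self.label else "mapped",
        )


@dataclass
class GeneSetLibrary:
    """A named collection of gene sets (GO / CORUM / pathway / disease terms)."""

    name: str
    terms: dict[str, set[str]]

    def __post_init__(self) -> None:
        clean: dict[str, set[str]] = {}
        for term, members in self.terms.items():
            mem = {normalize_symbol(s) for s in members}
            if not mem:
                raise ValueError(f"term {term!r} has no members")
            clean[term] = mem
        self.terms = clean

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for members in self.terms.values():
            out |= members
        return out

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class OrthologMap:
    """One-to-one symbol translation table (e.g. mouse symbol -> human symbol)."""

    pairs: dict[str, str]

    def __post_init__(self) -> None:
        self.pairs = {
            normalize_symbol(k): normalize_symbol(v) for k, v in self.pairs.items()
        }


# ---------------------------------------------------------------------------
# Edge lists


def _iter_data_lines(path: Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_edge_list(
    path: str | Path,
    dialect: str = "tsv2col",
    source_label: str | None = None,
) -> InteractionNetwork:
    """Read an undirected edge list in ``tsv2col`` or ``sif`` dialect.

    Returns a simple network: symbols normalized, self-loops dropped,
    duplicate rows collapsed. The number of dropped rows (self-loops +
    duplicates) is reported via ``warnings.warn``. An empty file yields an
    empty network with a warning rather than an error.
    """
    path = Path(path)
    if dialect not in ("tsv2col", "sif"):
        raise ValueError(f"unknown edge-list dialect {dialect!r}")
    label = source_label if source_label is not None else path.name
    net = InteractionNetwork()
    n_rows = n_dropped = 0
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if dialect == "tsv2col":
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            a, b = fields
        else:  # sif: nodeA relation nodeB
            if len(fields) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 columns (SIF), got {len(fields)}"
                )
            a, _, b = fields
        n_rows += 1
        m_before = net.m
        if not net.add_edge(a, b, sources=[label]) or net.m == m_before:
            n_dropped += 1
        # lone symbols from self-loop rows still enter the node set
        if normalize_symbol(a) == normalize_symbol(b):
            net.graph.add_node(normalize_symbol(a))
    if n_rows == 0:
        warnings.warn(f"{path}: no data rows; returning empty network")
    elif n_dropped:
        warnings.warn(
            f"{path}: dropped {n_dropped} of {n_rows} rows (self-loops/duplicates)"
        )
    return net


def write_edge_list(net: InteractionNetwork, path: str | Path) -> None:
    """Write a 2-column TSV edge list (sorted, one row per undirected edge)."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{u}\t{v}\n")
    # isolated nodes are not representable in an edge list; warn if any
    isolated = [n for n in net.graph.nodes if net.graph.degree[n] == 0]
    if isolated:
        warnings.warn(f"{path}: {len(isolated)} isolated nodes not written")


def merge_networks(networks: Sequence[InteractionNetwork]) -> InteractionNetwork:
    """Union of node and edge sets; per-edge source labels are merged.

    Commutative, associative and idempotent on node/edge sets.
    """
    if not networks:
        raise ValueError("merge_networks requires at least one network")
    out = InteractionNetwork()
    for net in networks:
        out.graph.add_nodes_from(net.graph.nodes)
        for u, v, data in net.graph.edges(data=True):
            out.add_edge(u, v, sources=data.get("sources", set()))
    return out


# ---------------------------------------------------------------------------
# Gene lists, GMT libraries, ortholog maps


def read_gene_list(path: str | Path, label: str | None = None) -> HitList:
    """Read a one-symbol-per-line gene list into a :class:`HitList`."""
    path = Path(path)
    symbols = [line.strip() for _, line in _iter_data_lines(path)]
    return HitList(symbols, label=label if label is not None else path.stem)


def write_gene_list(hits: HitList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in hits.symbols:
            fh.write(s + "\n")


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetLibrary:
    """Read a GMT gene-set library (term, description, members...).

    The description column is preserved in the file format but unused.
    """
    path = Path(path)
    terms: dict[str, set[str]] = {}
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"{path}:{lineno}: GMT row needs >= 3 columns, got {len(fields)}"
            )
        term, _desc, *members = fields
        members = [m for m in members if m.strip()]
        if not members:
            raise ParseError(f"{path}:{lineno}: GMT term {term!r} has no members")
        terms[term] = {normalize_symbol(m) for m in members}
    return GeneSetLibrary(name=name if name is not None else path.stem, terms=terms)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(library.terms):
            members = "\t".join(sorted(library.terms[term]))
            fh.write(f"{term}\tna\t{members}\n")


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a 2-column TSV mapping source symbols to target symbols."""
    path = Path(path)
    pairs: dict[str, str] = {}
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        src, dst = (normalize_symbol(f) for f in fields)
        if src in pairs and pairs[src] != dst:
            raise ParseError(
                f"{path}:{lineno}: conflicting mapping for {src} "
                f"({pairs[src]} vs {dst})"
            )
        pairs[src] = dst
    return OrthologMap(pairs)
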