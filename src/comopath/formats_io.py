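"""Readers and writers for gene lists, GMT pathway files, PPI tables and networks.

All gene/protein identifiers pass through :func:`normalize_symbol`
(uppercase, whitespace-stripped); no alias or ortholog mapping is attempted.
TSV dialect throughout: tab-delimited, UTF-8, no quoting, ``#`` comments skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Column presets for PPI tables: generic 2-column edge list, and the HPRD
#: binary-interaction flat file (interactor gene symbols in columns 1 and 4).
PPI_DIALECTS: dict[str, tuple[int, int]] = {
    "edgelist": (0, 1),
    "hprd": (0, 3),
}


def normalize_symbol(symbol: str) -> str:
    """Canonical form of a gene/protein symbol: stripped and uppercased."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """A labelled, normalized set of susceptibility gene symbols.

    Parameters
    ----------
    label
        Short identifier for the disease cluster (e.g. ``"SCZ"``).
    members
        Normalized gene symbols; duplicates are impossible by construction.
    """

    label: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.label:
            raise ValidationError("GeneSet label must be non-empty")
        if any(not m for m in self.members):
            raise ValidationError("GeneSet contains an empty symbol")

    @classmethod
    def from_symbols(cls, label: str, symbols: Iterable[str]) -> "GeneSet":
        members = frozenset(
            normalize_symbol(s) for s in symbols if normalize_symbol(s)
        )
        return cls(label=label, members=members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.members

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.members))


@dataclass(frozen=True)
class PathwayDef:
    """One named pathway with its member genes."""

    pathway_id: str
    display_name: str
    source_db: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(
                f"pathway {self.pathway_id!r} has no members"
            )

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class PathwayCollection:
    """Named pathways plus the background gene universe.

    When ``universe`` is not supplied it is derived as the union of all
    pathway members — the annotation's own gene space, which is the natural
    background for over-representation tests against that annotation.
    """

    pathways: list[PathwayDef]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        ids = [p.pathway_id for p in self.pathways]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate pathway ids: {dup}")
        derived = frozenset().union(*(p.members for p in self.pathways)) \
            if self.pathways else frozenset()
        if not self.universe:
            self.universe = derived
        if len(self.universe) < 1:
            raise ValidationError("pathway collection universe is empty")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self) -> Iterator[PathwayDef]:
        return iter(self.pathways)

    def merged_with(self, other: "PathwayCollection") -> "PathwayCollection":
        """Concatenate two collections into one test family."""
        return PathwayCollection(
            pathways=self.pathways + other.pathways,
            universe=self.universe | other.universe,
        )


@dataclass
class InteractionNetwork:
    """An undirected PPI network with no self-loops and no isolated nodes."""

    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted((a, b))) for a, b in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def validate(self) -> None:
        if any(a == b for a, b in self.graph.edges):
            raise ValidationError("network contains a self-loop")
        isolated = [n for n, d in self.graph.degree if d == 0]
        if isolated:
            raise ValidationError(f"network contains isolated nodes: {isolated[:5]}")


def _data_lines(path: Path) -> Iterator[tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping blanks/comments."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_gene_list(path: str | Path, label: str) -> GeneSet:
    """Read a disease gene list: one symbol per line, or first TSV column.

    Blank lines and ``#`` comments are ignored; symbols are normalized and
    duplicates collapse. Raises :class:`ValidationError` when no valid symbol
    survives.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene list not found: {path}")
    symbols: list[str] = []
    for _, line in _data_lines(path):
        first = line.split("\t")[0]
        sym = normalize_symbol(first)
        if sym:
            symbols.append(sym)
    if not symbols:
        raise ValidationError(f"gene list {path} contains no valid symbols")
    return GeneSet.from_symbols(label, symbols)


def write_gene_list(gene_set: GeneSet, path: str | Path) -> None:
    """Write a gene set, one symbol per line, sorted for determinism."""
    with open(path, "w", encoding="utf-8") as fh:
        for sym in sorted(gene_set.members):
            fh.write(sym + "\n")


def read_gmt(path: str | Path, source_db: str = "GMT") -> PathwayCollection:
    """Read a Broad-format GMT file: name, description, tab-separated members.

    The derived universe is the exact union of all member sets.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GMT file not found: {path}")
    pathways: list[PathwayDef] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"GMT line has {len(fields)} fields, need >= 3", line=lineno
            )
        name, description = fields[0].strip(), fields[1].strip()
        members = frozenset(
            normalize_symbol(f) for f in fields[2:] if normalize_symbol(f)
        )
        if not members:
            raise ParseError(f"pathway {name!r} has no members", line=lineno)
        pathways.append(
            PathwayDef(
                pathway_id=name,
                display_name=description or name,
                source_db=source_db,
                members=members,
            )
        )
    return PathwayCollection(pathways=pathways)


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pw in collection.pathways:
            fh.write(
                "\t".join([pw.pathway_id, pw.display_name, *sorted(pw.members)])
                + "\n"
            )


def read_ppi_table(
    path: str | Path, col_a: int = 0, col_b: int = 1
) -> InteractionNetwork:
    """Read a PPI TSV into a cleaned undirected network.

    Edges are canonicalized as unordered pairs; self-interactions and
    duplicate rows (including reversed duplicates) are removed. Nodes left
    with no edge after cleaning — "disperse nodes" — are dropped, so the
    result contains no isolated nodes.

    ``col_a``/``col_b`` select the interactor columns; use the presets in
    :data:`PPI_DIALECTS` for the generic edge-list and HPRD flat-file layouts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PPI table not found: {path}")
    graph = nx.Graph()
    n_self = n_dup = 0
    needed = max(col_a, col_b) + 1
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < needed:
            raise ParseError(
                f"row has {len(fields)} columns, need >= {needed}", line=lineno
            )
        a = normalize_symbol(fields[col_a])
        b = normalize_symbol(fields[col_b])
        if not a or not b:
            raise ParseError("empty interactor symbol", line=lineno)
        if a == b:
            n_self += 1
            continue
        if graph.has_edge(a, b):
            n_dup += 1  # first occurrence wins
            continue
        graph.add_edge(a, b)
    if n_self or n_dup:
        logger.warning(
            "PPI cleaning: removed %d self-interactions, %d duplicate pairs",
            n_self,
            n_dup,
        )
    if graph.number_of_edges() == 0:
        raise ValidationError(f"no interactions survive cleaning in {path}")
    network = InteractionNetwork(graph=graph)
    network.validate()
    return network


def write_ppi_table(network: InteractionNetwork, path: str | Path) -> None:
    """Write a network as a sorted 2-column edge list TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#interactor_a\tinteractor_b\n")
        for a, b in sorted(network.edges):
            fh.write(f"{a}\t{b}\n")


def _as_nx(graph) -> nx.Graph:
    if isinstance(graph, nx.Graph):
        return graph
    inner = getattr(graph, "graph", None)
    if isinstance(inner, nx.Graph):
        return inner
    raise TypeError(f"cannot interpret {type(graph).__name__} as a network")


def write_network(graph, path: str | Path, format: str = "sif") -> None:
    """Export a network for Cytoscape as SIF, GraphML or a TSV edge list.

    SIF: one ``nodeA <relation> nodeB`` line per edge; the relation token is
    the edge's ``interaction`` attribute (default ``pp``). GraphML carries all
    node and edge attributes (node class, degrees, kappa scores). The TSV edge
    list round-trips exactly through :func:`read_ppi_table`.
    """
    g = _as_nx(graph)
    fmt = format.lower()
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for a, b, data in sorted(g.edges(data=True)):
                rel = data.get("interaction", "pp")
                fh.write(f"{a}\t{rel}\t{b}\n")
    elif fmt == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#node_a\tinteraction\tnode_b\n")
            for a, b, data in sorted(g.edges(data=True)):
                rel = data.get("interaction", "pp")
                fh.write(f"{a}\t{rel}\t{b}\n")
    else:
        raise ValidationError(f"unknown network format {format!r}")


ENRICHMENT_COLUMNS: Sequence[str] = (
    "pathway",
    "specificity",
    "p_adjusted",
    "total",
    "unique_cluster1",
    "unique_cluster2",
    "common",
)


def write_enrichment_table(records, path: str | Path) -> None:
    """Write enrichment records as a TSV mirroring the two-cluster table layout.

    Columns: pathway name, specificity label, adjusted p, total mapped count,
    unique cluster-1 count, unique cluster-2 count, common count. Records with
    equal adjusted p keep their input order.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(ENRICHMENT_COLUMNS) + "\n")
        for rec in records:
            c = rec.counts
            fh.write(
                "\t".join(
                    [
                        rec.pathway.display_name,
                        rec.label.value,
                        format(rec.p_adj, ".6g"),
                        str(c.total),
                        str(c.unique1),
                        str(c.unique2),
                        str(c.common),
                    ]
                )
                + "\n"
            )
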