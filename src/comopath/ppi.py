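"""PPI-based inference of pleiotropic candidate genes and hub proteins.

Susceptibility proteins of both diseases are mapped onto a cleaned
interactome and retrieved together with their first interaction neighbours.
A neighbour touching susceptibility proteins of both diseases is, by guilt
by association, a candidate pleiotropic risk factor; candidates with at
least ``h`` distinct partners from each disease (default 5) are hubs.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import pandas as pd

from .errors import ValidationError
from .formats_io import GeneSet, InteractionNetwork

logger = logging.getLogger(__name__)


class NodeClass(enum.Enum):
    SUS1 = "sus1"          # susceptibility protein of disease 1 only
    SUS2 = "sus2"          # susceptibility protein of disease 2 only
    SUS_BOTH = "sus_both"  # on both diseases' susceptibility lists
    NEIGHBOR = "neighbor"  # non-susceptibility first neighbour

    @property
    def is_susceptibility(self) -> bool:
        return self is not NodeClass.NEIGHBOR


@dataclass
class AnnotatedPPINetwork:
    """Susceptibility proteins plus first neighbours, with node classes.

    Backed by a :class:`networkx.Graph` whose nodes carry a ``node_class``
    attribute; classes partition the node set.
    """

    graph: nx.Graph

    @property
    def node_class(self) -> dict[str, NodeClass]:
        return {
            n: NodeClass(d["node_class"])
            for n, d in self.graph.nodes(data=True)
        }

    def nodes_of_class(self, cls: NodeClass) -> set[str]:
        return {
            n
            for n, d in self.graph.nodes(data=True)
            if d["node_class"] == cls.value
        }

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def class_counts(self) -> dict[str, int]:
        out = {c.value: 0 for c in NodeClass}
        for _, d in self.graph.nodes(data=True):
            out[d["node_class"]] += 1
        return out

    def partner_degrees(self, protein: str) -> tuple[int, int]:
        """Distinct disease-1 / disease-2 susceptibility partners of a node.

        Partners on both lists count toward both diseases.
        """
        deg1 = deg2 = 0
        for nb in self.graph.neighbors(protein):
            cls = self.graph.nodes[nb]["node_class"]
            if cls in (NodeClass.SUS1.value, NodeClass.SUS_BOTH.value):
                deg1 += 1
            if cls in (NodeClass.SUS2.value, NodeClass.SUS_BOTH.value):
                deg2 += 1
        return deg1, deg2


@dataclass(frozen=True)
class CandidateRecord:
    """A non-susceptibility protein interacting with both diseases' proteins."""

    protein: str
    deg1: int
    deg2: int
    is_hub: bool = False


def annotate_network(
    ppi: InteractionNetwork, set1: GeneSet, set2: GeneSet
) -> AnnotatedPPINetwork:
    """Extract susceptibility proteins and their first neighbours from a PPI.

    Susceptibility symbols absent from the interactome are dropped (count
    logged). Every retained non-susceptibility node is adjacent to at least
    one susceptibility protein; the edge set is the induced subgraph on the
    retained nodes.
    """
    sus_all = set1.members | set2.members
    present = sus_all & ppi.nodes
    n_dropped = len(sus_all) - len(present)
    if n_dropped:
        logger.info(
            "%d susceptibility proteins absent from the PPI were dropped",
            n_dropped,
        )
    if not present:
        raise ValidationError(
            "no susceptibility protein maps into the PPI network"
        )
    neighbors = set()
    for p in present:
        neighbors.update(ppi.graph.neighbors(p))
    neighbors -= sus_all

    keep = present | neighbors
    sub = nx.Graph(ppi.graph.subgraph(keep))
    for node in sub.nodes:
        if node in set1.members and node in set2.members:
            cls = NodeClass.SUS_BOTH
        elif node in set1.members:
            cls = NodeClass.SUS1
        elif node in set2.members:
            cls = NodeClass.SUS2
        else:
            cls = NodeClass.NEIGHBOR
        sub.nodes[node]["node_class"] = cls.value
    return AnnotatedPPINetwork(graph=sub)


def infer_candidates(
    net: AnnotatedPPINetwork, min_each: int = 1
) -> list[CandidateRecord]:
    """Neighbour proteins interacting with both diseases' susceptibility proteins.

    A neighbour is emitted when it has at least ``min_each`` distinct
    susceptibility partners from each disease (proteins on both lists count
    toward both). Results are sorted by min(deg1, deg2) descending, then
    total partner count descending, then symbol.
    """
    if min_each < 1:
        raise ValidationError(f"min_each={min_each} must be >= 1")
    out = []
    for protein in net.nodes_of_class(NodeClass.NEIGHBOR):
        deg1, deg2 = net.partner_degrees(protein)
        if deg1 >= min_each and deg2 >= min_each:
            out.append(CandidateRecord(protein=protein, deg1=deg1, deg2=deg2))
    out.sort(
        key=lambda r: (-min(r.deg1, r.deg2), -(r.deg1 + r.deg2), r.protein)
    )
    return out


def detect_hubs(
    candidates: Sequence[CandidateRecord], h: int = 5
) -> list[CandidateRecord]:
    """Candidates with at least ``h`` partners from each disease (inclusive)."""
    if h < 1:
        raise ValidationError(f"hub threshold h={h} must be >= 1")
    return [
        CandidateRecord(r.protein, r.deg1, r.deg2, is_hub=True)
        for r in candidates
        if r.deg1 >= h and r.deg2 >= h
    ]


def extract_subnetwork(
    net: AnnotatedPPINetwork, candidates: Sequence[CandidateRecord]
) -> AnnotatedPPINetwork:
    """Induced sub-network of the candidates and their susceptibility partners.

    Node set: candidates plus every susceptibility protein adjacent to one.
    Edge set: all parent-network edges among the retained nodes (induced
    semantics, so susceptibility–susceptibility and candidate–candidate
    adjacencies are kept). Node classes carry over.
    """
    if not candidates:
        raise ValidationError("candidate list is empty")
    neighbor_nodes = net.nodes_of_class(NodeClass.NEIGHBOR)
    cand_nodes = {r.protein for r in candidates}
    missing = cand_nodes - neighbor_nodes
    if missing:
        raise ValidationError(
            f"candidates not in the network's neighbour stratum: "
            f"{sorted(missing)[:5]}"
        )
    keep = set(cand_nodes)
    for protein in cand_nodes:
        for nb in net.graph.neighbors(protein):
            if NodeClass(net.graph.nodes[nb]["node_class"]).is_susceptibility:
                keep.add(nb)
    sub = nx.Graph(net.graph.subgraph(keep))
    return AnnotatedPPINetwork(graph=sub)


@dataclass
class PartnerCensus:
    """Per-neighbour partner degrees plus aggregate threshold counts."""

    table: pd.DataFrame
    aggregates: dict[str, int]


def partner_census(net: AnnotatedPPINetwork) -> PartnerCensus:
    """Count, per neighbour, its susceptibility partners from each disease.

    Aggregates report how many neighbours reach deg1 >= x and deg2 >= x for
    x in {1, 2}, and how many satisfy the dual rule (>= 1 from each disease).
    """
    rows = []
    for protein in sorted(net.nodes_of_class(NodeClass.NEIGHBOR)):
        deg1, deg2 = net.partner_degrees(protein)
        rows.append({"protein": protein, "deg1": deg1, "deg2": deg2})
    table = pd.DataFrame(rows, columns=["protein", "deg1", "deg2"])
    agg = {}
    for x in (1, 2):
        agg[f"deg1_ge_{x}"] = int((table["deg1"] >= x).sum()) if len(table) else 0
        agg[f"deg2_ge_{x}"] = int((table["deg2"] >= x).sum()) if len(table) else 0
    agg["dual"] = (
        int(((table["deg1"] >= 1) & (table["deg2"] >= 1)).sum())
        if len(table)
        else 0
    )
    return PartnerCensus(table=table, aggregates=agg)
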