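"""Pathway–pathway crosstalk network from kappa scores on shared genes.

Two significant pathways are joined by an edge when the chance-corrected
agreement (Cohen's kappa) of their gene-membership indicators, evaluated over
the mapped query genes, reaches a connectivity threshold ``theta`` (default
0.4). The mapped genes themselves are overlaid as a second node layer, each
tagged with its cluster of origin and linked to every significant pathway it
belongs to.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .enrichment import EnrichmentRecord, EnrichmentResult
from .errors import DomainError, ValidationError
from .formats_io import GeneSet


def kappa_score(
    members_a: Iterable[str],
    members_b: Iterable[str],
    domain: Iterable[str],
) -> float:
    """Cohen's kappa between two pathways' membership indicators over a domain.

    With ``a = |A∩B|``, ``b = |A\\B|``, ``c = |B\\A|``, ``d`` the genes in
    neither set and ``T`` the domain size, the observed agreement is
    ``Po = (a+d)/T`` and the chance agreement
    ``Pe = ((a+b)(a+c) + (c+d)(b+d)) / T**2``; kappa is ``(Po-Pe)/(1-Pe)``.

    Degenerate case ``Pe = 1`` (both indicators constant): returns 1.0 when
    the two indicator vectors are identical, else 0.0 — the continuity
    convention for perfect agreement on a constant vector.
    """
    A, B, D = set(members_a), set(members_b), set(domain)
    if not D:
        raise DomainError("kappa domain must be non-empty")
    if not A <= D:
        raise DomainError(f"members outside domain: {sorted(A - D)[:5]}")
    if not B <= D:
        raise DomainError(f"members outside domain: {sorted(B - D)[:5]}")
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    T = len(D)
    d = T - a - b - c
    po = (a + d) / T
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / (T * T)
    if pe == 1.0:
        return 1.0 if A == B else 0.0
    return (po - pe) / (1.0 - pe)


@dataclass
class CrosstalkGraph:
    """Pathway nodes joined by kappa edges, with an overlaid gene layer.

    Backed by one :class:`networkx.Graph`: pathway nodes carry
    ``kind="pathway"`` plus the enrichment attributes, gene nodes carry
    ``kind="gene"`` and their cluster origin; kappa edges carry
    ``interaction="crosstalk"`` and the score, membership edges
    ``interaction="contains"``.
    """

    graph: nx.Graph

    @property
    def pathway_nodes(self) -> set[str]:
        return {
            n for n, d in self.graph.nodes(data=True) if d["kind"] == "pathway"
        }

    @property
    def gene_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == "gene"}

    @property
    def kappa_edges(self) -> dict[tuple[str, str], float]:
        return {
            tuple(sorted((a, b))): d["kappa"]
            for a, b, d in self.graph.edges(data=True)
            if d["interaction"] == "crosstalk"
        }

    @property
    def membership_edges(self) -> set[tuple[str, str]]:
        """(gene, pathway) pairs."""
        out = set()
        for a, b, d in self.graph.edges(data=True):
            if d["interaction"] != "contains":
                continue
            if self.graph.nodes[a]["kind"] == "gene":
                out.add((a, b))
            else:
                out.add((b, a))
        return out

    def gene_origin(self, gene: str) -> str:
        return self.graph.nodes[gene]["origin"]


def build_crosstalk_graph(
    records: EnrichmentResult | Sequence[EnrichmentRecord],
    cluster1: GeneSet,
    cluster2: GeneSet,
    theta: float = 0.4,
    domain: Iterable[str] | None = None,
) -> CrosstalkGraph:
    """Construct the crosstalk network for one enrichment run.

    Each significant pathway's membership vector is its members restricted to
    the susceptibility query; pairs whose kappa reaches ``theta`` are joined.
    ``domain`` defaults to the run's mapped query genes (every susceptibility
    gene appearing in at least one tested pathway); pass
    ``EnrichmentResult.universe`` to score agreement over the full background
    instead.
    """
    rec_list = list(records)
    if not rec_list:
        raise ValidationError("need at least one enrichment record")
    if not 0 < theta <= 1:
        raise DomainError(f"theta={theta} must lie in (0, 1]")

    query = cluster1.members | cluster2.members
    if domain is None:
        if isinstance(records, EnrichmentResult):
            domain_set = set(records.mapped_query)
        else:
            domain_set = set().union(
                *(r.pathway.members & query for r in rec_list)
            )
    else:
        domain_set = set(domain)

    g = nx.Graph()
    mapped: dict[str, set[str]] = {}
    for rec in rec_list:
        pid = rec.pathway.pathway_id
        mapped[pid] = rec.pathway.members & query & domain_set
        c = rec.counts
        frac1 = (c.unique1 + c.common) / c.total
        frac2 = (c.unique2 + c.common) / c.total
        g.add_node(
            pid,
            kind="pathway",
            name=rec.pathway.display_name,
            specificity=rec.label.value,
            p_adj=rec.p_adj,
            cluster1_fraction=frac1,
            cluster2_fraction=frac2,
        )

    pids = sorted(mapped)
    for i, pa in enumerate(pids):
        for pb in pids[i + 1:]:
            score = kappa_score(mapped[pa], mapped[pb], domain_set)
            if score >= theta:
                g.add_edge(pa, pb, interaction="crosstalk", kappa=score)

    for pid in pids:
        for gene in sorted(mapped[pid]):
            if gene not in g:
                in1, in2 = gene in cluster1.members, gene in cluster2.members
                origin = "both" if in1 and in2 else ("1" if in1 else "2")
                g.add_node(gene, kind="gene", origin=origin)
            g.add_edge(gene, pid, interaction="contains")

    return CrosstalkGraph(graph=g)


def shared_gene_report(graph: CrosstalkGraph) -> pd.DataFrame:
    """Tabulate each overlaid gene with the pathways it maps into.

    One row per gene node with its membership degree and the sorted pathway
    list; rows ordered by pathway count descending, then symbol.
    """
    membership: dict[str, list[str]] = {}
    for gene, pathway in graph.membership_edges:
        membership.setdefault(gene, []).append(pathway)
    rows = [
        {
            "gene": gene,
            "pathway_count": len(pws),
            "pathways": ";".join(sorted(pws)),
        }
        for gene, pws in membership.items()
    ]
    df = pd.DataFrame(rows, columns=["gene", "pathway_count", "pathways"])
    if len(df):
        df = df.sort_values(
            ["pathway_count", "gene"], ascending=[False, True]
        ).reset_index(drop=True)
    return df
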