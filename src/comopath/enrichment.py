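"""Two-cluster pathway over-representation analysis.

Both disease gene lists are merged into one query; each pathway gets a single
hypergeometric upper-tail p-value against the background universe, adjusted
across the whole tested family by Benjamini–Hochberg. Significant pathways are
then classified as specific to one cluster — when more than a fraction ``tau``
(default 0.66) of the pathway's mapped genes come from that cluster — or as
shared by both.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, ValidationError
from .formats_io import GeneSet, PathwayCollection, PathwayDef

logger = logging.getLogger(__name__)


class Specificity(enum.Enum):
    """Cluster-specificity label of a significant pathway."""

    CLUSTER1 = "cluster1"
    CLUSTER2 = "cluster2"
    BOTH = "both"


@dataclass(frozen=True)
class ClusterCounts:
    """Per-pathway breakdown of mapped query genes by cluster origin.

    ``total = unique1 + unique2 + common`` always holds: each mapped gene is
    in exactly one of the three strata.
    """

    unique1: int
    unique2: int
    common: int

    def __post_init__(self) -> None:
        if min(self.unique1, self.unique2, self.common) < 0:
            raise DomainError("cluster counts must be non-negative")

    @property
    def total(self) -> int:
        return self.unique1 + self.unique2 + self.common

    def swapped(self) -> "ClusterCounts":
        return ClusterCounts(self.unique2, self.unique1, self.common)


@dataclass(frozen=True)
class EnrichmentRecord:
    """One pathway's enrichment result.

    ``k``/``K``/``n``/``N`` are the hypergeometric overlap, pathway size,
    query size and universe size, all within the background universe.
    """

    pathway: PathwayDef
    counts: ClusterCounts
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_adj: float
    label: Specificity


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k), inclusive of ``k``.

    ``X`` counts annotated genes in a size-``n`` query drawn without
    replacement from a size-``N`` universe containing ``K`` annotated genes.
    """
    if not 0 <= K <= N:
        raise DomainError(f"pathway size K={K} outside [0, N={N}]")
    if not 0 <= n <= N:
        raise DomainError(f"query size n={n} outside [0, N={N}]")
    if not 0 <= k <= min(K, n):
        raise DomainError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    # sf(k-1) = P(X > k-1) = P(X >= k)
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DomainError("p-values must lie in [0, 1]")
    adjusted = multipletests(p, method="fdr_bh")[1]
    return [float(q) for q in adjusted]


def classify_specificity(counts: ClusterCounts, tau: float = 0.66) -> Specificity:
    """Assign a cluster-specificity label from mapped-gene proportions.

    The fraction attributed to cluster *i* is ``(unique_i + common) / total``:
    genes on both lists count toward both clusters. A pathway is specific to
    the cluster whose fraction strictly exceeds ``tau`` while the other's does
    not; otherwise it is shared (``BOTH``).
    """
    if not 0.5 < tau < 1:
        raise DomainError(f"tau={tau} must lie in (0.5, 1)")
    total = counts.total
    if total < 1:
        raise DomainError("cannot classify a pathway with zero mapped genes")
    frac1 = (counts.unique1 + counts.common) / total
    frac2 = (counts.unique2 + counts.common) / total
    if frac1 > tau and frac2 <= tau:
        return Specificity.CLUSTER1
    if frac2 > tau and frac1 <= tau:
        return Specificity.CLUSTER2
    return Specificity.BOTH


@dataclass
class EnrichmentResult:
    """Significant pathways plus the query context they were computed in.

    Behaves as a sequence of :class:`EnrichmentRecord`, sorted by adjusted
    p ascending (ties broken by pathway id). ``mapped_query`` is the set of
    query genes appearing in at least one *tested* pathway — the membership
    domain the crosstalk kappa scores are computed over.
    """

    records: list[EnrichmentRecord]
    query: frozenset[str]
    mapped_query: frozenset[str]
    universe: frozenset[str]
    n_tested: int
    alpha: float
    tau: float

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[EnrichmentRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def label_counts(self) -> dict[str, int]:
        out = {s.value: 0 for s in Specificity}
        for rec in self.records:
            out[rec.label.value] += 1
        return out


def enrich_two_cluster(
    cluster1: GeneSet,
    cluster2: GeneSet,
    collection: PathwayCollection,
    alpha: float = 0.05,
    tau: float = 0.66,
) -> EnrichmentResult:
    """Two-cluster over-representation across a pathway collection.

    The query is ``(cluster1 | cluster2) & universe``. Pathways overlapping
    the query in at least one gene form the BH family; each gets a
    hypergeometric upper-tail p-value, and records with adjusted p < ``alpha``
    are retained, classified, and sorted by adjusted p.
    """
    if not 0 < alpha < 1:
        raise DomainError(f"alpha={alpha} must lie in (0, 1)")
    if not cluster1.members or not cluster2.members:
        raise ValidationError("both clusters must be non-empty")
    universe = collection.universe
    set1 = cluster1.members & universe
    set2 = cluster2.members & universe
    query = set1 | set2
    if not query:
        raise ValidationError(
            "no query gene maps into the background universe"
        )
    N = len(universe)
    n = len(query)

    tested: list[tuple[PathwayDef, frozenset[str]]] = []
    n_skipped = 0
    for pw in collection:
        members = pw.members & universe
        overlap = members & query
        if not overlap:
            n_skipped += 1  # k = 0: untestable, kept out of the BH family
            continue
        tested.append((pw, members))
    if n_skipped:
        logger.info("excluded %d pathways with zero query overlap", n_skipped)
    if not tested:
        return EnrichmentResult(
            records=[],
            query=frozenset(query),
            mapped_query=frozenset(),
            universe=universe,
            n_tested=0,
            alpha=alpha,
            tau=tau,
        )

    p_raw = [
        hypergeom_tail(len(members & query), len(members), n, N)
        for _, members in tested
    ]
    p_adj = bh_adjust(p_raw)

    mapped_query = frozenset().union(
        *(members & query for _, members in tested)
    )

    records: list[EnrichmentRecord] = []
    for (pw, members), pr, pa in zip(tested, p_raw, p_adj):
        if pa >= alpha:
            continue
        mapped = members & query
        common = len(mapped & set1 & set2)
        unique1 = len(mapped & set1) - common
        unique2 = len(mapped & set2) - common
        counts = ClusterCounts(unique1=unique1, unique2=unique2, common=common)
        records.append(
            EnrichmentRecord(
                pathway=pw,
                counts=counts,
                k=counts.total,
                K=len(members),
                n=n,
                N=N,
                p_raw=pr,
                p_adj=pa,
                label=classify_specificity(counts, tau=tau),
            )
        )
    records.sort(key=lambda r: (r.p_adj, r.pathway.pathway_id))
    return EnrichmentResult(
        records=records,
        query=frozenset(query),
        mapped_query=mapped_query,
        universe=universe,
        n_tested=len(tested),
        alpha=alpha,
        tau=tau,
    )
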