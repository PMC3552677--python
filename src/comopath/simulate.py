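"""Seeded synthetic benchmark with planted ground truth.

Emulates the dual-disease study design end to end: two partially overlapping
susceptibility gene lists, a pathway annotation containing cluster-specific,
shared-enriched and null pathways, and an undirected PPI network with planted
pleiotropic candidate proteins wired to prescribed numbers of each disease's
proteins. Everything is a pure function of the seed, planted wiring is exact
(partners sampled without replacement), and all files are emitted in the
formats the readers in :mod:`comopath.formats_io` consume.

Defaults mirror the study conditions: 196 + 200 susceptibility genes with 14
shared (union 382) in a 2,000-gene universe; 10 cluster-1-specific, 11
cluster-2-specific and 7 shared planted pathways of size 20 drawing 75% of
their members from the target cluster(s), plus 50 nulls; 20 planted dual
candidates of which 9 have at least 5 partners from each disease.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError
from .formats_io import (
    GeneSet,
    read_gene_list,
    read_gmt,
    read_ppi_table,
)

#: (disease-1 partners, disease-2 partners) for each planted candidate.
#: The first nine satisfy the hub rule (both >= 5).
DEFAULT_CANDIDATE_WIRING: tuple[tuple[int, int], ...] = (
    (5, 5), (5, 6), (6, 5), (6, 6), (7, 5), (5, 7), (8, 6), (6, 8), (7, 7),
    (1, 1), (1, 2), (2, 1), (2, 2), (3, 1), (1, 3), (3, 3), (4, 2), (2, 4),
    (4, 4), (4, 1),
)

FILE_NAMES = {
    "cluster1": "cluster1.txt",
    "cluster2": "cluster2.txt",
    "gmt": "pathways.gmt",
    "ppi": "ppi.tsv",
    "background": "background.txt",
    "truth": "truth.yaml",
}


@dataclass(frozen=True)
class PathwayPlan:
    """Counts and composition of the planted pathway collection.

    Within each cluster-specific group, the first ``2 * n_crosstalk_pairs``
    pathways are generated in pairs sharing ``crosstalk_overlap`` of their
    target-cluster members, so the kappa crosstalk layer has planted edges
    to recover (real annotations contain heavily overlapping pathways).
    """

    n_cluster1: int = 10
    n_cluster2: int = 11
    n_shared: int = 7
    n_null: int = 50
    size: int = 20
    null_size: int = 20
    enrichment_fraction: float = 0.75
    n_crosstalk_pairs: int = 2
    crosstalk_overlap: float = 0.6

    @property
    def n_planted(self) -> int:
        return self.n_cluster1 + self.n_cluster2 + self.n_shared


@dataclass(frozen=True)
class PPIPlan:
    """Topology plan for the synthetic interactome.

    Decoys split into two helper pools, each wired only to one disease's
    exclusive susceptibility proteins, so no decoy ever satisfies the dual
    rule by accident; planted candidates are wired exactly to their
    (deg1, deg2) targets. Background decoy–decoy edges are Erdős–Rényi by
    default, or preferential attachment with ``model="preferential"``.
    """

    n_decoys: int = 200
    background_edge_prob: float = 0.02
    model: str = "erdos_renyi"
    mean_extra_sus_links: float = 1.0
    planted_candidates: tuple[tuple[int, int], ...] = DEFAULT_CANDIDATE_WIRING


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generator configuration; all randomness flows from ``seed``."""

    seed: int = 0
    universe_size: int = 2000
    n_genes_1: int = 196
    n_genes_2: int = 200
    n_common: int = 14
    pathways: PathwayPlan = field(default_factory=PathwayPlan)
    ppi: PPIPlan = field(default_factory=PPIPlan)
    #: each entry plants one shared gene into that many enriched pathways
    multi_gene_memberships: tuple[int, ...] = (12, 4)

    def validate(self) -> None:
        if self.n_common > min(self.n_genes_1, self.n_genes_2):
            raise ValidationError(
                "n_common exceeds a disease list size"
            )
        if self.n_genes_1 + self.n_genes_2 - self.n_common > self.universe_size:
            raise ValidationError("gene lists do not fit in the universe")
        pw = self.pathways
        if max(pw.size, pw.null_size) > self.universe_size:
            raise ValidationError("pathway size exceeds universe size")
        if not 0 <= pw.enrichment_fraction <= 1:
            raise ValidationError("enrichment_fraction outside [0, 1]")
        if not 0 <= self.ppi.background_edge_prob <= 1:
            raise ValidationError("background_edge_prob outside [0, 1]")
        if len(self.multi_gene_memberships) > self.n_common:
            raise ValidationError(
                "more multi-pathway genes than shared genes available"
            )
        if any(k > pw.n_planted for k in self.multi_gene_memberships):
            raise ValidationError(
                "multi-pathway membership exceeds planted pathway count"
            )
        if 2 * pw.n_crosstalk_pairs > min(pw.n_cluster1, pw.n_cluster2):
            raise ValidationError(
                "crosstalk pairs exceed the cluster-specific pathway counts"
            )
        if not 0 <= pw.crosstalk_overlap <= 1:
            raise ValidationError("crosstalk_overlap outside [0, 1]")
        n1_excl = self.n_genes_1 - self.n_common
        n2_excl = self.n_genes_2 - self.n_common
        for d1, d2 in self.ppi.planted_candidates:
            if d1 < 1 or d2 < 1:
                raise ValidationError("planted candidate degrees must be >= 1")
            if d1 > n1_excl or d2 > n2_excl:
                raise ValidationError(
                    f"candidate wiring ({d1},{d2}) exceeds available "
                    f"exclusive susceptibility proteins ({n1_excl},{n2_excl})"
                )

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticConfig":
        data = dict(data)
        if "pathways" in data:
            data["pathways"] = PathwayPlan(**data["pathways"])
        if "ppi" in data:
            ppi = dict(data["ppi"])
            if "planted_candidates" in ppi:
                ppi["planted_candidates"] = tuple(
                    tuple(pair) for pair in ppi["planted_candidates"]
                )
            data["ppi"] = PPIPlan(**ppi)
        if "multi_gene_memberships" in data:
            data["multi_gene_memberships"] = tuple(
                data["multi_gene_memberships"]
            )
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class SyntheticTruth:
    """Planted ground truth, consistent with the emitted files by recount."""

    config: SyntheticConfig
    out_dir: Path
    cluster1: frozenset[str]
    cluster2: frozenset[str]
    pathway_labels: dict[str, str]          # pathway id -> cluster1/cluster2/both/null
    pathway_target_counts: dict[str, int]   # members drawn from the target cluster(s)
    multi_genes: dict[str, int]             # planted gene -> enriched-pathway memberships
    candidates: dict[str, tuple[int, int]]  # planted protein -> (deg1, deg2)
    candidate_partners: dict[str, tuple[tuple[str, ...], tuple[str, ...]]]

    @property
    def files(self) -> dict[str, Path]:
        return {key: self.out_dir / name for key, name in FILE_NAMES.items()}

    @property
    def hub_truth(self) -> set[str]:
        """Planted candidates meeting the default hub rule (>= 5 each)."""
        return {
            p for p, (d1, d2) in self.candidates.items() if d1 >= 5 and d2 >= 5
        }

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "cluster1": sorted(self.cluster1),
            "cluster2": sorted(self.cluster2),
            "pathway_labels": dict(sorted(self.pathway_labels.items())),
            "pathway_target_counts": dict(
                sorted(self.pathway_target_counts.items())
            ),
            "multi_genes": dict(sorted(self.multi_genes.items())),
            "candidates": {
                p: list(self.candidates[p]) for p in sorted(self.candidates)
            },
            "candidate_partners": {
                p: [sorted(a), sorted(b)]
                for p, (a, b) in sorted(self.candidate_partners.items())
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticTruth":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(
            config=SyntheticConfig.from_dict(data["config"]),
            out_dir=path.parent,
            cluster1=frozenset(data["cluster1"]),
            cluster2=frozenset(data["cluster2"]),
            pathway_labels=data["pathway_labels"],
            pathway_target_counts=data["pathway_target_counts"],
            multi_genes=data["multi_genes"],
            candidates={
                p: tuple(v) for p, v in data["candidates"].items()
            },
            candidate_partners={
                p: (tuple(a), tuple(b))
                for p, (a, b) in data["candidate_partners"].items()
            },
        )


def _sample(rng: np.random.Generator, pool: list[str], k: int) -> list[str]:
    """Draw k distinct items from a (sorted) pool, deterministically."""
    if k > len(pool):
        raise ValidationError(
            f"cannot draw {k} items from a pool of {len(pool)}"
        )
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in idx]


def generate(
    config: SyntheticConfig, out_dir: str | Path
) -> SyntheticTruth:
    """Generate the synthetic dataset and write it under ``out_dir``.

    Emits ``cluster1.txt``, ``cluster2.txt``, ``pathways.gmt``, ``ppi.tsv``,
    ``background.txt`` and ``truth.yaml``. Identical configs yield
    byte-identical files.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    width = max(4, len(str(config.universe_size)))
    universe = [f"G{i:0{width}d}" for i in range(1, config.universe_size + 1)]

    # --- disease gene lists ------------------------------------------------
    common = sorted(_sample(rng, universe, config.n_common))
    pool = sorted(set(universe) - set(common))
    c1_excl = sorted(_sample(rng, pool, config.n_genes_1 - config.n_common))
    pool = sorted(set(pool) - set(c1_excl))
    c2_excl = sorted(_sample(rng, pool, config.n_genes_2 - config.n_common))
    cluster1 = sorted(common + c1_excl)
    cluster2 = sorted(common + c2_excl)

    # shared genes reserved as planted multi-pathway markers are kept out of
    # the random pathway draws so their membership degree is exact
    multi_genes = {
        common[j]: k for j, k in enumerate(config.multi_gene_memberships)
    }

    # --- pathway collection ------------------------------------------------
    pw = config.pathways
    k_target = int(round(pw.size * pw.enrichment_fraction))
    reserved = set(multi_genes)
    uni_set = set(universe)

    pathway_rows: list[tuple[str, str, list[str]]] = []  # (id, label, members)
    c1_pool = sorted(set(cluster1) - reserved)
    c2_pool = sorted(set(cluster2) - reserved)
    both_excl_pool_1 = sorted(set(c1_excl) - reserved)
    both_excl_pool_2 = sorted(set(c2_excl) - reserved)

    block_size = int(round(pw.crosstalk_overlap * k_target))

    def _planted_group(prefix: str, label: str, n_pw: int,
                       target_pool: list[str], filler_pool: list[str]) -> None:
        shared_block: list[str] = []
        for i in range(n_pw):
            if i // 2 < pw.n_crosstalk_pairs:
                if i % 2 == 0:
                    shared_block = _sample(rng, target_pool, block_size)
                rest = _sample(
                    rng,
                    sorted(set(target_pool) - set(shared_block)),
                    k_target - block_size,
                )
                target = shared_block + rest
            else:
                target = _sample(rng, target_pool, k_target)
            filler = _sample(rng, filler_pool, pw.size - k_target)
            pathway_rows.append(
                (f"{prefix}_{i + 1:02d}", label, target + filler)
            )

    _planted_group(
        "C1", "cluster1", pw.n_cluster1, c1_pool,
        sorted(uni_set - set(cluster1) - reserved),
    )
    _planted_group(
        "C2", "cluster2", pw.n_cluster2, c2_pool,
        sorted(uni_set - set(cluster2) - reserved),
    )
    for i in range(pw.n_shared):
        # balanced draw from the two exclusive strata keeps neither
        # cluster's fraction above the specificity threshold
        k1 = k_target // 2 + (i % 2 if k_target % 2 else 0)
        k2 = k_target - k1
        target = _sample(rng, both_excl_pool_1, k1) + _sample(
            rng, both_excl_pool_2, k2
        )
        filler_pool = sorted(
            uni_set - set(cluster1) - set(cluster2) - reserved
        )
        filler = _sample(rng, filler_pool, pw.size - k_target)
        pathway_rows.append((f"SH_{i + 1:02d}", "both", target + filler))
    for i in range(pw.n_null):
        members = _sample(rng, sorted(uni_set - reserved), pw.null_size)
        pathway_rows.append((f"NULL_{i + 1:02d}", "null", members))

    # plant the multi-pathway shared genes into the first k enriched pathways
    enriched_ids = [pid for pid, label, _ in pathway_rows if label != "null"]
    members_by_id = {pid: set(m) for pid, _, m in pathway_rows}
    for gene, k in multi_genes.items():
        for pid in enriched_ids[:k]:
            members_by_id[pid].add(gene)

    pathway_labels: dict[str, str] = {}
    pathway_target_counts: dict[str, int] = {}
    set1, set2 = set(cluster1), set(cluster2)
    for pid, label, _ in pathway_rows:
        pathway_labels[pid] = label
        members = members_by_id[pid]
        if label == "cluster1":
            pathway_target_counts[pid] = len(members & set1)
        elif label == "cluster2":
            pathway_target_counts[pid] = len(members & set2)
        elif label == "both":
            pathway_target_counts[pid] = len(members & (set1 | set2))
        else:
            pathway_target_counts[pid] = 0

    # --- PPI network -------------------------------------------------------
    plan = config.ppi
    cwidth = max(3, len(str(len(plan.planted_candidates))))
    cand_names = [
        f"CAND{i + 1:0{cwidth}d}" for i in range(len(plan.planted_candidates))
    ]
    dwidth = max(4, len(str(plan.n_decoys)))
    decoys = [f"D{i + 1:0{dwidth}d}" for i in range(plan.n_decoys)]
    half = plan.n_decoys // 2
    helpers1, helpers2 = decoys[:half], decoys[half:]

    edges: set[tuple[str, str]] = set()

    def add_edge(a: str, b: str) -> None:
        if a != b:
            edges.add((a, b) if a < b else (b, a))

    candidates: dict[str, tuple[int, int]] = {}
    candidate_partners: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {}
    for name, (d1, d2) in zip(cand_names, plan.planted_candidates):
        p1 = _sample(rng, sorted(c1_excl), d1)
        p2 = _sample(rng, sorted(c2_excl), d2)
        for p in p1 + p2:
            add_edge(name, p)
        candidates[name] = (d1, d2)
        candidate_partners[name] = (tuple(sorted(p1)), tuple(sorted(p2)))

    # helper decoys: single-disease attachments only
    for helper_pool, sus_pool in ((helpers1, c1_excl), (helpers2, c2_excl)):
        sus_sorted = sorted(sus_pool)
        for helper in helper_pool:
            n_att = 1 + int(rng.poisson(plan.mean_extra_sus_links))
            for p in _sample(rng, sus_sorted, min(n_att, len(sus_sorted))):
                add_edge(helper, p)

    # coverage pass: every susceptibility protein appears in the PPI
    covered = {x for e in edges for x in e}
    for p in sorted(set(c1_excl) - covered):
        add_edge(p, helpers1[int(rng.integers(len(helpers1)))])
    for p in sorted(set(c2_excl) - covered):
        add_edge(p, helpers2[int(rng.integers(len(helpers2)))])
    for p in common:  # shared proteins attach to exclusive sus proteins only
        anchor_pool = sorted(c1_excl) if rng.random() < 0.5 else sorted(c2_excl)
        add_edge(p, anchor_pool[int(rng.integers(len(anchor_pool)))])

    # decoy-decoy background
    if plan.model == "erdos_renyi":
        n_d = len(decoys)
        for i in range(n_d):
            draws = rng.random(n_d - i - 1)
            for j_off in np.nonzero(draws < plan.background_edge_prob)[0]:
                add_edge(decoys[i], decoys[i + 1 + int(j_off)])
    elif plan.model == "preferential":
        degree = {d: 1 for d in decoys}
        for i, node in enumerate(decoys[1:], start=1):
            prev = decoys[:i]
            weights = np.array([degree[p] for p in prev], dtype=float)
            weights /= weights.sum()
            pick = prev[int(rng.choice(i, p=weights))]
            add_edge(node, pick)
            degree[node] += 1
            degree[pick] += 1
    else:
        raise ValidationError(f"unknown PPI background model {plan.model!r}")

    # --- emit files --------------------------------------------------------
    files = {key: out_dir / name for key, name in FILE_NAMES.items()}
    with open(files["cluster1"], "w", encoding="utf-8") as fh:
        fh.writelines(g + "\n" for g in cluster1)
    with open(files["cluster2"], "w", encoding="utf-8") as fh:
        fh.writelines(g + "\n" for g in cluster2)
    with open(files["background"], "w", encoding="utf-8") as fh:
        fh.writelines(g + "\n" for g in universe)
    with open(files["gmt"], "w", encoding="utf-8") as fh:
        for pid, label, _ in pathway_rows:
            fh.write(
                "\t".join(
                    [pid, f"synthetic {label} pathway {pid}",
                     *sorted(members_by_id[pid])]
                )
                + "\n"
            )
    with open(files["ppi"], "w", encoding="utf-8") as fh:
        fh.write("#interactor_a\tinteractor_b\n")
        for a, b in sorted(edges):
            fh.write(f"{a}\t{b}\n")

    truth = SyntheticTruth(
        config=config,
        out_dir=out_dir,
        cluster1=frozenset(cluster1),
        cluster2=frozenset(cluster2),
        pathway_labels=pathway_labels,
        pathway_target_counts=pathway_target_counts,
        multi_genes=multi_genes,
        candidates=candidates,
        candidate_partners=candidate_partners,
    )
    truth.to_yaml(files["truth"])
    return truth


def recount_truth(truth: SyntheticTruth) -> list[str]:
    """Independently re-read the emitted files and recount against the truth.

    Returns a list of human-readable mismatch descriptions (empty when the
    files are consistent with the stored ground truth).
    """
    mismatches: list[str] = []
    files = truth.files
    cfg = truth.config

    gs1 = read_gene_list(files["cluster1"], "cluster1")
    gs2 = read_gene_list(files["cluster2"], "cluster2")
    if len(gs1) != cfg.n_genes_1:
        mismatches.append(
            f"cluster1 size {len(gs1)} != configured {cfg.n_genes_1}"
        )
    if len(gs2) != cfg.n_genes_2:
        mismatches.append(
            f"cluster2 size {len(gs2)} != configured {cfg.n_genes_2}"
        )
    overlap = len(gs1.members & gs2.members)
    if overlap != cfg.n_common:
        mismatches.append(f"overlap {overlap} != configured {cfg.n_common}")
    if gs1.members != truth.cluster1:
        mismatches.append("cluster1 members differ from stored truth")
    if gs2.members != truth.cluster2:
        mismatches.append("cluster2 members differ from stored truth")

    collection = read_gmt(files["gmt"], source_db="synthetic")
    by_id = {p.pathway_id: p for p in collection}
    set1, set2 = set(truth.cluster1), set(truth.cluster2)
    for pid, label in truth.pathway_labels.items():
        if pid not in by_id:
            mismatches.append(f"pathway {pid} missing from GMT")
            continue
        members = by_id[pid].members
        if label == "cluster1":
            got = len(members & set1)
        elif label == "cluster2":
            got = len(members & set2)
        elif label == "both":
            got = len(members & (set1 | set2))
        else:
            got = 0
        want = truth.pathway_target_counts[pid]
        if got != want:
            mismatches.append(
                f"pathway {pid}: {got} target-cluster members, expected {want}"
            )
    enriched_ids = [
        pid for pid, label in truth.pathway_labels.items() if label != "null"
    ]
    for gene, k in truth.multi_genes.items():
        got = sum(1 for pid in enriched_ids if gene in by_id[pid].members)
        if got != k:
            mismatches.append(
                f"multi-pathway gene {gene} in {got} enriched pathways, "
                f"expected {k}"
            )

    network = read_ppi_table(files["ppi"], 0, 1)
    for name, (d1, d2) in truth.candidates.items():
        if name not in network.nodes:
            mismatches.append(f"planted candidate {name} missing from PPI")
            continue
        nbrs = set(network.graph.neighbors(name))
        got1 = len(nbrs & (set1 - set2))
        got2 = len(nbrs & (set2 - set1))
        if (got1, got2) != (d1, d2):
            mismatches.append(
                f"candidate {name}: wiring ({got1},{got2}), "
                f"expected ({d1},{d2})"
            )
    return mismatches


def verify_truth(truth: SyntheticTruth) -> None:
    """Assert-style wrapper around :func:`recount_truth`."""
    mismatches = recount_truth(truth)
    if mismatches:
        raise AssertionError(
            "synthetic truth mismatch: " + "; ".join(mismatches)
        )
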