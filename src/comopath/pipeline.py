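"""End-to-end orchestration: gene sources → enrichment → crosstalk → PPI inference.

One :class:`PipelineConfig` drives the whole run; every stage's headline
counts land in a :class:`PipelineReport` that is also written to disk as TSV
and human-readable text. Stage failures propagate as
:class:`~comopath.errors.PipelineStageError` carrying the stage name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .crosstalk import build_crosstalk_graph, shared_gene_report
from .enrichment import enrich_two_cluster
from .errors import PipelineStageError, ValidationError
from .formats_io import (
    PPI_DIALECTS,
    PathwayCollection,
    read_gene_list,
    read_gmt,
    read_ppi_table,
    write_enrichment_table,
    write_network,
)
from .ppi import (
    annotate_network,
    detect_hubs,
    extract_subnetwork,
    infer_candidates,
    partner_census,
)
from .simulate import SyntheticConfig, generate

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for one pipeline run.

    Either ``simulation`` is set (the synthetic generator produces the
    inputs) or the explicit file paths are. Thresholds: ``alpha`` (BH
    significance), ``tau`` (cluster-specificity fraction), ``theta`` (kappa
    connectivity), ``min_each`` (dual-candidate rule), ``hub_threshold``.
    """

    out_dir: Path
    simulation: SyntheticConfig | None = None
    cluster1_path: Path | None = None
    cluster2_path: Path | None = None
    gmt_paths: list[Path] = field(default_factory=list)
    background_path: Path | None = None
    ppi_path: Path | None = None
    ppi_dialect: str = "edgelist"
    alpha: float = 0.05
    tau: float = 0.66
    theta: float = 0.4
    min_each: int = 1
    hub_threshold: int = 5
    verbosity: int = 0

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.simulation is None:
            needed = [
                self.cluster1_path,
                self.cluster2_path,
                self.ppi_path,
            ]
            if any(p is None for p in needed) or not self.gmt_paths:
                raise ValidationError(
                    "either a simulation config or all input paths "
                    "(cluster1, cluster2, gmt, ppi) must be given"
                )
        if self.ppi_dialect not in PPI_DIALECTS:
            raise ValidationError(
                f"unknown PPI dialect {self.ppi_dialect!r}; "
                f"choose from {sorted(PPI_DIALECTS)}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        base = path.parent

        def _p(key):
            return (base / data[key]) if key in data and data[key] else None

        sim = data.get("simulation")
        return cls(
            out_dir=base / data.get("out_dir", "comopath_out"),
            simulation=SyntheticConfig.from_dict(sim) if sim else None,
            cluster1_path=_p("cluster1"),
            cluster2_path=_p("cluster2"),
            gmt_paths=[base / g for g in data.get("gmt", [])],
            background_path=_p("background"),
            ppi_path=_p("ppi"),
            ppi_dialect=data.get("ppi_dialect", "edgelist"),
            alpha=float(data.get("alpha", 0.05)),
            tau=float(data.get("tau", 0.66)),
            theta=float(data.get("theta", 0.4)),
            min_each=int(data.get("min_each", 1)),
            hub_threshold=int(data.get("hub_threshold", 5)),
            verbosity=int(data.get("verbosity", 0)),
        )


@dataclass
class PipelineReport:
    """Stage-by-stage counts and the thresholds that produced them."""

    counts: dict[str, int]
    thresholds: dict[str, float]
    artifacts: dict[str, Path]

    def to_text(self) -> str:
        lines = ["comopath pipeline report", "=" * 24, "", "thresholds:"]
        for key, val in self.thresholds.items():
            lines.append(f"  {key} = {val}")
        lines.append("")
        lines.append("stage counts:")
        for key, val in self.counts.items():
            lines.append(f"  {key}\t{val}")
        return "\n".join(lines) + "\n"

    def write(self, out_dir: Path) -> None:
        with open(out_dir / "report.tsv", "w", encoding="utf-8") as fh:
            fh.write("quantity\tvalue\n")
            for key, val in self.thresholds.items():
                fh.write(f"threshold:{key}\t{val}\n")
            for key, val in self.counts.items():
                fh.write(f"{key}\t{val}\n")
        with open(out_dir / "report.txt", "w", encoding="utf-8") as fh:
            fh.write(self.to_text())


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage name attached
                raise PipelineStageError(name, exc) from exc

        return wrapper

    return deco


@_stage("gene_sources")
def _load_gene_sources(config: PipelineConfig):
    if config.simulation is not None:
        sim_dir = config.out_dir / "synthetic"
        truth = generate(config.simulation, sim_dir)
        files = truth.files
        config.cluster1_path = files["cluster1"]
        config.cluster2_path = files["cluster2"]
        config.gmt_paths = [files["gmt"]]
        config.background_path = files["background"]
        config.ppi_path = files["ppi"]
        config.ppi_dialect = "edgelist"
    gs1 = read_gene_list(config.cluster1_path, "cluster1")
    gs2 = read_gene_list(config.cluster2_path, "cluster2")
    return gs1, gs2


@_stage("pathway_enrichment")
def _run_enrichment(config: PipelineConfig, gs1, gs2):
    collection: PathwayCollection | None = None
    for path in config.gmt_paths:
        part = read_gmt(path)
        collection = part if collection is None else collection.merged_with(part)
    if config.background_path is not None:
        background = read_gene_list(config.background_path, "background")
        collection = PathwayCollection(
            pathways=collection.pathways, universe=background.members
        )
    result = enrich_two_cluster(
        gs1, gs2, collection, alpha=config.alpha, tau=config.tau
    )
    write_enrichment_table(result, config.out_dir / "enrichment.tsv")
    return result


@_stage("network_construction")
def _run_crosstalk(config: PipelineConfig, result, gs1, gs2):
    graph = build_crosstalk_graph(result, gs1, gs2, theta=config.theta)
    write_network(graph, config.out_dir / "crosstalk.graphml", "graphml")
    write_network(graph, config.out_dir / "crosstalk.sif", "sif")
    report = shared_gene_report(graph)
    report.to_csv(config.out_dir / "shared_genes.tsv", sep="\t", index=False)
    return graph, report


@_stage("candidate_prediction")
def _run_ppi(config: PipelineConfig, gs1, gs2):
    col_a, col_b = PPI_DIALECTS[config.ppi_dialect]
    ppi = read_ppi_table(config.ppi_path, col_a, col_b)
    net = annotate_network(ppi, gs1, gs2)
    census = partner_census(net)
    candidates = infer_candidates(net, min_each=config.min_each)
    hubs = detect_hubs(candidates, h=config.hub_threshold)
    hub_names = {r.protein for r in hubs}
    with open(config.out_dir / "candidates.tsv", "w", encoding="utf-8") as fh:
        fh.write("protein\tdeg1\tdeg2\tis_hub\n")
        for rec in candidates:
            fh.write(
                f"{rec.protein}\t{rec.deg1}\t{rec.deg2}"
                f"\t{str(rec.protein in hub_names).lower()}\n"
            )
    sub = None
    if candidates:
        sub = extract_subnetwork(net, candidates)
        write_network(sub, config.out_dir / "subnetwork.graphml", "graphml")
        write_network(sub, config.out_dir / "subnetwork.sif", "sif")
    return ppi, net, census, candidates, hubs, sub


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run all stages in flow-chart order and write every artifact.

    Deterministic given the config (including any simulation seed): rerunning
    with the same config reproduces the same report and files.
    """
    config.out_dir.mkdir(parents=True, exist_ok=True)

    gs1, gs2 = _load_gene_sources(config)
    overlap = len(gs1.members & gs2.members)
    counts: dict[str, int] = {
        "genes_cluster1": len(gs1),
        "genes_cluster2": len(gs2),
        "genes_common": overlap,
        "genes_union": len(gs1.members | gs2.members),
    }

    result = _run_enrichment(config, gs1, gs2)
    labels = result.label_counts()
    counts.update(
        {
            "pathways_tested": result.n_tested,
            "pathways_significant": len(result),
            "pathways_cluster1": labels["cluster1"],
            "pathways_cluster2": labels["cluster2"],
            "pathways_both": labels["both"],
        }
    )

    if len(result):
        graph, shared = _run_crosstalk(config, result, gs1, gs2)
        counts.update(
            {
                "crosstalk_kappa_edges": len(graph.kappa_edges),
                "crosstalk_gene_nodes": len(graph.gene_nodes),
                "crosstalk_membership_edges": len(graph.membership_edges),
            }
        )
    else:
        logger.warning("no significant pathways; crosstalk stage skipped")
        counts.update(
            {
                "crosstalk_kappa_edges": 0,
                "crosstalk_gene_nodes": 0,
                "crosstalk_membership_edges": 0,
            }
        )

    ppi, net, census, candidates, hubs, sub = _run_ppi(config, gs1, gs2)
    class_counts = net.class_counts()
    counts.update(
        {
            "ppi_nodes": ppi.n_nodes,
            "ppi_edges": ppi.n_edges,
            "network_nodes": net.n_nodes,
            "network_edges": net.n_edges,
            "network_sus1": class_counts["sus1"],
            "network_sus2": class_counts["sus2"],
            "network_sus_both": class_counts["sus_both"],
            "network_neighbors": class_counts["neighbor"],
            "neighbors_ge1_disease1": census.aggregates["deg1_ge_1"],
            "neighbors_ge1_disease2": census.aggregates["deg2_ge_1"],
            "neighbors_ge2_disease1": census.aggregates["deg1_ge_2"],
            "neighbors_ge2_disease2": census.aggregates["deg2_ge_2"],
            "candidates": len(candidates),
            "hubs": len(hubs),
            "subnetwork_nodes": sub.n_nodes if sub else 0,
            "subnetwork_edges": sub.n_edges if sub else 0,
        }
    )

    report = PipelineReport(
        counts=counts,
        thresholds={
            "alpha": config.alpha,
            "tau": config.tau,
            "theta": config.theta,
            "min_each": config.min_each,
            "hub_threshold": config.hub_threshold,
        },
        artifacts={
            "enrichment": config.out_dir / "enrichment.tsv",
            "crosstalk_graphml": config.out_dir / "crosstalk.graphml",
            "crosstalk_sif": config.out_dir / "crosstalk.sif",
            "shared_genes": config.out_dir / "shared_genes.tsv",
            "candidates": config.out_dir / "candidates.tsv",
            "subnetwork_graphml": config.out_dir / "subnetwork.graphml",
            "subnetwork_sif": config.out_dir / "subnetwork.sif",
            "report_tsv": config.out_dir / "report.tsv",
            "report_txt": config.out_dir / "report.txt",
        },
    )
    report.write(config.out_dir)
    return report
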