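"""End-to-end orchestration: DE -> enrichment -> networks -> screen.

`screen_candidates` is the pure in-memory composition; `run_pipeline` wraps
it with file I/O, a run manifest and structured per-stage logging so a run
is auditable (genes in, genes called, edges kept, candidates out).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

try:
    from importlib.metadata import version as _dist_version

    _pkg_version = _dist_version("coexscreen")
except Exception:  # pragma: no cover - metadata missing in odd installs
    _pkg_version = "unknown"

from coexscreen.diffexpr import (
    DEFAULT_FDR_MAX,
    DEFAULT_MIN_ABS_LOG2FC,
    DEGTable,
    make_deg_table,
    read_deg_table,
    write_deg_table,
)
from coexscreen.enrichment import (
    DEFAULT_N_LNC,
    DEFAULT_P_MAX,
    EnrichmentRecord,
    enrichment_frame,
    fisher_enrichment,
    select_network_genes,
)
from coexscreen.io import (
    CASE,
    CONTROL,
    ExpressionMatrix,
    GeneSetCollection,
    SampleDesign,
    read_design,
    read_expression_matrix,
    read_gmt,
    write_gene_list,
    write_group_network,
    write_table,
)
from coexscreen.network import DEFAULT_EDGE_FDR, GroupNetwork, build_group_network
from coexscreen.topology import (
    DEFAULT_TOP_K,
    CandidateSelection,
    TopologyRecord,
    differential_topology,
    rank_top,
    select_candidates,
    topology_frame,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and the anchor gene for one pipeline run.

    Threshold defaults mirror the reference screen: DEG call at FDR < 0.05
    and |log2FC| > 1, enrichment gate at raw Fisher P < 0.01, network edges
    at correlation FDR < 0.01, 30 lncRNAs, top-20 ranking.
    """

    matrix: str
    design: str
    out_dir: str
    anchor: str
    go_gmt: str | None = None
    pathway_gmt: str | None = None
    biotype: str | None = None
    deg_table: str | None = None
    network_genes: str | None = None
    deg_fdr_max: float = DEFAULT_FDR_MAX
    deg_min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC
    enrich_p_max: float = DEFAULT_P_MAX
    edge_fdr_max: float = DEFAULT_EDGE_FDR
    n_lnc: int = DEFAULT_N_LNC
    top_k: int = DEFAULT_TOP_K
    log2fc_mode: str = "diff_of_logmeans"
    seed: int = 0

    def validate(self) -> None:
        for name in ("deg_fdr_max", "enrich_p_max", "edge_fdr_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.deg_min_abs_log2fc < 0:
            raise ValueError("deg_min_abs_log2fc must be nonnegative")
        if self.n_lnc < 0:
            raise ValueError("n_lnc must be nonnegative")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not self.anchor:
            raise ValueError("anchor gene id must be set")
        if self.network_genes is None and self.go_gmt is None:
            raise ValueError("provide go_gmt/pathway_gmt or an explicit network_genes list")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ScreenResult:
    """In-memory outputs of every stage."""

    deg_table: DEGTable
    go_records: list[EnrichmentRecord]
    pathway_records: list[EnrichmentRecord]
    network_genes: list[str]
    case_network: GroupNetwork
    control_network: GroupNetwork
    topology: list[TopologyRecord]
    top_ranked: list[TopologyRecord]
    selection: CandidateSelection
    stage_counts: dict = field(default_factory=dict)


def screen_candidates(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    anchor: str,
    go_sets: GeneSetCollection | None = None,
    pathway_sets: GeneSetCollection | None = None,
    deg_table: DEGTable | None = None,
    network_genes: Sequence[str] | None = None,
    deg_fdr_max: float = DEFAULT_FDR_MAX,
    deg_min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC,
    enrich_p_max: float = DEFAULT_P_MAX,
    edge_fdr_max: float = DEFAULT_EDGE_FDR,
    n_lnc: int = DEFAULT_N_LNC,
    top_k: int = DEFAULT_TOP_K,
    log2fc_mode: str = "diff_of_logmeans",
) -> ScreenResult:
    """Run every stage in memory and return all intermediate results.

    ``network_genes`` bypasses the enrichment-based gene selection;
    ``deg_table`` bypasses the built-in DE stage.
    """
    design.validate_against(matrix)

    if deg_table is None:
        deg_table = make_deg_table(
            matrix, design, mode=log2fc_mode, fdr_max=deg_fdr_max, min_abs_log2fc=deg_min_abs_log2fc
        )
    called = deg_table.called_ids()
    logger.info("DE stage: %d genes in, %d called", len(deg_table), len(called))

    go_records: list[EnrichmentRecord] = []
    pathway_records: list[EnrichmentRecord] = []
    if network_genes is None:
        if go_sets is None or pathway_sets is None:
            raise ValueError("network gene selection needs both GO and pathway gene sets")
        universe = list(matrix.gene_ids)
        go_records = fisher_enrichment(called, universe, go_sets)
        pathway_records = fisher_enrichment(called, universe, pathway_sets)
        network_genes = select_network_genes(
            go_records, pathway_records, deg_table, matrix, p_max=enrich_p_max, n_lnc=n_lnc
        )
    else:
        network_genes = list(network_genes)
    logger.info("gene selection: %d network genes", len(network_genes))
    if len(network_genes) < 2:
        raise ValueError(
            f"only {len(network_genes)} network genes selected; need >= 2 to build networks"
        )
    if anchor not in network_genes:
        raise ValueError(f"anchor gene {anchor!r} is not among the selected network genes")

    control_network = build_group_network(
        matrix, design, design.control_label, network_genes, fdr_max=edge_fdr_max
    )
    case_network = build_group_network(
        matrix, design, design.case_label, network_genes, fdr_max=edge_fdr_max
    )
    logger.info(
        "networks: control %d edges, case %d edges",
        control_network.n_edges,
        case_network.n_edges,
    )

    topology = differential_topology(case_network, control_network, network_genes)
    top_ranked = rank_top(topology, k=top_k)
    selection = select_candidates(topology, anchor)
    logger.info("screen: %d candidates relative to %s", len(selection.candidates), anchor)

    return ScreenResult(
        deg_table=deg_table,
        go_records=go_records,
        pathway_records=pathway_records,
        network_genes=network_genes,
        case_network=case_network,
        control_network=control_network,
        topology=topology,
        top_ranked=top_ranked,
        selection=selection,
        stage_counts={
            "genes_in": len(deg_table),
            "degs_called": len(called),
            "network_genes": len(network_genes),
            "edges_control": control_network.n_edges,
            "edges_case": case_network.n_edges,
            "candidates": len(selection.candidates),
        },
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured run, writing every stage output plus a manifest.

    Returns the manifest dict.  Any stage error aborts the run; partial
    outputs in ``out_dir`` are flagged in a ``FAILED`` marker file rather
    than silently reused.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"

    try:
        matrix = read_expression_matrix(config.matrix, biotype_path=config.biotype)
        design = read_design(config.design)
        go_sets = read_gmt(config.go_gmt, namespace="GO") if config.go_gmt else None
        pathway_sets = (
            read_gmt(config.pathway_gmt, namespace="pathway") if config.pathway_gmt else None
        )
        deg_table = read_deg_table(config.deg_table) if config.deg_table else None
        network_genes = None
        if config.network_genes:
            from coexscreen.io import read_gene_list

            network_genes = read_gene_list(config.network_genes)

        result = screen_candidates(
            matrix,
            design,
            anchor=config.anchor,
            go_sets=go_sets,
            pathway_sets=pathway_sets,
            deg_table=deg_table,
            network_genes=network_genes,
            deg_fdr_max=config.deg_fdr_max,
            deg_min_abs_log2fc=config.deg_min_abs_log2fc,
            enrich_p_max=config.enrich_p_max,
            edge_fdr_max=config.edge_fdr_max,
            n_lnc=config.n_lnc,
            top_k=config.top_k,
            log2fc_mode=config.log2fc_mode,
        )

        write_deg_table(result.deg_table, out / "deg.tsv")
        if result.go_records:
            write_table(enrichment_frame(result.go_records), out / "enrichment_go.tsv")
        if result.pathway_records:
            write_table(enrichment_frame(result.pathway_records), out / "enrichment_pathway.tsv")
        write_gene_list(result.network_genes, out / "network_genes.txt")
        for net, name in (
            (result.control_network, "network_control"),
            (result.case_network, "network_case"),
        ):
            write_group_network(net, out / f"{name}.tsv", format="edge_tsv")
            write_group_network(net, out / f"{name}.graphml", format="graphml")
        write_table(topology_frame(result.topology), out / "topology.tsv")
        write_table(topology_frame(result.top_ranked), out / "top_ranked.tsv")
        with open(out / "candidates.tsv", "w") as fh:
            fh.write("gene_id\n")
            for g in result.selection.candidates:
                fh.write(f"{g}\n")

        import networkx
        import numpy
        import pandas
        import scipy

        manifest = {
            "config": asdict(config),
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "versions": {
                "coexscreen": _pkg_version,
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "pandas": pandas.__version__,
                "networkx": networkx.__version__,
            },
            "stage_counts": result.stage_counts,
            "anchor": {
                "gene": result.selection.anchor_gene,
                "dif_degree": result.selection.anchor_dif_degree,
                "dif_kcore": result.selection.anchor_dif_kcore,
            },
            "candidates": result.selection.candidates,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        if failed_marker.exists():
            failed_marker.unlink()
        return manifest
    except Exception as exc:
        failed_marker.write_text(f"pipeline run failed: {exc}\n")
        raise
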