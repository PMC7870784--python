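"""End-to-end orchestration: risk genes -> risk pathways -> crosstalk ->
consensus miRNA targets -> miRNA-pathway pairs -> miRSNP-annotated network ->
axes.  Each stage is importable on its own; this module just chains them with
one consistent universe and significance threshold."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .axes import Axis, extract_axes
from .crosstalk import CrosstalkEdge, crosstalk_network
from .enrichment import EnrichmentResult, coverage_fraction, enrich
from .io import MiRSNPTable, PathwayCollection, PredictionTable, RiskGeneList
from .mirna import (
    ConsensusTargetMap,
    MirnaPathwayPair,
    build_consensus,
    mirna_pathway_enrichment,
)
from .mirsnp import filter_mirsnps, records_from_table, split_by_class
from .pmsn import PMSNGraph, TopologySummary, build_pmsn, hub_report, topology

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineResult:
    enrichment: list  # EnrichmentResult, all tested pathways with x >= 1
    risk_pathways: PathwayCollection  # the significant subset
    coverage: float
    crosstalk: list  # CrosstalkEdge among the significant pathways
    consensus: ConsensusTargetMap
    pairs: list  # retained MirnaPathwayPair
    target_site_snps: list
    mirna_gene_snps: list
    pmsn: PMSNGraph
    topology: TopologySummary | None
    hubs: dict | None
    axes: list  # Axis


def run_pipeline(
    risk_genes: RiskGeneList,
    pathways: PathwayCollection,
    predictions: PredictionTable,
    mirsnps: MiRSNPTable,
    *,
    universe: Iterable[str] | None = None,
    m: int | None = None,
    alpha: float = 0.01,
    k: int = 4,
    min_dbs: int = 2,
    tail: str = "upper",
    hub_degree_gt: int = 3,
    crosstalk_scope: str = "risk-only",
) -> PipelineResult:
    """Run every stage with shared (universe, alpha) settings.

    ``crosstalk_scope`` is "risk-only" (pairs among the significant risk
    pathways, the default) or "vs-all" (every pathway pair in the collection,
    keeping only edges touching a risk pathway).
    """
    results = enrich(risk_genes, pathways, universe=universe, m=m, alpha=alpha, tail=tail)
    significant_ids = [r.pathway_id for r in results if r.significant]
    cov = coverage_fraction(results, risk_genes)
    risk_pathways = pathways.subset(significant_ids)

    if len(significant_ids) >= 2:
        if crosstalk_scope == "risk-only":
            edges = crosstalk_network(risk_pathways, universe=universe, m=m, alpha=alpha)
        elif crosstalk_scope == "vs-all":
            all_edges = crosstalk_network(pathways, universe=universe, m=m, alpha=alpha)
            keep = set(significant_ids)
            edges = [e for e in all_edges if e.a in keep or e.b in keep]
        else:
            raise ValueError(f"unknown crosstalk_scope {crosstalk_scope!r}")
    else:
        edges = []

    consensus = build_consensus(predictions, k=k)
    pairs = (
        mirna_pathway_enrichment(consensus, risk_pathways, universe=universe, m=m, alpha=alpha)
        if significant_ids
        else []
    )

    records = records_from_table(mirsnps)
    kept = filter_mirsnps(records, min_dbs=min_dbs)
    target_site, mirna_gene = split_by_class(kept)

    pmsn = build_pmsn(pairs, target_site, mirna_gene, pathways)
    topo = topology(pmsn) if pmsn.graph.number_of_nodes() else None
    hubs = hub_report(topo, mirna_degree_gt=hub_degree_gt) if topo else None

    axis_list = extract_axes(target_site, consensus, risk_genes, pairs, pathways)
    return PipelineResult(
        enrichment=results,
        risk_pathways=risk_pathways,
        coverage=cov,
        crosstalk=edges,
        consensus=consensus,
        pairs=pairs,
        target_site_snps=target_site,
        mirna_gene_snps=mirna_gene,
        pmsn=pmsn,
        topology=topo,
        hubs=hubs,
        axes=axis_list,
    )
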