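"""The pathway-based miRSNP switching network (PMSN) and its topology.

The PMSN is an undirected bipartite graph: miRNA nodes on one side, risk
pathways on the other, with an edge for every retained miRNA-pathway
enrichment pair.  Target-site miRSNPs annotate edges (the SNP sits in a
binding site of a gene belonging to that edge's pathway); miRNA-gene miRSNPs
annotate miRNA nodes.  Topology analysis reports exact degrees, normalized
betweenness centrality, and a power-law fit of the degree histogram by
least squares on log-log axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import MIRNA_GENE, TARGET_SITE, PathwayCollection
from .mirna import MirnaPathwayPair
from .mirsnp import MiRSNPRecord

__all__ = [
    "PMSNGraph",
    "TopologySummary",
    "build_pmsn",
    "topology",
    "fit_power_law",
    "hub_report",
]


@dataclass(frozen=True)
class PMSNGraph:
    """Bipartite miRNA-pathway graph with miRSNP annotations.

    Node attribute ``kind`` is "mirna" or "pathway"; miRNA nodes carry a
    ``snps`` tuple of annotating rsIDs; edges carry ``p_adj`` and a ``snps``
    tuple of (rsID, gene) annotations.  ``unattached`` lists filtered miRSNP
    records that could not be placed on any node or edge (reported, never
    silently dropped).
    """

    graph: nx.Graph
    unattached: tuple = ()

    @property
    def mirna_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "mirna")

    @property
    def pathway_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "pathway")

    def assert_bipartite(self) -> None:
        for u, v in self.graph.edges():
            ku, kv = self.graph.nodes[u]["kind"], self.graph.nodes[v]["kind"]
            if {ku, kv} != {"mirna", "pathway"}:
                raise AssertionError(f"non-bipartite edge ({u}, {v}): kinds ({ku}, {kv})")


def build_pmsn(
    pairs: Sequence[MirnaPathwayPair],
    target_site_snps: Iterable[MiRSNPRecord],
    mirna_gene_snps: Iterable[MiRSNPRecord],
    pathways: PathwayCollection,
) -> PMSNGraph:
    """Assemble the PMSN from retained pairs and filtered miRSNP records.

    A target-site SNP (rs, miRNA, gene) annotates edge (miRNA, P) iff that
    edge exists and the gene belongs to P; a miRNA-gene SNP annotates its
    miRNA's node iff the node exists.  Records attaching nowhere are returned
    in ``unattached``.
    """
    g = nx.Graph()
    for pair in pairs:
        if pair.pathway not in pathways.entries:
            raise KeyError(f"pair references unknown pathway id {pair.pathway!r}")
        g.add_node(pair.mirna, kind="mirna", snps=())
        g.add_node(pair.pathway, kind="pathway")
        g.add_edge(pair.mirna, pair.pathway, p_adj=pair.p_adj, x=pair.x, snps=())

    unattached: list[MiRSNPRecord] = []
    for snp in sorted(target_site_snps, key=MiRSNPRecord.sort_key):
        if snp.snp_class != TARGET_SITE:
            raise ValueError(f"{snp.rsid}: expected a {TARGET_SITE} record")
        placed = False
        if g.has_node(snp.mirna):
            for pathway in g.neighbors(snp.mirna):
                if snp.gene in pathways.genes(pathway):
                    data = g.edges[snp.mirna, pathway]
                    data["snps"] = tuple(sorted(set(data["snps"]) | {(snp.rsid, snp.gene)}))
                    placed = True
        if not placed:
            unattached.append(snp)

    for snp in sorted(mirna_gene_snps, key=MiRSNPRecord.sort_key):
        if snp.snp_class != MIRNA_GENE:
            raise ValueError(f"{snp.rsid}: expected a {MIRNA_GENE} record")
        if g.has_node(snp.mirna):
            node = g.nodes[snp.mirna]
            node["snps"] = tuple(sorted(set(node["snps"]) | {snp.rsid}))
        else:
            unattached.append(snp)

    pmsn = PMSNGraph(graph=g, unattached=tuple(unattached))
    pmsn.assert_bipartite()
    return pmsn


@dataclass(frozen=True)
class TopologySummary:
    degrees: Mapping[str, int]
    kinds: Mapping[str, str]
    betweenness: Mapping[str, float]
    degree_histogram: Mapping[int, int]  # over all nodes, zero bins omitted
    degree_histogram_by_class: Mapping[str, Mapping[int, int]]
    powerlaw_exponent: float
    powerlaw_r2: float

    def degree_table(self) -> pd.DataFrame:
        rows = sorted(
            ((n, self.kinds[n], d, self.betweenness[n]) for n, d in self.degrees.items()),
            key=lambda r: (-r[2], r[0]),
        )
        return pd.DataFrame(rows, columns=["node", "kind", "degree", "betweenness"])


def fit_power_law(histogram: Mapping[int, int]) -> tuple[float, float]:
    """Least-squares line on log10(degree) vs log10(frequency).

    Returns (exponent, R^2) where the fitted frequency is proportional to
    degree^(-exponent).  Zero-count and zero-degree bins are excluded; with
    fewer than two usable bins the fit is undefined and (nan, nan) returned.
    """
    pts = [(d, f) for d, f in histogram.items() if d > 0 and f > 0]
    if len(pts) < 2:
        return float("nan"), float("nan")
    lx = np.log10([d for d, _ in pts])
    ly = np.log10([f for _, f in pts])
    slope, intercept = np.polyfit(lx, ly, 1)
    fitted = slope * lx + intercept
    ss_res = float(np.sum((ly - fitted) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(-slope), r2


def topology(pmsn: PMSNGraph) -> TopologySummary:
    """Degrees, normalized betweenness, degree histograms and power-law fit."""
    g = pmsn.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    degrees = {n: int(d) for n, d in g.degree()}
    kinds = {n: g.nodes[n]["kind"] for n in g.nodes}
    if g.number_of_nodes() <= 2:
        betweenness = {n: 0.0 for n in g.nodes}
    else:
        betweenness = {n: float(b) for n, b in nx.betweenness_centrality(g, normalized=True).items()}

    hist: dict[int, int] = {}
    for d in degrees.values():
        hist[d] = hist.get(d, 0) + 1
    by_class: dict[str, dict[int, int]] = {"mirna": {}, "pathway": {}}
    for n, d in degrees.items():
        cls = by_class.setdefault(kinds[n], {})
        cls[d] = cls.get(d, 0) + 1
    exponent, r2 = fit_power_law(hist)
    return TopologySummary(
        degrees=degrees,
        kinds=kinds,
        betweenness=betweenness,
        degree_histogram=dict(sorted(hist.items())),
        degree_histogram_by_class={k: dict(sorted(v.items())) for k, v in by_class.items()},
        powerlaw_exponent=exponent,
        powerlaw_r2=r2,
    )


def hub_report(summary: TopologySummary, mirna_degree_gt: int = 3) -> dict:
    """Hub miRNAs (degree strictly above the threshold) and pathway rankings.

    Returns ``{"mirnas": DataFrame, "pathways": DataFrame}`` with
    deterministic ordering (degree descending, then betweenness descending,
    ties by node id).
    """
    mirna_rows = sorted(
        (
            (n, d, summary.betweenness[n])
            for n, d in summary.degrees.items()
            if summary.kinds[n] == "mirna" and d > mirna_degree_gt
        ),
        key=lambda r: (-r[1], -r[2], r[0]),
    )
    pathway_rows = sorted(
        (
            (n, d, summary.betweenness[n])
            for n, d in summary.degrees.items()
            if summary.kinds[n] == "pathway"
        ),
        key=lambda r: (-r[1], -r[2], r[0]),
    )
    cols = ["node", "degree", "betweenness"]
    return {
        "mirnas": pd.DataFrame(mirna_rows, columns=cols),
        "pathways": pd.DataFrame(pathway_rows, columns=cols),
    }
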