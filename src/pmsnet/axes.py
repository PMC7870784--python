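"""Enumeration of miRSNP -> miRNA -> risk gene -> pathway axes.

An axis is the package's end product: one polymorphism (rsID) in the binding
site of one risk gene, the set of miRNAs sharing that binding site (miRNA
family membership emerges from sharing the SNP-gene site, not from an
annotation file), and the risk pathways that both contain the gene and are
significantly targeted by at least one of those miRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io import TARGET_SITE, PathwayCollection, RiskGeneList
from .mirna import ConsensusTargetMap, MirnaPathwayPair
from .mirsnp import MiRSNPRecord

__all__ = ["Axis", "extract_axes", "axis_report"]


@dataclass(frozen=True)
class Axis:
    rsid: str
    mirnas: tuple  # sorted; all share the (rsid, gene) binding site
    gene: str
    pathways: tuple  # sorted; each contains gene and has a retained pair with >=1 axis miRNA
    n_validated: int  # records of this site with experimental validation

    def __post_init__(self):
        if not self.mirnas:
            raise ValueError("axis without miRNAs")
        if not self.pathways:
            raise ValueError("axis without pathways")


def extract_axes(
    target_site_snps: Iterable[MiRSNPRecord],
    consensus: ConsensusTargetMap,
    risk_genes: RiskGeneList,
    pairs: Sequence[MirnaPathwayPair],
    pathways: PathwayCollection,
) -> list[Axis]:
    """Enumerate axes from post-filter outputs.

    Retained target-site SNPs are grouped by (rsID, gene); a group survives if
    its gene is a risk gene, keeping only miRNAs for which the gene is a
    consensus target (a SNP row unbacked by consensus targeting is evidence of
    nothing); each surviving group is paired with every pathway that contains
    the gene and has a retained enrichment pair with at least one of the
    group's miRNAs.  Groups with no qualifying miRNA or pathway yield no axis.
    Output is ordered by (rsID, gene); an empty result is valid.
    """
    risk = risk_genes.as_set()
    pair_index: dict[str, set] = {}
    for p in pairs:
        pair_index.setdefault(p.mirna, set()).add(p.pathway)

    groups: dict[tuple, dict] = {}
    for snp in target_site_snps:
        if snp.snp_class != TARGET_SITE:
            raise ValueError(f"{snp.rsid}: expected a {TARGET_SITE} record")
        key = (snp.rsid, snp.gene)
        entry = groups.setdefault(key, {"mirnas": set(), "validated": 0})
        entry["mirnas"].add(snp.mirna)
        entry["validated"] += int(snp.validated)

    axes: list[Axis] = []
    for (rsid, gene), entry in sorted(groups.items()):
        if gene not in risk:
            continue
        mirnas = sorted(
            m for m in entry["mirnas"] if gene in consensus.targets.get(m, frozenset())
        )
        if not mirnas:
            continue
        axis_pathways = sorted(
            pid
            for pid in pathways.ids()
            if gene in pathways.genes(pid)
            and any(pid in pair_index.get(m, set()) for m in mirnas)
        )
        if not axis_pathways:
            continue
        axes.append(
            Axis(
                rsid=rsid,
                mirnas=tuple(mirnas),
                gene=gene,
                pathways=tuple(axis_pathways),
                n_validated=entry["validated"],
            )
        )
    return axes


def axis_report(axes: Sequence[Axis]) -> pd.DataFrame:
    """One row per (axis, pathway) with a stable column order."""
    rows = [
        (a.rsid, ";".join(a.mirnas), a.gene, pathway, len(a.mirnas), a.n_validated)
        for a in axes
        for pathway in a.pathways
    ]
    return pd.DataFrame(
        rows, columns=["rsid", "mirnas", "gene", "pathway", "n_mirnas", "n_validated"]
    )
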