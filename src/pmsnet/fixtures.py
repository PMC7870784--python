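"""Packaged worked-example fixtures.

:func:`load_psd_enrichment_table` (re-exported from :mod:`pmsnet.io`) carries the
published KEGG enrichment table for the post-stroke-depression risk-gene
list.

:func:`igf1r_axis_fixture` builds, deterministically and without RNG, the
small input bundle behind the package's worked example: the rs28457673
polymorphism sits in the 3'-UTR binding site of IGF1R shared by five members
of the miR-15/16/195/497 seed family, IGF1R belongs to three risk pathways
(MAPK signalling hsa04010, PI3K-Akt signalling hsa04151, EGFR-TKI resistance
hsa01521), and each family member significantly targets each pathway — so
axis extraction must return exactly one axis.  The gene content of the
synthetic pathways is placeholder (labelled G-numbered symbols plus the named
risk genes); only the axis-relevant structure is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import (
    TARGET_SITE,
    MiRSNPTable,
    PathwayCollection,
    PredictionTable,
    RiskGeneList,
    collection_from_sets,
    load_psd_enrichment_table,
    mirsnps_from_frame,
    predictions_from_frame,
)

__all__ = ["load_psd_enrichment_table", "igf1r_axis_fixture", "AxisFixture"]

_FAMILY = ("hsa-mir-15a", "hsa-mir-15b", "hsa-mir-16", "hsa-mir-195", "hsa-mir-497")
_PATHWAY_NAMES = {
    "hsa04010": "MAPK signaling pathway",
    "hsa04151": "PI3K-Akt signaling pathway",
    "hsa01521": "EGFR tyrosine kinase inhibitor resistance",
    "hsa90001": "decoy pathway A",
    "hsa90002": "decoy pathway B",
}
_UNIVERSE_SIZE = 2000
_PATHWAY_SIZE = 30
_TARGETS_PER_PATHWAY = 15  # per family member, IGF1R included
_N_SOURCES = 10
_SUPPORT = 5  # tools agreeing on each family-member prediction (>= default k of 4)


@dataclass(frozen=True)
class AxisFixture:
    pathways: PathwayCollection
    risk_genes: RiskGeneList
    predictions: PredictionTable
    mirsnps: MiRSNPTable


def igf1r_axis_fixture() -> AxisFixture:
    universe = [f"G{i:04d}" for i in range(1, _UNIVERSE_SIZE + 1)]
    named = ["IGF1R", "BDNF", "NTRK2"]
    universe = named + universe

    # three risk pathways all containing IGF1R, plus two decoys without it
    sets: dict[str, list[str]] = {}
    cursor = 0
    for pid in ("hsa04010", "hsa04151", "hsa01521"):
        genes = ["IGF1R"] + [f"G{i:04d}" for i in range(cursor + 1, cursor + _PATHWAY_SIZE)]
        cursor += _PATHWAY_SIZE - 1
        sets[pid] = genes
    for pid in ("hsa90001", "hsa90002"):
        sets[pid] = [f"G{i:04d}" for i in range(cursor + 1, cursor + 1 + _PATHWAY_SIZE)]
        cursor += _PATHWAY_SIZE
    pathways = collection_from_sets(
        sets, names=_PATHWAY_NAMES, universe=universe,
        categories={pid: "Environmental information processing" for pid in sets},
    )

    risk = RiskGeneList(genes=("IGF1R", "BDNF", "NTRK2"))

    # each family member hits the first 15 genes of each risk pathway
    # (IGF1R among them), reported by 5 of the 10 tools; one decoy miRNA is
    # reported by too few tools to pass consensus
    sources = [f"tool{t:02d}" for t in range(1, _N_SOURCES + 1)]
    rows = []
    for mi, mirna in enumerate(_FAMILY):
        targets: list[str] = []
        for pid in ("hsa04010", "hsa04151", "hsa01521"):
            targets.extend(sets[pid][:_TARGETS_PER_PATHWAY])
        for gene in dict.fromkeys(targets):
            for t in range(_SUPPORT):
                rows.append((mirna, gene, sources[(mi + t) % _N_SOURCES]))
    for t in range(3):  # below the 4-of-10 consensus threshold
        rows.append(("hsa-mir-9999", "IGF1R", sources[t]))
    predictions = predictions_from_frame(
        pd.DataFrame(rows, columns=["mirna", "gene", "source"]), roster=sources
    )

    snp_rows = [
        ("rs28457673", TARGET_SITE, mirna, "IGF1R", db, mirna == "hsa-mir-497")
        for mirna in _FAMILY
        for db in ("tsdb1", "tsdb2")
    ]
    mirsnps = mirsnps_from_frame(
        pd.DataFrame(
            snp_rows, columns=["rsid", "snp_class", "mirna", "gene", "source", "validated"]
        ),
        target_site_roster=["tsdb1", "tsdb2", "tsdb3", "tsdb4"],
        mirna_gene_roster=["mgdb1", "mgdb2", "mgdb3"],
    )
    return AxisFixture(
        pathways=pathways, risk_genes=risk, predictions=predictions, mirsnps=mirsnps
    )
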