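"""miRSNP evidence filtering and classification.

A miRSNP is a polymorphism sitting either inside a miRNA target site (usually
a 3'-UTR binding site, class ``TARGET_SITE``) or inside the miRNA-producing
gene itself (class ``MIRNA_GENE``).  Evidence comes from several annotation
databases of uneven quality; a record is kept when it is experimentally
validated OR confirmed by at least ``min_dbs`` distinct databases.  A SNP
observed with several miRNAs is one record per (rsID, miRNA, gene) triple —
per-binding-site semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .io import MIRNA_GENE, TARGET_SITE, MiRSNPTable

log = logging.getLogger(__name__)

__all__ = ["MiRSNPRecord", "records_from_table", "filter_mirsnps", "split_by_class"]


@dataclass(frozen=True)
class MiRSNPRecord:
    rsid: str
    snp_class: str  # TARGET_SITE | MIRNA_GENE
    mirna: str
    gene: str | None  # None for MIRNA_GENE records
    databases: frozenset
    validated: bool

    def __post_init__(self):
        if self.snp_class not in (TARGET_SITE, MIRNA_GENE):
            raise ValueError(f"unknown class {self.snp_class!r}")
        if self.snp_class == TARGET_SITE and not self.gene:
            raise ValueError(f"{self.rsid}: target-site record without a gene")
        if not self.databases:
            raise ValueError(f"{self.rsid}: empty supporting-database set")

    def sort_key(self):
        return (self.rsid, self.snp_class, self.mirna, self.gene or "")


def records_from_table(table: MiRSNPTable) -> list[MiRSNPRecord]:
    """Aggregate per-database rows into one record per (rsID, class, miRNA, gene).

    The validated flag is ORed across a record's rows.
    """
    grouped: dict[tuple, dict] = {}
    for row in table.table.itertuples(index=False):
        key = (row.rsid, row.snp_class, row.mirna, row.gene or None)
        entry = grouped.setdefault(key, {"dbs": set(), "validated": False})
        entry["dbs"].add(row.source)
        entry["validated"] |= bool(row.validated)
    records = [
        MiRSNPRecord(
            rsid=rsid,
            snp_class=cls,
            mirna=mirna,
            gene=gene,
            databases=frozenset(v["dbs"]),
            validated=v["validated"],
        )
        for (rsid, cls, mirna, gene), v in grouped.items()
    ]
    records.sort(key=MiRSNPRecord.sort_key)
    return records


def filter_mirsnps(records: Iterable[MiRSNPRecord], min_dbs: int = 2) -> list[MiRSNPRecord]:
    """Keep records that are validated OR supported by >= min_dbs databases."""
    if min_dbs < 1:
        raise ValueError("min_dbs must be >= 1")
    kept = [r for r in records if r.validated or len(r.databases) >= min_dbs]
    kept.sort(key=MiRSNPRecord.sort_key)
    by_class = {TARGET_SITE: 0, MIRNA_GENE: 0}
    for r in kept:
        by_class[r.snp_class] += 1
    log.info(
        "retained %d/%d miRSNP records (%d target-site, %d miRNA-gene)",
        len(kept), len(list(records)) if not hasattr(records, "__len__") else len(records),
        by_class[TARGET_SITE], by_class[MIRNA_GENE],
    )
    return kept


def split_by_class(
    records: Iterable[MiRSNPRecord],
) -> tuple[list[MiRSNPRecord], list[MiRSNPRecord]]:
    """Partition records into (target-site, miRNA-gene) lists."""
    target_site = sorted(
        (r for r in records if r.snp_class == TARGET_SITE), key=MiRSNPRecord.sort_key
    )
    mirna_gene = sorted(
        (r for r in records if r.snp_class == MIRNA_GENE), key=MiRSNPRecord.sort_key
    )
    return target_site, mirna_gene
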