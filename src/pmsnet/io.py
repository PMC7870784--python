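"""Readers and writers for the formats the pipeline touches.

Gene sets travel as GMT (one set per line: id, description, genes...), flat
tables as TSV, networks as GraphML or an edge-list TSV.  Readers validate and
reject malformed input rather than repairing it silently; every writer/reader
pair is a content identity on canonical form (uppercased gene symbols,
lowercased miRNA names, sorted serialization).

The GMT description field optionally carries a category label after a ``|``
separator (``name|category``), since gene-set collections in this package are
category-labelled (e.g. KEGG top-level classes).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

TARGET_SITE = "TARGET_SITE"
MIRNA_GENE = "MIRNA_GENE"

_RSID_RE = re.compile(r"^rs\d+$")


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# gene sets


@dataclass(frozen=True)
class Pathway:
    id: str
    name: str
    category: str
    genes: frozenset

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"pathway {self.id}: empty gene set")


@dataclass(frozen=True)
class PathwayCollection:
    """Named gene sets with category labels; the reference sets of every test."""

    entries: Mapping[str, Pathway]
    universe_hint: frozenset | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())

    def ids(self) -> list[str]:
        return sorted(self.entries)

    def genes(self, pathway_id: str) -> frozenset:
        return self.entries[pathway_id].genes

    def universe(self) -> frozenset:
        if self.universe_hint is not None:
            return self.universe_hint
        out: set = set()
        for p in self.entries.values():
            out |= p.genes
        return frozenset(out)

    def subset(self, ids: Iterable[str]) -> "PathwayCollection":
        ids = list(ids)
        missing = [i for i in ids if i not in self.entries]
        if missing:
            raise KeyError(f"unknown pathway ids: {missing}")
        return PathwayCollection(
            entries={i: self.entries[i] for i in ids},
            universe_hint=self.universe_hint,
        )


def collection_from_sets(
    sets: Mapping[str, Iterable[str]],
    names: Mapping[str, str] | None = None,
    categories: Mapping[str, str] | None = None,
    universe: Iterable[str] | None = None,
) -> PathwayCollection:
    """Build a validated collection from plain ``{id: genes}`` mappings."""
    entries = {}
    for pid, genes in sets.items():
        entries[pid] = Pathway(
            id=pid,
            name=(names or {}).get(pid, pid),
            category=(categories or {}).get(pid, ""),
            genes=frozenset(str(g).upper() for g in genes),
        )
    hint = frozenset(str(g).upper() for g in universe) if universe is not None else None
    return PathwayCollection(entries=entries, universe_hint=hint)


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> PathwayCollection:
    path = Path(path)
    entries: dict[str, Pathway] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            pid, desc = fields[0], fields[1]
            if pid in entries:
                raise ParseError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            name, _, category = desc.partition("|")
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                raise ParseError(f"{path}:{lineno}: pathway {pid!r} has no genes")
            entries[pid] = Pathway(id=pid, name=name, category=category, genes=genes)
    if not entries:
        raise ParseError(f"{path}: no gene sets")
    log.info("read %d gene sets from %s", len(entries), path)
    hint = frozenset(str(g).upper() for g in universe) if universe is not None else None
    return PathwayCollection(entries=entries, universe_hint=hint)


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for pid in collection.ids():
            p = collection.entries[pid]
            desc = f"{p.name}|{p.category}" if p.category else p.name
            fh.write("\t".join([pid, desc, *sorted(p.genes)]) + "\n")


# ---------------------------------------------------------------------------
# risk-gene list


@dataclass(frozen=True)
class RiskGeneList:
    """Curated disease risk genes, order-preserving, with optional evidence notes."""

    genes: tuple
    evidence: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.genes:
            raise ValueError("risk-gene list is empty")
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if list(self.genes).count(g) > 1})
            raise ValueError(f"duplicate genes in risk list: {dupes}")

    def __len__(self):
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def as_set(self) -> frozenset:
        return frozenset(self.genes)


def read_gene_list(path: str | Path) -> RiskGeneList:
    """One gene symbol per line, optional tab-separated evidence annotation."""
    path = Path(path)
    genes: list[str] = []
    evidence: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            gene = parts[0].strip().upper()
            if not gene:
                raise ParseError(f"{path}:{lineno}: empty gene symbol")
            if gene in genes:
                raise ParseError(f"{path}:{lineno}: duplicate gene {gene!r}")
            genes.append(gene)
            if len(parts) > 1 and parts[1].strip():
                evidence[gene] = parts[1].strip()
    if not genes:
        raise ParseError(f"{path}: no genes")
    return RiskGeneList(genes=tuple(genes), evidence=evidence)


def write_gene_list(genes: RiskGeneList, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g in genes:
            ev = genes.evidence.get(g, "")
            fh.write(f"{g}\t{ev}\n" if ev else f"{g}\n")


# ---------------------------------------------------------------------------
# miRNA target predictions


def normalize_mirna(name: str) -> str:
    """Lowercase, ``hsa-`` prefixed miRNA identifier."""
    n = name.strip().lower()
    if not n:
        raise ValueError("empty miRNA identifier")
    if not n.startswith("hsa-"):
        n = "hsa-" + n
    return n


@dataclass(frozen=True)
class PredictionTable:
    """Merged per-source miRNA->gene predictions with provenance.

    ``table`` has columns (mirna, gene, source), deduplicated triples;
    ``roster`` is the declared set of prediction sources (the k-of-N consensus
    denominator), which may exceed the sources actually present.
    """

    table: pd.DataFrame
    roster: tuple

    def __post_init__(self):
        unknown = set(self.table["source"]) - set(self.roster)
        if unknown:
            raise ValueError(f"sources outside declared roster: {sorted(unknown)}")

    @property
    def n_sources(self) -> int:
        return len(self.roster)


def predictions_from_frame(
    frame: pd.DataFrame, roster: Sequence[str] | None = None
) -> PredictionTable:
    df = frame.loc[:, ["mirna", "gene", "source"]].copy()
    df["mirna"] = df["mirna"].map(normalize_mirna)
    df["gene"] = df["gene"].str.upper()
    df = df.drop_duplicates(ignore_index=True)
    df = df.sort_values(["mirna", "gene", "source"], ignore_index=True)
    roster = tuple(roster) if roster is not None else tuple(sorted(df["source"].unique()))
    return PredictionTable(table=df, roster=roster)


def read_predictions(
    paths: Sequence[str | Path],
    roster: Sequence[str] | None = None,
    sources: Sequence[str] | None = None,
) -> PredictionTable:
    """Read one two-column TSV (miRNA, gene) per prediction source.

    The source name defaults to the filename stem; an explicit ``sources``
    list overrides it positionally.  ``roster`` declares the full tool roster
    when it is larger than the files supplied.
    """
    frames = []
    for idx, path in enumerate(paths):
        path = Path(path)
        source = sources[idx] if sources is not None else path.stem
        rows = []
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ParseError(
                        f"{path}:{lineno}: expected 2 columns (miRNA, gene), got {len(parts)}"
                    )
                rows.append((parts[0], parts[1]))
        if not rows:
            raise ParseError(f"{path}: no predictions")
        df = pd.DataFrame(rows, columns=["mirna", "gene"])
        df["source"] = source
        frames.append(df)
    if not frames:
        raise ParseError("no prediction files supplied")
    merged = pd.concat(frames, ignore_index=True)
    return predictions_from_frame(merged, roster=roster)


def write_predictions(pred: PredictionTable, outdir: str | Path) -> list[Path]:
    """One TSV per source under ``outdir``; inverse of :func:`read_predictions`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for source, group in pred.table.groupby("source", sort=True):
        p = outdir / f"{source}.tsv"
        group[["mirna", "gene"]].to_csv(p, sep="\t", header=False, index=False)
        written.append(p)
    return written


# ---------------------------------------------------------------------------
# miRSNP tables


@dataclass(frozen=True)
class MiRSNPTable:
    """Rows of (rsid, class, mirna, gene, source, validated); one row per
    supporting database.  Aggregation into per-binding-site records happens in
    the integration stage."""

    table: pd.DataFrame
    target_site_roster: tuple = ()
    mirna_gene_roster: tuple = ()


_MIRSNP_COLUMNS = ["rsid", "snp_class", "mirna", "gene", "source", "validated"]


def mirsnps_from_frame(
    frame: pd.DataFrame,
    target_site_roster: Sequence[str] | None = None,
    mirna_gene_roster: Sequence[str] | None = None,
) -> MiRSNPTable:
    df = frame.loc[:, _MIRSNP_COLUMNS].copy()
    df["mirna"] = df["mirna"].map(normalize_mirna)
    df["gene"] = df["gene"].fillna("").str.upper()
    df["validated"] = df["validated"].astype(bool)
    for i, row in df.iterrows():
        if not _RSID_RE.match(row["rsid"]):
            raise ParseError(f"row {i}: invalid rsID {row['rsid']!r}")
        if row["snp_class"] not in (TARGET_SITE, MIRNA_GENE):
            raise ParseError(f"row {i}: unknown class {row['snp_class']!r}")
        if row["snp_class"] == TARGET_SITE and not row["gene"]:
            raise ParseError(f"row {i}: {TARGET_SITE} row missing gene symbol")
    ts = df.loc[df["snp_class"] == TARGET_SITE, "source"]
    mg = df.loc[df["snp_class"] == MIRNA_GENE, "source"]
    ts_roster = tuple(target_site_roster) if target_site_roster else tuple(sorted(ts.unique()))
    mg_roster = tuple(mirna_gene_roster) if mirna_gene_roster else tuple(sorted(mg.unique()))
    if not set(ts).issubset(ts_roster):
        raise ParseError(f"target-site sources outside roster: {sorted(set(ts) - set(ts_roster))}")
    if not set(mg).issubset(mg_roster):
        raise ParseError(f"miRNA-gene sources outside roster: {sorted(set(mg) - set(mg_roster))}")
    df = df.drop_duplicates(ignore_index=True).sort_values(_MIRSNP_COLUMNS, ignore_index=True)
    return MiRSNPTable(table=df, target_site_roster=ts_roster, mirna_gene_roster=mg_roster)


def read_mirsnp_table(
    path: str | Path,
    target_site_roster: Sequence[str] | None = None,
    mirna_gene_roster: Sequence[str] | None = None,
) -> MiRSNPTable:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    missing = [c for c in _MIRSNP_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    truthy = {"1": True, "true": True, "0": False, "false": False}
    bad = [v for v in df["validated"].str.lower().unique() if v not in truthy]
    if bad:
        raise ParseError(f"{path}: invalid validated flags {bad}")
    df["validated"] = df["validated"].str.lower().map(truthy)
    return mirsnps_from_frame(df, target_site_roster, mirna_gene_roster)


def write_mirsnp_table(snps: MiRSNPTable, path: str | Path) -> None:
    df = snps.table.copy()
    df["validated"] = df["validated"].map({True: "1", False: "0"})
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# networks


def write_network(graph: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Serialize a network as GraphML or an edge-list TSV.

    Set- or tuple-valued attributes are flattened to ``;``-joined strings so
    the output is diffable text in both formats.  An empty graph yields a
    valid file with zero edges.
    """
    path = Path(path)
    g = graph.copy()
    for _, data in g.nodes(data=True):
        _flatten_attrs(data)
    for _, _, data in g.edges(data=True):
        _flatten_attrs(data)
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "edge-tsv":
        attr_keys = sorted({k for _, _, d in g.edges(data=True) for k in d})
        with path.open("w") as fh:
            fh.write("\t".join(["source", "target", *attr_keys]) + "\n")
            for u, v, d in sorted(g.edges(data=True)):
                fh.write("\t".join([str(u), str(v), *(str(d.get(k, "")) for k in attr_keys)]) + "\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def _flatten_attrs(data: dict) -> None:
    for k, v in list(data.items()):
        if isinstance(v, (set, frozenset, tuple, list)):
            data[k] = ";".join(str(e) for e in sorted(v))


# ---------------------------------------------------------------------------
# pair tables (retained miRNA-pathway tests)

_PAIR_COLUMNS = ["mirna", "pathway", "x", "n", "j", "m", "p", "p_adj"]


def write_pair_table(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.loc[:, _PAIR_COLUMNS].to_csv(path, sep="\t", index=False)


def read_pair_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# packaged fixture: the published KEGG enrichment table


def load_psd_enrichment_table() -> pd.DataFrame:
    """The packaged post-stroke-depression KEGG enrichment table.

    22 rows (pathway id, name, BH-adjusted p, category) as printed in the
    source study; all rows pass the adjusted p < 0.01 significance threshold
    used throughout the pipeline.
    """
    ref = resources.files("pmsnet").joinpath("data/psd_kegg_enrichment.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    df["p_adjust"] = df["p_adjust"].astype(float)
    return df
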