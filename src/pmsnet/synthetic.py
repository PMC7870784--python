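"""Seeded generator of synthetic pipeline inputs with planted structure.

The generator emulates every external input the pipeline consumes — a gene
universe, pathway gene sets, a curated risk-gene list, per-tool miRNA-target
prediction tables, and miRSNP evidence tables — while planting known
structure so each stage has ground truth:

* a handful of "planted" pathways in which the risk-gene list is enriched
  (a configurable fraction of risk genes are drawn from their member sets,
  spread evenly so small pathways are enriched too);
* shared-gene blocks between consecutive planted pathways, giving the
  crosstalk stage planted positive edges;
* hub miRNAs targeting a fixed fraction of every planted pathway's genes, and
  per-axis miRNA groups targeting a subset of them, giving the miRNA-pathway
  stage planted significant pairs and the topology stage planted hubs;
* per-axis target-site SNPs shared by the axis miRNAs on one risk gene,
  guaranteed to survive the database-consensus filter, giving axis extraction
  a known answer.

Prediction noise is modelled as independent per-tool Bernoulli detection of
true pairs (sensitivity) plus uniform false-positive pairs (fp rate); there
is no inter-tool correlation.  The same seed and config always produce a
byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    MIRNA_GENE,
    TARGET_SITE,
    MiRSNPTable,
    PathwayCollection,
    PredictionTable,
    RiskGeneList,
    collection_from_sets,
    mirsnps_from_frame,
    predictions_from_frame,
    write_gene_list,
    write_gmt,
    write_mirsnp_table,
    write_predictions,
)

__all__ = ["AxisSpec", "SynthConfig", "GroundTruth", "SyntheticBundle", "generate", "plant_axis"]

_CATEGORIES = (
    "Environmental information processing (signal transduction)",
    "Metabolism",
    "Organismal systems (nervous system)",
    "Organismal systems (immune system)",
    "Human diseases",
)


@dataclass(frozen=True)
class AxisSpec:
    """One planted miRSNP -> miRNA-group -> gene -> pathways axis."""

    n_mirnas: int = 5
    n_pathways: int = 3
    gene: str | None = None  # generator picks a dedicated universe gene if None


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults are the study conditions the suite runs at."""

    seed: int
    universe_size: int = 20_000
    n_pathways: int = 300
    pathway_size_range: tuple = (20, 300)  # log-uniform
    n_risk_genes: int = 54
    n_planted_pathways: int = 5
    enrichment_strength: float = 0.6  # fraction of risk genes drawn from planted pathways
    n_mirnas: int = 500
    target_count_range: tuple = (20, 200)  # log-uniform background targets per miRNA
    n_sources: int = 10
    source_sensitivity: float = 0.7
    source_fp_rate: float = 0.001
    n_target_site_snps: int = 60  # records, including planted axis sites
    n_mirna_gene_snps: int = 15
    target_site_db_roster: int = 4
    mirna_gene_db_roster: int = 3
    db_overlap_p: float = 0.4  # extra-database attachment probability
    validated_fraction: float = 0.2
    crosstalk_block_size: int = 15
    n_hub_mirnas: int = 1
    planted_target_fraction: float = 0.5  # of a planted pathway's genes hit by a planted miRNA
    consensus_k: int = 4
    min_dbs: int = 2
    axes: tuple = (AxisSpec(),)

    def validate(self) -> None:
        probs = {
            "enrichment_strength": self.enrichment_strength,
            "source_sensitivity": self.source_sensitivity,
            "source_fp_rate": self.source_fp_rate,
            "db_overlap_p": self.db_overlap_p,
            "validated_fraction": self.validated_fraction,
            "planted_target_fraction": self.planted_target_fraction,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        counts = {
            "universe_size": self.universe_size,
            "n_pathways": self.n_pathways,
            "n_risk_genes": self.n_risk_genes,
            "n_planted_pathways": self.n_planted_pathways,
            "n_mirnas": self.n_mirnas,
            "n_sources": self.n_sources,
            "target_site_db_roster": self.target_site_db_roster,
            "mirna_gene_db_roster": self.mirna_gene_db_roster,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_risk_genes > self.universe_size:
            raise ValueError("more risk genes than universe genes")
        if self.n_planted_pathways > self.n_pathways:
            raise ValueError("more planted pathways than pathways")
        if self.pathway_size_range[1] > self.universe_size:
            raise ValueError("pathway size range exceeds universe")
        if not 1 <= self.pathway_size_range[0] <= self.pathway_size_range[1]:
            raise ValueError("invalid pathway size range")
        if self.consensus_k > self.n_sources:
            raise ValueError("consensus threshold exceeds the source roster")
        if self.min_dbs > self.target_site_db_roster:
            raise ValueError("min_dbs exceeds the target-site database roster")
        reserved = self.n_hub_mirnas + sum(a.n_mirnas for a in self.axes)
        if reserved > self.n_mirnas:
            raise ValueError(
                f"planted miRNAs ({reserved}) exceed the miRNA count ({self.n_mirnas})"
            )
        axis_genes = [a.gene for a in self.axes if a.gene is not None]
        if len(set(axis_genes)) != len(axis_genes):
            raise ValueError("duplicate explicit axis genes")
        for a in self.axes:
            if a.n_mirnas < 1:
                raise ValueError("axis needs at least one miRNA")
            if a.n_pathways < 1:
                raise ValueError("axis needs at least one pathway")
            if a.n_pathways > self.n_planted_pathways:
                raise ValueError(
                    f"axis wants {a.n_pathways} pathways but only "
                    f"{self.n_planted_pathways} are planted"
                )
        planted_sites = sum(a.n_mirnas for a in self.axes)
        if planted_sites > self.n_target_site_snps:
            raise ValueError("planted axis SNP records exceed n_target_site_snps")


def plant_axis(config: SynthConfig, axis_spec: AxisSpec) -> SynthConfig:
    """Return a config with one more planted axis, validated for feasibility.

    The returned config guarantees the axis survives every downstream filter:
    its SNP records are forced into >= min_dbs databases, its miRNA-gene
    predictions into >= consensus_k tools, its gene into the risk list and the
    named number of planted pathways, and its miRNA targeting is strong enough
    to pass the significance threshold at the generator's defaults.
    """
    new = dataclasses.replace(config, axes=(*config.axes, axis_spec))
    new.validate()
    return new


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure, recorded at generation time for verification."""

    planted_pathways: tuple
    risk_gene_membership: Mapping[str, tuple]  # risk gene -> planted pathways containing it
    crosstalk_edges: tuple  # (a, b) with a < b
    true_targets: Mapping[str, frozenset]
    planted_pairs: tuple  # (mirna, pathway)
    hub_mirnas: tuple
    axes: tuple  # dicts: rsid, gene, mirnas, pathways
    mirsnp_records: Mapping[str, int]  # per class
    mirsnp_retained: Mapping[str, int]

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            raise TypeError(type(o))

        payload = {
            "planted_pathways": list(self.planted_pathways),
            "risk_gene_membership": {g: list(p) for g, p in self.risk_gene_membership.items()},
            "crosstalk_edges": [list(e) for e in self.crosstalk_edges],
            "true_targets": {m: sorted(t) for m, t in self.true_targets.items()},
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "hub_mirnas": list(self.hub_mirnas),
            "axes": list(self.axes),
            "mirsnp_records": dict(self.mirsnp_records),
            "mirsnp_retained": dict(self.mirsnp_retained),
        }
        return json.dumps(payload, indent=1, sort_keys=True, default=default)


@dataclass(frozen=True)
class SyntheticBundle:
    config: SynthConfig
    pathways: PathwayCollection  # universe_hint carries the full synthetic universe
    risk_genes: RiskGeneList
    predictions: PredictionTable
    mirsnps: MiRSNPTable
    truth: GroundTruth

    def write(self, outdir: str | Path) -> dict:
        """Serialize every input in the formats the readers consume."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gmt": outdir / "pathways.gmt",
            "universe": outdir / "universe.txt",
            "genes": outdir / "risk_genes.tsv",
            "predictions": outdir / "predictions",
            "mirsnps": outdir / "mirsnps.tsv",
            "truth": outdir / "truth.json",
        }
        write_gmt(self.pathways, paths["gmt"])
        with paths["universe"].open("w") as fh:
            for g in sorted(self.pathways.universe()):
                fh.write(g + "\n")
        write_gene_list(self.risk_genes, paths["genes"])
        write_predictions(self.predictions, paths["predictions"])
        write_mirsnp_table(self.mirsnps, paths["mirsnps"])
        paths["truth"].write_text(self.truth.to_json() + "\n")
        return paths


def _log_uniform_ints(rng: np.random.Generator, lo: int, hi: int, size: int) -> np.ndarray:
    vals = np.exp(rng.uniform(np.log(lo), np.log(hi + 1), size=size))
    return np.clip(vals.astype(np.int64), lo, hi)


def generate(config: SynthConfig) -> SyntheticBundle:
    """Generate a full, internally consistent synthetic bundle."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    universe = np.array([f"G{i:05d}" for i in range(1, config.universe_size + 1)])

    # --- pathways -----------------------------------------------------------
    pids = [f"PW{i:04d}" for i in range(1, config.n_pathways + 1)]
    planted = tuple(pids[: config.n_planted_pathways])
    sizes = _log_uniform_ints(rng, *config.pathway_size_range, size=config.n_pathways)
    sets: dict[str, set] = {
        pid: set(rng.choice(universe, size=int(sz), replace=False))
        for pid, sz in zip(pids, sizes)
    }

    # crosstalk blocks: a chain over the planted pathways; block genes are kept
    # out of planted miRNA targeting below so the only planted dependencies
    # between miRNAs and pathways are the ones recorded in the ground truth
    crosstalk_edges = []
    block_genes: set = set()
    for a, b in zip(planted, planted[1:]):
        block = rng.choice(universe, size=config.crosstalk_block_size, replace=False)
        sets[a].update(block)
        sets[b].update(block)
        block_genes.update(block)
        crosstalk_edges.append(tuple(sorted((a, b))))

    # --- axis genes (placed before risk-gene sampling) ----------------------
    taken_genes: set = set()
    axis_genes: list[str] = []
    axis_pathway_lists: list[tuple] = []
    offset = 0
    for spec in config.axes:
        if spec.gene is not None:
            gene = spec.gene.upper()
        else:
            while True:
                gene = str(rng.choice(universe))
                if gene not in taken_genes:
                    break
        if gene in taken_genes:
            raise ValueError(f"axis gene {gene} already used by another axis")
        taken_genes.add(gene)
        axis_genes.append(gene)
        chosen = tuple(
            planted[(offset + i) % config.n_planted_pathways] for i in range(spec.n_pathways)
        )
        offset += spec.n_pathways
        axis_pathway_lists.append(chosen)
        for pid in chosen:
            sets[pid].add(gene)

    # --- miRNAs and true targets --------------------------------------------
    mirnas = [f"hsa-mir-{i:04d}" for i in range(1, config.n_mirnas + 1)]
    hub_mirnas = tuple(mirnas[: config.n_hub_mirnas])
    cursor = config.n_hub_mirnas
    axis_mirna_lists: list[tuple] = []
    for spec in config.axes:
        axis_mirna_lists.append(tuple(mirnas[cursor : cursor + spec.n_mirnas]))
        cursor += spec.n_mirnas

    bg_counts = _log_uniform_ints(rng, *config.target_count_range, size=config.n_mirnas)
    true_targets: dict[str, set] = {
        m: set(rng.choice(universe, size=int(c), replace=False))
        for m, c in zip(mirnas, bg_counts)
    }

    def plant_targets(mirna: str, pathway: str) -> None:
        genes = sorted(sets[pathway] - block_genes)
        n_hit = max(1, int(round(config.planted_target_fraction * len(genes))))
        hit = rng.choice(genes, size=n_hit, replace=False)
        true_targets[mirna].update(hit)

    planted_pairs: list[tuple] = []
    for hub in hub_mirnas:
        for pid in planted:
            plant_targets(hub, pid)
            planted_pairs.append((hub, pid))
    for gene, group, pw_list in zip(axis_genes, axis_mirna_lists, axis_pathway_lists):
        for mirna in group:
            true_targets[mirna].add(gene)
            for pid in pw_list:
                plant_targets(mirna, pid)
                planted_pairs.append((mirna, pid))

    # --- risk genes ----------------------------------------------------------
    n_from_planted = int(round(config.enrichment_strength * config.n_risk_genes))
    risk: list[str] = list(axis_genes)
    membership: dict[str, tuple] = {}
    # spread planted members evenly so small planted pathways are enriched too
    slot = 0
    guard = 0
    while len(risk) < n_from_planted:
        pid = planted[slot % len(planted)]
        candidates = sorted(sets[pid] - set(risk))
        guard += 1
        if guard > 100 * config.n_risk_genes:
            raise ValueError("cannot place enough risk genes inside planted pathways")
        if candidates:
            risk.append(str(rng.choice(candidates)))
        slot += 1
    planted_union: set = set()
    for pid in planted:
        planted_union |= sets[pid]
    for g in risk:
        membership[g] = tuple(pid for pid in planted if g in sets[pid])
    # background risk genes are drawn outside every pathway gene set
    # (unannotated genes), so pathway membership of the risk list — and hence
    # enrichment and coverage ground truth — is exactly the planted part
    all_union: set = set()
    for genes in sets.values():
        all_union |= genes
    pool = np.array(sorted(set(universe) - all_union - set(risk)))
    n_bg = config.n_risk_genes - len(risk)
    if n_bg < 0:
        raise ValueError("axis genes exceed the planted risk-gene budget")
    if n_bg > len(pool):
        raise ValueError("universe too small for unannotated background risk genes")
    risk += [str(g) for g in rng.choice(pool, size=n_bg, replace=False)]

    # --- prediction tables ----------------------------------------------------
    sources = [f"tool{t:02d}" for t in range(1, config.n_sources + 1)]
    pair_mirnas: list[str] = []
    pair_genes: list[str] = []
    for m in mirnas:
        for g in sorted(true_targets[m]):
            pair_mirnas.append(m)
            pair_genes.append(g)
    n_true = len(pair_mirnas)
    detected = rng.random((n_true, config.n_sources)) < config.source_sensitivity

    # force planted axis binding pairs through the k-of-N consensus
    forced = {
        (mirna, gene)
        for gene, group in zip(axis_genes, axis_mirna_lists)
        for mirna in group
    }
    for idx in range(n_true):
        if (pair_mirnas[idx], pair_genes[idx]) in forced:
            cols = rng.choice(config.n_sources, size=config.consensus_k, replace=False)
            detected[idx, cols] = True

    frames = []
    n_possible = config.n_mirnas * config.universe_size
    for t, source in enumerate(sources):
        mask = detected[:, t]
        df = pd.DataFrame(
            {
                "mirna": np.asarray(pair_mirnas, dtype=object)[mask],
                "gene": np.asarray(pair_genes, dtype=object)[mask],
            }
        )
        n_fp = rng.binomial(n_possible, config.source_fp_rate)
        if n_fp:
            fp = pd.DataFrame(
                {
                    "mirna": np.asarray(mirnas, dtype=object)[
                        rng.integers(0, config.n_mirnas, size=n_fp)
                    ],
                    "gene": universe[rng.integers(0, config.universe_size, size=n_fp)],
                }
            )
            df = pd.concat([df, fp], ignore_index=True)
        df["source"] = source
        frames.append(df)
    predictions = predictions_from_frame(pd.concat(frames, ignore_index=True), roster=sources)

    # --- miRSNP tables ----------------------------------------------------------
    ts_roster = [f"tsdb{i}" for i in range(1, config.target_site_db_roster + 1)]
    mg_roster = [f"mgdb{i}" for i in range(1, config.mirna_gene_db_roster + 1)]
    rs_counter = 1_000_000
    rows: list[tuple] = []
    truth_axes = []
    n_ts_records = 0

    def db_draw(roster: list[str], forced_min: int) -> list[str]:
        extra = int(rng.binomial(len(roster) - forced_min, config.db_overlap_p))
        count = min(len(roster), forced_min + extra)
        return sorted(rng.choice(roster, size=count, replace=False))

    for gene, group, pw_list in zip(axis_genes, axis_mirna_lists, axis_pathway_lists):
        rsid = f"rs{rs_counter}"
        rs_counter += 1
        for mirna in group:
            validated = bool(rng.random() < config.validated_fraction)
            for db in db_draw(ts_roster, config.min_dbs):
                rows.append((rsid, TARGET_SITE, mirna, gene, db, validated))
            n_ts_records += 1
        truth_axes.append(
            {"rsid": rsid, "gene": gene, "mirnas": list(group), "pathways": sorted(pw_list)}
        )

    retained = {TARGET_SITE: n_ts_records, MIRNA_GENE: 0}  # planted sites always pass
    while n_ts_records < config.n_target_site_snps:
        rsid = f"rs{rs_counter}"
        rs_counter += 1
        mirna = str(rng.choice(mirnas))
        gene = str(rng.choice(sorted(true_targets[mirna])))
        validated = bool(rng.random() < config.validated_fraction)
        dbs = db_draw(ts_roster, 1)
        for db in dbs:
            rows.append((rsid, TARGET_SITE, mirna, gene, db, validated))
        n_ts_records += 1
        retained[TARGET_SITE] += int(validated or len(dbs) >= config.min_dbs)

    # annotate planted miRNAs first so node-level marks exist, then random ones
    mg_targets = list(hub_mirnas) + [m for grp in axis_mirna_lists for m in grp]
    for i in range(config.n_mirna_gene_snps):
        rsid = f"rs{rs_counter}"
        rs_counter += 1
        mirna = mg_targets[i] if i < len(mg_targets) else str(rng.choice(mirnas))
        validated = bool(rng.random() < config.validated_fraction)
        dbs = db_draw(mg_roster, 1)
        for db in dbs:
            rows.append((rsid, MIRNA_GENE, mirna, "", db, validated))
        retained[MIRNA_GENE] += int(validated or len(dbs) >= config.min_dbs)

    mirsnps = mirsnps_from_frame(
        pd.DataFrame(rows, columns=["rsid", "snp_class", "mirna", "gene", "source", "validated"]),
        target_site_roster=ts_roster,
        mirna_gene_roster=mg_roster,
    )

    truth = GroundTruth(
        planted_pathways=planted,
        risk_gene_membership=membership,
        crosstalk_edges=tuple(crosstalk_edges),
        true_targets={m: frozenset(t) for m, t in true_targets.items()},
        planted_pairs=tuple(sorted(planted_pairs)),
        hub_mirnas=hub_mirnas,
        axes=tuple(truth_axes),
        mirsnp_records={
            TARGET_SITE: config.n_target_site_snps,
            MIRNA_GENE: config.n_mirna_gene_snps,
        },
        mirsnp_retained=retained,
    )
    pathways = collection_from_sets(
        {pid: sets[pid] for pid in pids},
        names={pid: f"synthetic pathway {pid}" for pid in pids},
        categories={pid: _CATEGORIES[i % len(_CATEGORIES)] for i, pid in enumerate(pids)},
        universe=universe,
    )
    return SyntheticBundle(
        config=config,
        pathways=pathways,
        risk_genes=RiskGeneList(genes=tuple(risk)),
        predictions=predictions,
        mirsnps=mirsnps,
        truth=truth,
    )
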