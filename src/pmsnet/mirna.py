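"""Consensus miRNA-target integration and miRNA -> pathway enrichment.

Target predictions from N independent tools are unreliable individually; a
(miRNA, gene) pair is kept only when at least k distinct tools agree (the
k-of-N consensus rule, default 4 of 10).  Each surviving miRNA's target set is
then tested against every risk pathway with the upper-tail hypergeometric
statistic, with a single global BH correction over all (miRNA, pathway)
combinations, so the false-discovery rate is controlled over the reported
pair list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .enrichment import resolve_universe
from .io import PathwayCollection, PredictionTable
from .stats import bh_adjust, hypergeom_upper_many

__all__ = [
    "ConsensusTargetMap",
    "MirnaPathwayPair",
    "build_consensus",
    "mirna_pathway_enrichment",
    "pairs_to_frame",
]


@dataclass(frozen=True)
class ConsensusTargetMap:
    """miRNA -> target-gene sets surviving the >=k-of-N source rule."""

    targets: Mapping[str, frozenset]
    k: int
    n_sources: int

    def __len__(self):
        return len(self.targets)

    def target_counts(self) -> pd.DataFrame:
        rows = sorted((m, len(g)) for m, g in self.targets.items())
        return pd.DataFrame(rows, columns=["mirna", "n_targets"])


def build_consensus(predictions: PredictionTable, k: int = 4) -> ConsensusTargetMap:
    """Retain exactly the (miRNA, gene) pairs supported by >= k distinct sources."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > predictions.n_sources:
        raise ValueError(f"k={k} exceeds the source roster size {predictions.n_sources}")
    df = predictions.table
    if df.empty:
        raise ValueError("empty prediction table")
    support = df.groupby(["mirna", "gene"], sort=False)["source"].nunique()
    kept = support[support >= k]
    targets: dict[str, set] = {}
    for mirna, gene in kept.index:
        targets.setdefault(mirna, set()).add(gene)
    return ConsensusTargetMap(
        targets={m: frozenset(g) for m, g in targets.items()},
        k=k,
        n_sources=predictions.n_sources,
    )


@dataclass(frozen=True)
class MirnaPathwayPair:
    mirna: str
    pathway: str
    x: int
    n: int
    j: int
    m: int
    p: float
    p_adj: float


def mirna_pathway_enrichment(
    targets: ConsensusTargetMap,
    risk_pathways: PathwayCollection,
    universe: Iterable[str] | None = None,
    m: int | None = None,
    alpha: float = 0.01,
    fdr_scope: str = "global",
) -> list[MirnaPathwayPair]:
    """Test every miRNA target set against every risk pathway.

    Returns the pairs retained at adjusted p < alpha, sorted by
    (miRNA, pathway).  ``fdr_scope`` is "global" (one BH family over all
    combinations; the default) or "per-mirna".
    """
    if len(risk_pathways) == 0:
        raise ValueError("empty pathway collection")
    if fdr_scope not in ("global", "per-mirna"):
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    uni, m_eff = resolve_universe(risk_pathways, universe, m)

    pids = risk_pathways.ids()
    psets = {}
    for pid in pids:
        genes = risk_pathways.genes(pid)
        psets[pid] = genes & uni if uni is not None else genes

    mirnas = sorted(targets.targets)
    combos, js, ns, xs = [], [], [], []
    for mirna in mirnas:
        tset = targets.targets[mirna]
        if uni is not None:
            tset = tset & uni
        n = len(tset)
        for pid in pids:
            combos.append((mirna, pid))
            js.append(len(psets[pid]))
            ns.append(n)
            xs.append(len(tset & psets[pid]))
    if not combos:
        return []

    ps = hypergeom_upper_many(m_eff, js, ns, xs)
    if fdr_scope == "global":
        adjusted = np.asarray(bh_adjust(ps, alpha=alpha).adjusted)
    else:
        adjusted = np.empty_like(ps)
        n_path = len(pids)
        for i in range(len(mirnas)):
            sl = slice(i * n_path, (i + 1) * n_path)
            adjusted[sl] = bh_adjust(ps[sl], alpha=alpha).adjusted

    pairs = [
        MirnaPathwayPair(
            mirna=mirna, pathway=pid, x=x, n=n, j=j, m=m_eff, p=float(p), p_adj=float(q)
        )
        for (mirna, pid), x, n, j, p, q in zip(combos, xs, ns, js, ps, adjusted)
        if q < alpha
    ]
    pairs.sort(key=lambda pr: (pr.mirna, pr.pathway))
    return pairs


def pairs_to_frame(pairs: Iterable[MirnaPathwayPair]) -> pd.DataFrame:
    rows = [
        (p.mirna, p.pathway, p.x, p.n, p.j, p.m, p.p, p.p_adj) for p in pairs
    ]
    return pd.DataFrame(rows, columns=["mirna", "pathway", "x", "n", "j", "m", "p", "p_adj"])


def pairs_from_frame(frame: pd.DataFrame) -> list[MirnaPathwayPair]:
    pairs = [
        MirnaPathwayPair(
            mirna=r.mirna, pathway=r.pathway, x=int(r.x), n=int(r.n), j=int(r.j),
            m=int(r.m), p=float(r.p), p_adj=float(r.p_adj),
        )
        for r in frame.itertuples(index=False)
    ]
    pairs.sort(key=lambda pr: (pr.mirna, pr.pathway))
    return pairs
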