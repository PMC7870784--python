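"""Pairwise crosstalk among risk pathways.

Two pathways "crosstalk" when they share more genes than a uniform draw would
give: each unordered pair is scored with the upper-tail hypergeometric
probability of its overlap (symmetric in the two set sizes), BH correction
runs across all tested pairs, and pairs with adjusted p below alpha become
edges of an undirected crosstalk network whose edge weight -log10(p_adj)
tracks association strength.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import pandas as pd

from .enrichment import resolve_universe
from .io import PathwayCollection
from .stats import bh_adjust, hypergeom_upper_many

__all__ = ["CrosstalkEdge", "crosstalk_network", "crosstalk_degree", "crosstalk_graph"]

_P_FLOOR = 1e-300


@dataclass(frozen=True)
class CrosstalkEdge:
    a: str  # lexicographically smaller pathway id
    b: str
    x: int
    p: float
    p_adj: float
    weight: float

    def __post_init__(self):
        if not self.a < self.b:
            raise ValueError("crosstalk edge must be stored with a < b")


def crosstalk_network(
    pathways: PathwayCollection,
    universe: Iterable[str] | None = None,
    m: int | None = None,
    alpha: float = 0.01,
) -> list[CrosstalkEdge]:
    """Test all unordered pathway pairs; keep edges with adjusted p < alpha."""
    pids = pathways.ids()
    if len(pids) < 2:
        raise ValueError("crosstalk needs at least 2 pathways")
    uni, m_eff = resolve_universe(pathways, universe, m)

    sets = {}
    for pid in pids:
        genes = pathways.genes(pid)
        if uni is not None:
            genes = genes & uni
            if not genes:
                raise ValueError(f"pathway {pid} has no genes inside the universe")
        sets[pid] = genes

    pairs = list(itertools.combinations(pids, 2))
    js = [len(sets[a]) for a, _ in pairs]
    ns = [len(sets[b]) for _, b in pairs]
    xs = [len(sets[a] & sets[b]) for a, b in pairs]
    ps = hypergeom_upper_many(m_eff, js, ns, xs)
    adjusted = bh_adjust(ps, alpha=alpha).adjusted

    edges = []
    for (a, b), x, p, q in zip(pairs, xs, ps, adjusted):
        if q < alpha:
            edges.append(
                CrosstalkEdge(
                    a=min(a, b),
                    b=max(a, b),
                    x=x,
                    p=float(p),
                    p_adj=float(q),
                    weight=-math.log10(max(float(q), _P_FLOOR)),
                )
            )
    edges.sort(key=lambda e: (e.a, e.b))
    return edges


def crosstalk_degree(
    edges: Iterable[CrosstalkEdge],
    pathways: PathwayCollection | None = None,
) -> pd.DataFrame:
    """Per-pathway count of incident kept edges, sorted descending (ties by id).

    Passing the collection includes zero-degree pathways in the table.
    """
    counts: dict[str, int] = {}
    if pathways is not None:
        counts = {pid: 0 for pid in pathways.ids()}
    for e in edges:
        counts[e.a] = counts.get(e.a, 0) + 1
        counts[e.b] = counts.get(e.b, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["pathway", "degree"])


def crosstalk_graph(edges: Iterable[CrosstalkEdge]) -> nx.Graph:
    """The kept edges as an undirected weighted graph (for serialization)."""
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.a, e.b, x=e.x, p=e.p, p_adj=e.p_adj, weight=e.weight)
    return g
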