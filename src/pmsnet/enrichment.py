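"""Over-representation analysis of a risk-gene list against a pathway collection.

For each pathway with gene set of size ``j`` inside a universe of ``m`` genes,
the overlap ``x`` with the ``n``-gene query is scored with the upper-tail
hypergeometric probability P(X >= x); Benjamini-Hochberg correction runs over
the full family of tested pathways (including those with zero overlap, which
contribute p = 1 and only the family size M).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io import PathwayCollection, RiskGeneList
from .stats import bh_adjust, hypergeom_upper_many

log = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "enrich", "coverage_fraction", "resolve_universe"]


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    name: str
    category: str
    x: int
    j: int
    n: int
    m: int
    p: float
    p_adj: float
    hits: frozenset
    significant: bool


def resolve_universe(
    collection: PathwayCollection,
    universe: Iterable[str] | None = None,
    m: int | None = None,
) -> tuple[frozenset | None, int]:
    """Resolve the (universe set, m) pair used by a test family.

    Precedence: explicit ``universe`` set > explicit integer ``m`` (sets kept
    as-is, no restriction) > the collection's own universe (hint or union of
    all gene sets).
    """
    if universe is not None:
        uni = frozenset(str(g).upper() for g in universe)
        return uni, len(uni)
    if m is not None:
        union = collection.universe()
        if m < len(union):
            raise ValueError(
                f"explicit m={m} smaller than the {len(union)} genes in the collection"
            )
        return None, int(m)
    uni = collection.universe()
    return uni, len(uni)


def enrich(
    query: RiskGeneList | Iterable[str],
    collection: PathwayCollection,
    universe: Iterable[str] | None = None,
    m: int | None = None,
    alpha: float = 0.01,
    tail: str = "upper",
) -> list[EnrichmentResult]:
    """Test the query gene list against every pathway in the collection.

    Returns one result per pathway with x >= 1, sorted by adjusted p
    ascending (ties broken by pathway id); ``significant`` flags adjusted
    p < alpha.  Query genes outside the universe are dropped from n with a
    logged warning.
    """
    query_genes = [str(g).upper() for g in query]
    if not query_genes:
        raise ValueError("empty query")
    uni, m_eff = resolve_universe(collection, universe, m)

    if uni is not None:
        kept = [g for g in dict.fromkeys(query_genes) if g in uni]
        dropped = len(set(query_genes)) - len(kept)
        if dropped:
            log.warning("dropped %d query genes outside the universe", dropped)
        if not kept:
            raise ValueError("query outside universe")
        qset = frozenset(kept)
    else:
        qset = frozenset(query_genes)
    n = len(qset)

    pids = collection.ids()
    js, xs, hitsets = [], [], []
    for pid in pids:
        genes = collection.genes(pid)
        if uni is not None:
            genes = genes & uni
        hits = genes & qset
        js.append(len(genes))
        xs.append(len(hits))
        hitsets.append(frozenset(hits))

    from .stats import hypergeom_lower_printed  # local: rarely used path

    if tail == "upper":
        ps = hypergeom_upper_many(m_eff, js, [n] * len(pids), xs)
    elif tail == "printed-lower":
        ps = np.array(
            [hypergeom_lower_printed(m=m_eff, j=j, n=n, x=x) for j, x in zip(js, xs)]
        )
    else:
        raise ValueError(f"unknown tail {tail!r}")

    adjusted = bh_adjust(ps, alpha=alpha).adjusted
    results = [
        EnrichmentResult(
            pathway_id=pid,
            name=collection.entries[pid].name,
            category=collection.entries[pid].category,
            x=x,
            j=j,
            n=n,
            m=m_eff,
            p=float(p),
            p_adj=float(q),
            hits=hits,
            significant=bool(q < alpha),
        )
        for pid, x, j, p, q, hits in zip(pids, xs, js, ps, adjusted, hitsets)
        if x >= 1
    ]
    results.sort(key=lambda r: (r.p_adj, r.pathway_id))
    return results


def coverage_fraction(results: Iterable[EnrichmentResult], query: RiskGeneList | Iterable[str]) -> float:
    """Fraction of query genes hit by at least one significant pathway."""
    query_genes = [str(g).upper() for g in query]
    covered: set = set()
    for r in results:
        if r.significant:
            covered |= r.hits
    return len([g for g in dict.fromkeys(query_genes) if g in covered]) / len(
        dict.fromkeys(query_genes)
    )
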