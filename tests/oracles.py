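"""Independent reference implementations used only to check the package.

Everything here is deliberately naive: exact rational arithmetic, explicit
enumeration of draws, and breadth-first path enumeration.  None of it shares
code with the implementation under test.
"""

from __future__ import annotations

import itertools
from collections import deque
from fractions import Fraction
from math import comb


def rational_upper_tail(m: int, j: int, n: int, x: int) -> Fraction:
    """P(X >= x) for Hypergeometric(m, j, n) as an exact rational."""
    total = comb(m, n)
    acc = Fraction(0)
    for i in range(x, min(j, n) + 1):
        acc += Fraction(comb(j, i) * comb(m - j, n - i), total)
    return acc


def rational_lower_tail(m: int, j: int, n: int, x: int) -> Fraction:
    total = comb(m, n)
    acc = Fraction(0)
    for i in range(0, min(x, j, n) + 1):
        acc += Fraction(comb(j, i) * comb(m - j, n - i), total)
    return acc


def draws_upper_tail(m: int, j: int, n: int, x: int) -> Fraction:
    """Same tail by literally enumerating every n-subset of an m-element
    universe whose first j elements form the reference set."""
    reference = set(range(j))
    hits = sum(
        1 for draw in itertools.combinations(range(m), n) if len(reference & set(draw)) >= x
    )
    return Fraction(hits, comb(m, n))


def betweenness_by_path_enumeration(graph) -> dict:
    """Normalized betweenness via explicit shortest-path enumeration.

    For each ordered source, a BFS builds the shortest-path predecessor DAG;
    all shortest paths to every target are then enumerated one by one and
    interior vertices counted.  O(paths) — fine for graphs of a few dozen
    nodes, which is all this oracle is for.
    """
    nodes = list(graph.nodes())
    score = {v: 0.0 for v in nodes}
    n = len(nodes)
    if n <= 2:
        return score

    adjacency = {v: sorted(graph.neighbors(v)) for v in nodes}
    for s_idx, s in enumerate(nodes):
        dist = {s: 0}
        preds: dict = {s: []}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for w in adjacency[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    preds[w] = [u]
                    queue.append(w)
                elif dist[w] == dist[u] + 1:
                    preds[w].append(u)

        def all_paths(t):
            if t == s:
                return [[s]]
            out = []
            for p in preds[t]:
                for path in all_paths(p):
                    out.append(path + [t])
            return out

        for t in nodes[s_idx + 1 :]:  # each unordered pair once
            if t not in dist:
                continue
            paths = all_paths(t)
            for path in paths:
                for v in path[1:-1]:
                    score[v] += 1.0 / len(paths)

    norm = (n - 1) * (n - 2) / 2.0
    return {v: score[v] / norm for v in nodes}
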