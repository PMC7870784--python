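"""Exact hypergeometric tail probabilities and Benjamini-Hochberg FDR control.

Every over-representation test in this package reduces to one question: given
a universe of ``m`` genes, a reference set of ``j`` genes and a query set of
``n`` genes, how surprising is an observed overlap of ``x`` genes?  Under the
null hypothesis that the query is a uniform draw without replacement, the
overlap follows a hypergeometric distribution, and the enrichment p-value is
the upper tail P(X >= x).

The lower tail P(X <= x) is also exposed (:func:`hypergeom_lower_printed`)
because some published formulations write the cumulative sum from zero; it is
anti-conservative for over-representation and exists only for literal
reproduction via the ``tail`` switch accepted by the pipeline stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom as _hypergeom

__all__ = [
    "HypergeomParams",
    "PValueVector",
    "hypergeom_upper",
    "hypergeom_lower_printed",
    "hypergeom_upper_many",
    "bh_adjust",
]


@dataclass(frozen=True)
class HypergeomParams:
    """Parameters of one overlap test.

    m
        universe size (total genes).
    j
        size of the reference set (e.g. a pathway).
    n
        size of the query set (another pathway, or a miRNA target set).
    x
        observed overlap between the two sets.
    """

    m: int
    j: int
    n: int
    x: int

    def __post_init__(self) -> None:
        for field in ("m", "j", "n", "x"):
            v = getattr(self, field)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ValueError(f"{field} must be a non-negative integer, got {v!r}")
            if v < 0:
                raise ValueError(f"{field} must be non-negative, got {v}")
        if self.j > self.m:
            raise ValueError(f"j ({self.j}) exceeds universe size m ({self.m})")
        if self.n > self.m:
            raise ValueError(f"n ({self.n}) exceeds universe size m ({self.m})")
        if self.x > min(self.j, self.n):
            raise ValueError(
                f"x ({self.x}) exceeds min(j, n) = {min(self.j, self.n)}"
            )


def _coerce(params, m, j, n, x) -> HypergeomParams:
    if params is not None:
        return params
    return HypergeomParams(m=m, j=j, n=n, x=x)


def hypergeom_upper(
    params: HypergeomParams | None = None,
    *,
    m: int | None = None,
    j: int | None = None,
    n: int | None = None,
    x: int | None = None,
) -> float:
    """Upper-tail P(X >= x) of Hypergeometric(m, j, n).

    Accepts either a :class:`HypergeomParams` or the four counts as keywords.
    This is the enrichment p-value used throughout the pipeline.
    """
    p = _coerce(params, m, j, n, x)
    # sf(x - 1) = P(X >= x); exact also at x = 0 where the tail is 1.
    val = float(_hypergeom.sf(p.x - 1, p.m, p.j, p.n))
    return min(max(val, 0.0), 1.0)


def hypergeom_lower_printed(
    params: HypergeomParams | None = None,
    *,
    m: int | None = None,
    j: int | None = None,
    n: int | None = None,
    x: int | None = None,
) -> float:
    """Lower-tail P(X <= x): the cumulative sum running from i = 0 to x.

    Satisfies ``hypergeom_upper(x) == 1 - hypergeom_lower_printed(x - 1)``
    for x >= 1.  Not a sensible over-representation statistic; see module
    docstring.
    """
    p = _coerce(params, m, j, n, x)
    val = float(_hypergeom.cdf(p.x, p.m, p.j, p.n))
    return min(max(val, 0.0), 1.0)


def hypergeom_upper_many(
    m: int,
    j: Sequence[int] | np.ndarray,
    n: Sequence[int] | np.ndarray,
    x: Sequence[int] | np.ndarray,
) -> np.ndarray:
    """Vectorized upper tail over parallel arrays of (j, n, x) at fixed m."""
    j = np.asarray(j, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    x = np.asarray(x, dtype=np.int64)
    if np.any(j > m) or np.any(n > m):
        raise ValueError("set size exceeds universe size m")
    if np.any(x > np.minimum(j, n)) or np.any(x < 0):
        raise ValueError("overlap x outside [0, min(j, n)]")
    return np.clip(_hypergeom.sf(x - 1, m, j, n), 0.0, 1.0)


@dataclass(frozen=True)
class PValueVector:
    """Raw and BH-adjusted p-values, kept in the original input order."""

    raw: tuple
    adjusted: tuple
    alpha: float = 0.01

    def significant(self, alpha: float | None = None) -> np.ndarray:
        a = self.alpha if alpha is None else alpha
        return np.asarray(self.adjusted) < a


def bh_adjust(raw: Sequence[float], alpha: float = 0.01) -> PValueVector:
    """Benjamini-Hochberg step-up adjustment.

    Sort ascending, take ``p_(k) * M / k``, enforce monotonicity by a
    cumulative minimum from the largest rank down, clip to 1, and map back to
    the input order.  Stable sort, so tied p-values keep their input order
    (they receive identical adjusted values regardless).
    """
    p = np.asarray(raw, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d sequence of p-values")
    if p.size == 0:
        return PValueVector(raw=(), adjusted=(), alpha=alpha)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        bad = p[(~np.isfinite(p)) | (p < 0) | (p > 1)][0]
        raise ValueError(f"p-value outside [0, 1]: {bad!r}")
    M = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * M / np.arange(1, M + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adjusted = np.empty(M, dtype=float)
    adjusted[order] = adj_sorted
    return PValueVector(raw=tuple(p.tolist()), adjusted=tuple(adjusted.tolist()), alpha=alpha)
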