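"""Over-representation and overlap statistics for gene lists.

Hypergeometric upper-tail ORA against a GMT collection with size filters
and BH correction, two-sided Fisher overlap with an explicit background
universe, and a greedy Jaccard redundancy reduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from netmediator._stats import bh_adjust
from netmediator.io_formats import GeneSetCollection

__all__ = ["OverlapResult", "hypergeom_ora", "fisher_overlap", "reduce_redundancy"]

DEFAULT_BACKGROUND = 20_000


@dataclass
class OverlapResult:
    """A 2x2 overlap table with its odds ratio and p-value.

    a = |query ∩ set|, b = |query \\ set|, c = |set \\ query|,
    d = background remainder; odds_ratio = (a*d)/(b*c).
    """

    name: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    adj_p: float = float("nan")

    @property
    def background_size(self) -> int:
        return self.a + self.b + self.c + self.d


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if a == 0:
        return 0.0
    if b * c == 0:
        return float("inf")
    return (a * d) / (b * c)


def hypergeom_ora(
    query: list[str],
    collection: GeneSetCollection,
    background: list[str],
    min_size: int = 10,
    max_size: int = 500,
) -> list[OverlapResult]:
    """Upper-tail hypergeometric over-representation analysis.

    Sets are restricted to the background and kept if their filtered size
    is within [min_size, max_size]; p = P(X >= a) with N = |background|,
    K = filtered set size, n = |query|; BH across tested sets. Query genes
    outside the background are dropped with a warning.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background universe")
    q = [g for g in dict.fromkeys(query)]
    outside = [g for g in q if g not in bg]
    if outside:
        warnings.warn(f"{len(outside)} query gene(s) outside background dropped")
        q = [g for g in q if g in bg]
    qset = set(q)
    N, n = len(bg), len(qset)

    results: list[OverlapResult] = []
    for name in collection.names():
        members = set(collection.members(name)) & bg
        K = len(members)
        if not min_size <= K <= max_size:
            continue
        a = len(qset & members)
        b = n - a
        c = K - a
        d = N - n - c
        p = float(stats.hypergeom.sf(a - 1, N, K, n))
        results.append(
            OverlapResult(name=name, a=a, b=b, c=c, d=d, odds_ratio=_odds_ratio(a, b, c, d), p_value=p)
        )
    if results:
        adj = bh_adjust(np.array([r.p_value for r in results]))
        for r, ap in zip(results, adj):
            r.adj_p = float(ap)
    return results


def fisher_overlap(
    query: list[str],
    reference: list[str],
    background_size: int = DEFAULT_BACKGROUND,
    name: str = "overlap",
) -> OverlapResult:
    """Two-sided Fisher's exact test of the overlap of two gene lists.

    The 2x2 table is built inside an explicit background universe of
    ``background_size`` genes; the odds ratio is the sample odds ratio
    (a*d)/(b*c).
    """
    qset = set(query)
    rset = set(reference)
    if background_size < len(qset | rset):
        raise ValueError("background_size smaller than the union of the two lists")
    a = len(qset & rset)
    b = len(qset) - a
    c = len(rset) - a
    d = background_size - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return OverlapResult(
        name=name, a=a, b=b, c=c, d=d, odds_ratio=_odds_ratio(a, b, c, d), p_value=float(p)
    )


def reduce_redundancy(
    results: list[OverlapResult],
    member_map: dict[str, list[str]],
    cutoff: float = 0.8,
) -> list[OverlapResult]:
    """Drop terms too similar to an already-kept, more significant term.

    Greedy by ascending adjusted p (ties by name): a term is kept unless
    its member-set Jaccard similarity with any kept term exceeds
    ``cutoff``.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must be in (0, 1]")
    ordered = sorted(results, key=lambda r: (r.adj_p, r.p_value, r.name))
    kept: list[OverlapResult] = []
    kept_members: list[set[str]] = []
    for r in ordered:
        members = set(member_map.get(r.name, ()))
        redundant = False
        for km in kept_members:
            union = len(members | km)
            if union and len(members & km) / union > cutoff:
                redundant = True
                break
        if not redundant:
            kept.append(r)
            kept_members.append(members)
    return kept


def results_frame(results: list[OverlapResult]) -> pd.DataFrame:
    """Tabulate a list of OverlapResults."""
    return pd.DataFrame(
        {
            "name": [r.name for r in results],
            "overlap": [r.a for r in results],
            "query_only": [r.b for r in results],
            "set_only": [r.c for r in results],
            "rest": [r.d for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "p_value": [r.p_value for r in results],
            "adj_p": [r.adj_p for r in results],
        }
    ).set_index("name")
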