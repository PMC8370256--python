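"""Over-representation analysis of protein lists against term sets.

One-sided hypergeometric tests: for a query of ``n`` proteins drawn
from a universe of ``N``, a term annotating ``K`` universe proteins and
hitting ``k`` of the query has p = P[X >= k], X ~ Hypergeometric(N, K, n).
P-values are corrected across all tested terms with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's over-representation statistics."""

    term: str
    k: int  # hits in query
    K: int  # term size within the universe
    n: int  # query size
    N: int  # universe size
    p: float
    q: float

    def __post_init__(self) -> None:
        if not self.k <= min(self.K, self.n):
            raise ValueError("hit count cannot exceed term or query size")


def hypergeom_ora(
    query: Iterable[str],
    term_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` in each term set.

    The query must be a subset of the universe; term members outside the
    universe are ignored.  Terms with no universe members are dropped.
    Results are sorted by (q, p, term).
    """
    universe_set = set(universe)
    query_set = set(query)
    if not universe_set:
        raise ValueError("universe is empty")
    if not query_set:
        raise ValueError("query is empty")
    if not query_set <= universe_set:
        extra = sorted(query_set - universe_set)[:5]
        raise ValueError(f"query proteins outside the universe, e.g. {extra}")

    N, n = len(universe_set), len(query_set)
    rows: list[tuple[str, int, int, float]] = []
    for term, members in term_sets.items():
        member_set = set(members) & universe_set
        K = len(member_set)
        if K == 0:
            continue
        k = len(member_set & query_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, min(p, 1.0)))
    if not rows:
        return []
    _, q_values, _, _ = multipletests([p for *_, p in rows], method="fdr_bh")
    results = [
        EnrichmentResult(term=term, k=k, K=K, n=n, N=N, p=p, q=float(q))
        for (term, k, K, p), q in zip(rows, q_values)
    ]
    results.sort(key=lambda r: (r.q, r.p, r.term))
    return results
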