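"""Semantic query expansion over the concept graph.

Each query term contributes its graph neighborhood within ``k`` hops as
expansion candidates.  Candidates are ranked globally — tier 1
(REDIRECT/CODE, near-synonyms) before tier 2 (CATEGORY/ARTICLE, topical
relatives), then smaller distance, then larger first-hop weight, then
lexicographic — and the top ``cap`` are appended to the query with
tier-dependent boosts.  Terms the negation detector excluded are never
added back.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

from .graph import ConceptGraph, neighbors_within
from .textproc import QueryProfile

__all__ = ["Origin", "ExpansionParams", "WeightedQuery", "expand_query",
           "render_query"]

logger = logging.getLogger(__name__)


class Origin(enum.Enum):
    ORIGINAL = 0
    EXPANSION_T1 = 1
    EXPANSION_T2 = 2


@dataclass(frozen=True)
class ExpansionParams:
    """Knobs of the expansion step.

    ``cap`` bounds the number of *added* terms globally across the whole
    query, keeping the expanded query small.  Boosts weight original
    terms above tier-1 synonyms above tier-2 relatives.
    """

    k: int = 2
    cap: int = 20
    boost_original: float = 1.0
    boost_tier1: float = 0.6
    boost_tier2: float = 0.3

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.cap < 0:
            raise ValueError("cap must be >= 0")
        if not (0 < self.boost_tier2 <= self.boost_tier1
                <= self.boost_original):
            raise ValueError("boosts must satisfy 0 < tier2 <= tier1 <= original")


@dataclass
class WeightedQuery:
    """The expanded query Q': (term, weight, origin) entries, no duplicates."""

    entries: list[tuple[str, float, Origin]]

    def terms(self) -> set[str]:
        return {t for t, _, _ in self.entries}


def expand_query(q: QueryProfile, g: ConceptGraph,
                 params: ExpansionParams = ExpansionParams()) -> WeightedQuery:
    """Expand Q into the weighted query Q'.

    Original terms always survive with ``boost_original``.  Expansion
    candidates come from each term's ``k``-hop neighborhood; at most
    ``cap`` are added, best-ranked first, with the boost of their tier.
    A term reachable from several query terms counts once, under its
    best rank.  Terms not present in the graph contribute no candidates.
    """
    entries: list[tuple[str, float, Origin]] = [
        (t, params.boost_original, Origin.ORIGINAL) for t in sorted(q.terms)
    ]
    originals = set(q.terms)
    # candidate -> best (tier, distance, -weight, term) rank key
    ranks: dict[str, tuple[int, int, float, str]] = {}
    for term in sorted(originals):
        if term not in g:
            logger.debug("query term %r not in graph; no expansion", term)
            continue
        for nb in neighbors_within(g, term, params.k):
            if nb.term in originals or nb.term in q.excluded:
                continue
            key = (nb.tier, nb.distance, -nb.weight, nb.term)
            if nb.term not in ranks or key < ranks[nb.term]:
                ranks[nb.term] = key
    chosen = sorted(ranks.values())[:params.cap]
    for tier, _dist, _negw, term in chosen:
        boost = params.boost_tier1 if tier == 1 else params.boost_tier2
        origin = Origin.EXPANSION_T1 if tier == 1 else Origin.EXPANSION_T2
        entries.append((term, boost, origin))
    return WeightedQuery(entries=entries)


def render_query(wq: WeightedQuery) -> str:
    """Serialize Q' as a boosted query expression.

    Terms are sorted by (origin, weight descending, lexicographic);
    multi-word phrases are quoted; boosts attach as ``^weight``.
    """
    ordered = sorted(wq.entries, key=lambda e: (e[2].value, -e[1], e[0]))
    parts = []
    for term, weight, _ in ordered:
        quoted = f'"{term}"' if " " in term else term
        parts.append(f"{quoted}^{float(weight)}")
    return " ".join(parts)
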