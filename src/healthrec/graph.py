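"""Typed, weighted, directed health-concept graph.

The graph serves two roles in the recommender: it is the controlled
vocabulary against which free-text mentions are resolved, and it is the
substrate for semantic query expansion.  Nodes are case-folded term
labels (single words, multi-word phrases, classification codes); edges
carry one of four types:

* ``REDIRECT`` — synonym / abbreviation link (e.g. ``nstemi`` ->
  ``myocardial infarction``),
* ``CODE`` — classification-code link (e.g. ``i21`` ->
  ``myocardial infarction``),
* ``CATEGORY`` — membership in a topical category,
* ``ARTICLE`` — hyperlink-style relatedness between concept articles.

``REDIRECT`` and ``CODE`` form expansion tier 1 (near-synonymy);
``CATEGORY`` and ``ARTICLE`` form tier 2 (topical relatedness).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx

__all__ = [
    "EdgeType",
    "ConceptGraph",
    "Neighbor",
    "GraphFormatError",
    "load_graph",
    "write_graph",
    "neighbors_within",
    "vocabulary",
]


class EdgeType(enum.Enum):
    """The four admissible edge types of the concept graph."""

    CATEGORY = "CATEGORY"
    ARTICLE = "ARTICLE"
    CODE = "CODE"
    REDIRECT = "REDIRECT"

    @property
    def tier(self) -> int:
        """Expansion tier: 1 for REDIRECT/CODE, 2 for CATEGORY/ARTICLE."""
        return 1 if self in (EdgeType.REDIRECT, EdgeType.CODE) else 2


class GraphFormatError(ValueError):
    """Raised when a graph file or edge violates the format contract."""


def _canon(label: str) -> str:
    """Case-fold and whitespace-normalize a node label."""
    return " ".join(label.casefold().split())


class ConceptGraph:
    """Directed, weighted, typed term graph.

    Backed by a :class:`networkx.MultiDiGraph` keyed by edge type, so a
    pair of terms may be linked by edges of different types.  Duplicate
    edges (same source, target and type) are collapsed keeping the
    maximum weight.
    """

    def __init__(self) -> None:
        self._g = nx.MultiDiGraph()

    # -- construction -------------------------------------------------

    def add_node(self, label: str) -> str:
        label = _canon(label)
        if not label:
            raise GraphFormatError("empty node label")
        self._g.add_node(label)
        return label

    def add_edge(self, source: str, target: str, edge_type: EdgeType | str,
                 weight: float = 1.0) -> None:
        if isinstance(edge_type, str):
            try:
                edge_type = EdgeType(edge_type)
            except ValueError:
                raise GraphFormatError(f"unknown edge type: {edge_type!r}")
        if weight <= 0:
            raise GraphFormatError(f"edge weight must be > 0, got {weight}")
        source = self.add_node(source)
        target = self.add_node(target)
        if source == target:
            raise GraphFormatError(f"self-loop on {source!r}")
        key = edge_type.value
        if self._g.has_edge(source, target, key=key):
            old = self._g[source][target][key]["weight"]
            weight = max(old, weight)
        self._g.add_edge(source, target, key=key,
                         edge_type=edge_type, weight=weight)

    # -- inspection ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, label: str) -> bool:
        return _canon(label) in self._g

    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    def edges(self) -> list[tuple[str, str, EdgeType, float]]:
        return sorted(
            (u, v, d["edge_type"], d["weight"])
            for u, v, d in self._g.edges(data=True)
        )

    def incident(self, label: str) -> Iterable[tuple[str, EdgeType, float]]:
        """Edges touching ``label`` in either direction: (other, type, weight).

        Traversal is direction-blind: a REDIRECT from an abbreviation to
        its concept must make each endpoint reachable from the other.
        """
        label = _canon(label)
        if label not in self._g:
            return
        for _, v, d in self._g.out_edges(label, data=True):
            yield v, d["edge_type"], d["weight"]
        for u, _, d in self._g.in_edges(label, data=True):
            yield u, d["edge_type"], d["weight"]


@dataclass(frozen=True)
class Neighbor:
    """A node reachable from a query term during expansion.

    ``distance`` is the minimal hop count (direction-blind).  ``tier``
    is the worst edge tier along the best minimal path: a candidate is
    synonymy-grade (tier 1) only if every hop is a REDIRECT or CODE
    edge; any CATEGORY/ARTICLE hop makes the relation topical (tier 2).
    ``weight`` is the first-hop weight of that path; among minimal
    paths, lower tier wins, then larger first-hop weight.
    """

    term: str
    distance: int
    tier: int
    weight: float


def load_graph(path: str | Path) -> ConceptGraph:
    """Read a graph from TSV: ``source<TAB>target<TAB>edge_type<TAB>weight``.

    Lines starting with ``#`` and blank lines are ignored.  Labels are
    case-folded; duplicate edges keep the maximum weight.

    Raises
    ------
    GraphFormatError
        On a malformed line (naming the line number), unknown edge type,
        or non-positive weight.
    """
    g = ConceptGraph()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, "
                    f"got {len(fields)}")
            source, target, etype, weight_s = fields
            try:
                weight = float(weight_s)
            except ValueError:
                raise GraphFormatError(
                    f"{path}:{lineno}: weight is not a number: {weight_s!r}")
            try:
                g.add_edge(source, target, etype, weight)
            except GraphFormatError as exc:
                raise GraphFormatError(f"{path}:{lineno}: {exc}") from exc
    return g


def write_graph(g: ConceptGraph, path: str | Path) -> None:
    """Write the canonical TSV form (edges sorted; isolated nodes as comments)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# source\ttarget\tedge_type\tweight\n")
        linked: set[str] = set()
        for u, v, etype, w in g.edges():
            fh.write(f"{u}\t{v}\t{etype.value}\t{w:g}\n")
            linked.update((u, v))
        for node in sorted(g.nodes() - linked):
            fh.write(f"# node\t{node}\n")


def neighbors_within(g: ConceptGraph, term: str, k: int) -> list[Neighbor]:
    """All nodes within ``k`` hops of ``term`` (either edge direction).

    Returns one :class:`Neighbor` per reachable node (excluding ``term``
    itself) with its minimal hop distance, path tier and first-hop
    weight (see :class:`Neighbor`).  An unknown term yields an empty
    list.  Results are sorted by (distance, tier, -weight, term) for
    determinism.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    term = _canon(term)
    if term not in g:
        return []
    # Layered BFS; the (tier, -weight) key propagates along shortest
    # paths — tier degrades to 2 at the first topical hop — keeping the
    # best (smallest) key per node.
    dist: dict[str, int] = {term: 0}
    best: dict[str, tuple[int, float]] = {}
    frontier = [term]
    for depth in range(1, k + 1):
        nxt: list[str] = []
        for node in frontier:
            for other, etype, w in g.incident(node):
                if depth == 1:
                    key = (etype.tier, -w)
                else:
                    ptier, pweight = best[node]
                    key = (max(ptier, etype.tier), pweight)
                if other not in dist:
                    dist[other] = depth
                    best[other] = key
                    nxt.append(other)
                elif dist[other] == depth and key < best[other]:
                    best[other] = key
        frontier = nxt
        if not frontier:
            break
    out = [
        Neighbor(term=t, distance=d, tier=best[t][0], weight=-best[t][1])
        for t, d in dist.items() if d >= 1
    ]
    out.sort(key=lambda nb: (nb.distance, nb.tier, -nb.weight, nb.term))
    return out


def vocabulary(g: ConceptGraph) -> set[str]:
    """All node labels — the controlled vocabulary for term resolution."""
    return g.nodes()
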