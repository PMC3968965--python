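"""Vector-space retrieval of health information artifacts.

Classic tf-idf / cosine ranking over an inverted index: term weight
``(1 + ln tf) * ln(N / df)``, document vectors L2-normalized, a query is
a bag of boosted terms.  Two front ends share the index:

* :func:`recommend_naive` — plain retrieval on the raw query tokens
  (the baseline: no negation removal, no spell correction, no
  expansion),
* :func:`recommend_advanced` — the full pipeline: query cleaning,
  graph-based expansion, then retrieval.

Scores within a ranking are normalized by the maximum raw score so the
top entry is 1.0; scores from different pipelines are never compared
numerically — only the retrieved sets and ranks are.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .expansion import ExpansionParams, Origin, WeightedQuery, expand_query
from .graph import ConceptGraph
from .textproc import (NegationPattern, QueryProfile, SpellThresholds,
                       build_query, tokenize)

__all__ = ["Audience", "Artifact", "InvertedIndex", "RankedResult",
           "build_index", "score", "search_topk", "recommend_naive",
           "recommend_advanced", "load_corpus", "save_corpus",
           "save_index", "load_index"]


class Audience(enum.Enum):
    LAYMEN = "LAYMEN"
    EXPERT = "EXPERT"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class Artifact:
    """A recommendable health information artifact (item of the set R)."""

    id: str
    title: str
    body: str
    audience: Audience = Audience.UNKNOWN


@dataclass
class InvertedIndex:
    """Term -> postings with precomputed idf inputs and document norms."""

    postings: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    n_docs: int = 0
    doc_norms: dict[str, float] = field(default_factory=dict)
    title_boost: int = 2

    @property
    def doc_freq(self) -> dict[str, int]:
        return {t: len(p) for t, p in self.postings.items()}

    def idf(self, term: str) -> float:
        df = len(self.postings.get(term, ()))
        if df == 0:
            return 0.0
        return math.log(self.n_docs / df)

    def doc_ids(self) -> set[str]:
        return set(self.doc_norms)


@dataclass
class RankedResult:
    """Ranked recommendations S: (artifact id, raw score, normalized score).

    Ordered by non-increasing score, ties broken by artifact id; the top
    entry of a non-empty result has normalized score 1.0.
    """

    entries: list[tuple[str, float, float]] = field(default_factory=list)

    def ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __bool__(self) -> bool:
        return bool(self.entries)


def _doc_term_counts(a: Artifact, title_boost: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for tok in tokenize(a.title).words():
        counts[tok] = counts.get(tok, 0) + title_boost
    for tok in tokenize(a.body).words():
        counts[tok] = counts.get(tok, 0) + 1
    return counts


def build_index(corpus: list[Artifact], title_boost: int = 2) -> InvertedIndex:
    """Index a corpus: tf per document, idf = ln(N/df), norms precomputed.

    Title tokens count ``title_boost`` times (set 1 to disable).  A term
    appearing in every document has idf 0 and cannot contribute to any
    score.  Raises on duplicate artifact ids.
    """
    seen: set[str] = set()
    idx = InvertedIndex(title_boost=title_boost)
    for a in corpus:
        if a.id in seen:
            raise ValueError(f"duplicate artifact id: {a.id!r}")
        seen.add(a.id)
        for term, tf in sorted(_doc_term_counts(a, title_boost).items()):
            idx.postings.setdefault(term, []).append((a.id, tf))
    idx.n_docs = len(corpus)
    # document norms under (1 + ln tf) * idf weights
    sq: dict[str, float] = {a.id: 0.0 for a in corpus}
    for term, plist in idx.postings.items():
        w_idf = idx.idf(term)
        for doc_id, tf in plist:
            w = (1.0 + math.log(tf)) * w_idf
            sq[doc_id] += w * w
    idx.doc_norms = {d: math.sqrt(s) for d, s in sq.items()}
    return idx


def _query_vector(wq: WeightedQuery, idx: InvertedIndex) -> dict[str, float]:
    """Boosted query tf-idf vector; phrase entries contribute each token."""
    weights: dict[str, float] = {}
    for term, boost, _origin in wq.entries:
        for tok in term.split():
            weights[tok] = weights.get(tok, 0.0) + boost
    return {t: b * idx.idf(t) for t, b in weights.items() if idx.idf(t) > 0}


def score(wq: WeightedQuery, artifact_id: str, idx: InvertedIndex) -> float:
    """Cosine similarity between the boosted query and one document.

    0 exactly when the query and the document share no informative term.
    """
    if artifact_id not in idx.doc_norms:
        raise KeyError(f"unknown artifact id: {artifact_id!r}")
    qv = _query_vector(wq, idx)
    if not qv:
        return 0.0
    qnorm = math.sqrt(sum(w * w for w in qv.values()))
    dnorm = idx.doc_norms[artifact_id]
    if qnorm == 0.0 or dnorm == 0.0:
        return 0.0
    dot = 0.0
    for term, qw in qv.items():
        for doc_id, tf in idx.postings.get(term, ()):
            if doc_id == artifact_id:
                dot += qw * (1.0 + math.log(tf)) * idx.idf(term)
                break
    return dot / (qnorm * dnorm)


def search_topk(wq: WeightedQuery, idx: InvertedIndex, topk: int
                ) -> RankedResult:
    """Rank all documents with positive similarity; keep the best ``topk``.

    Normalized scores divide by the maximum raw score, so a non-empty
    result's first entry is exactly 1.0.
    """
    if topk < 1:
        raise ValueError("topk must be >= 1")
    qv = _query_vector(wq, idx)
    if not qv:
        return RankedResult()
    qnorm = math.sqrt(sum(w * w for w in qv.values()))
    dots: dict[str, float] = {}
    for term, qw in qv.items():
        w_idf = idx.idf(term)
        for doc_id, tf in idx.postings[term]:
            dots[doc_id] = dots.get(doc_id, 0.0) + qw * (1.0 + math.log(tf)) * w_idf
    scored = []
    for doc_id, dot in dots.items():
        dnorm = idx.doc_norms[doc_id]
        if dnorm > 0.0 and dot > 0.0:
            scored.append((doc_id, dot / (qnorm * dnorm)))
    scored.sort(key=lambda e: (-e[1], e[0]))
    scored = scored[:topk]
    if not scored:
        return RankedResult()
    top = scored[0][1]
    return RankedResult([(d, s, s / top) for d, s in scored])


def recommend_naive(text: str, idx: InvertedIndex, topk: int = 10
                    ) -> RankedResult:
    """Baseline retrieval: every raw token is a query term with weight 1.

    No negation removal, no spell correction, no expansion — the plain
    vector-space model the advanced pipeline is compared against.
    """
    tokens = sorted(set(tokenize(text).words()))
    wq = WeightedQuery([(t, 1.0, Origin.ORIGINAL) for t in tokens])
    return search_topk(wq, idx, topk) if tokens else RankedResult()


def recommend_advanced(text: str, g: ConceptGraph, idx: InvertedIndex,
                       params: ExpansionParams = ExpansionParams(),
                       topk: int = 10,
                       patterns: list[NegationPattern] | None = None,
                       thresholds: SpellThresholds = SpellThresholds(),
                       stopwords: set[str] | None = None) -> RankedResult:
    """Full pipeline: clean query, expand over the graph, rank."""
    q: QueryProfile = build_query(text, g, patterns=patterns,
                                  thresholds=thresholds, stopwords=stopwords)
    wq = expand_query(q, g, params)
    if not wq.entries:
        return RankedResult()
    return search_topk(wq, idx, topk)


# ----------------------------------------------------------------------
# corpus and index persistence


def load_corpus(path: str | Path) -> list[Artifact]:
    """Read a JSONL corpus: one object per line with id/title/body/audience."""
    corpus = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                corpus.append(Artifact(
                    id=str(obj["id"]), title=obj.get("title", ""),
                    body=obj["body"],
                    audience=Audience(obj.get("audience", "UNKNOWN"))))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: bad artifact record: {exc}")
    return corpus


def save_corpus(corpus: list[Artifact], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a in corpus:
            fh.write(json.dumps({"id": a.id, "title": a.title, "body": a.body,
                                 "audience": a.audience.value},
                                ensure_ascii=False) + "\n")


def save_index(idx: InvertedIndex, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload = {
        "n_docs": idx.n_docs,
        "title_boost": idx.title_boost,
        "postings": {t: p for t, p in sorted(idx.postings.items())},
        "doc_norms": dict(sorted(idx.doc_norms.items())),
    }
    (directory / "index.json").write_text(
        json.dumps(payload, ensure_ascii=False), encoding="utf-8")


def load_index(directory: str | Path) -> InvertedIndex:
    payload = json.loads(
        (Path(directory) / "index.json").read_text(encoding="utf-8"))
    return InvertedIndex(
        postings={t: [(d, tf) for d, tf in p]
                  for t, p in payload["postings"].items()},
        n_docs=payload["n_docs"],
        doc_norms=payload["doc_norms"],
        title_boost=payload["title_boost"])
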