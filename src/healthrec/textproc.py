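"""Linguistic query processing: tokenization, negation removal, fuzzy matching.

Turns raw personal-health-record text (discharge-letter fragments with
abbreviations, codes, misspellings and negations) into a clean query
term multiset Q whose members are terms of the concept-graph
vocabulary.  The steps are:

1. tokenize and record sentence boundaries,
2. resolve token spans against the vocabulary — longest phrase first,
   with Levenshtein / bigram-Jaccard spell correction for unknown
   tokens,
3. detect negation triggers ("no signs of", "in the absence of", ...)
   and remove every vocabulary term mentioned inside a trigger scope.

The trigger inventory is data, not code (a TSV shipped with the
package), so a deployment can localize it without touching the
implementation.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .graph import ConceptGraph, vocabulary

__all__ = [
    "Token",
    "TokenizedText",
    "NegationPattern",
    "QueryProfile",
    "SpellThresholds",
    "tokenize",
    "default_negation_patterns",
    "default_stopwords",
    "load_negation_patterns",
    "load_stopwords",
    "detect_negations",
    "levenshtein",
    "ngram_jaccard",
    "correct_term",
    "build_query",
]

logger = logging.getLogger(__name__)

_WORD_RE = re.compile(r"[^\W_]+", re.UNICODE)
_SENT_BREAK = re.compile(r"[.!?\n]")


@dataclass(frozen=True)
class Token:
    text: str       # case-folded
    start: int      # character offset in the source text
    end: int
    sentence: int   # 0-based sentence index


@dataclass
class TokenizedText:
    tokens: list[Token]

    def words(self) -> list[str]:
        return [t.text for t in self.tokens]


@dataclass(frozen=True)
class NegationPattern:
    """A negation trigger phrase and the scope it negates.

    FORWARD triggers negate the tokens that follow them; BACKWARD
    triggers negate the tokens before them.  A scope never crosses a
    sentence boundary and is capped at ``max_scope`` tokens.
    """

    trigger: str
    direction: str = "FORWARD"   # FORWARD | BACKWARD
    max_scope: int = 6

    def __post_init__(self) -> None:
        if not self.trigger.strip():
            raise ValueError("empty negation trigger")
        if self.direction not in ("FORWARD", "BACKWARD"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.max_scope < 1:
            raise ValueError("max_scope must be >= 1")


@dataclass
class QueryProfile:
    """The cleaned query: term multiset Q plus the negation-excluded set."""

    terms: Counter = field(default_factory=Counter)
    excluded: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        assert not (set(self.terms) & self.excluded)


@dataclass(frozen=True)
class SpellThresholds:
    """Limits for fuzzy matching of out-of-vocabulary tokens.

    Tokens shorter than ``min_length`` are never corrected: short
    abbreviations (ECG, MI) would otherwise collide with unrelated
    vocabulary.  ``enabled=False`` disables correction entirely (the
    naive-baseline configuration).
    """

    max_edit: int = 2
    min_jaccard: float = 0.5
    min_length: int = 4
    enabled: bool = True


def tokenize(text: str) -> TokenizedText:
    """Case-folded word tokens with offsets and sentence indices.

    Words are maximal alphanumeric runs, so punctuation and slashes
    split ("I21/I22" -> i21, i22).  Sentences break at ``. ! ?`` and
    newlines.
    """
    breaks = [m.start() for m in _SENT_BREAK.finditer(text)]
    tokens: list[Token] = []
    for m in _WORD_RE.finditer(text):
        sent = sum(1 for b in breaks if b < m.start())
        tokens.append(Token(m.group().casefold(), m.start(), m.end(), sent))
    return TokenizedText(tokens)


# ----------------------------------------------------------------------
# shipped language resources


def _data_path(name: str):
    return resources.files("healthrec").joinpath("data", name)


def load_negation_patterns(path) -> list[NegationPattern]:
    """Read a trigger table: ``trigger<TAB>direction<TAB>max_scope``."""
    patterns = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            trigger, direction, scope = line.split("\t")
            patterns.append(NegationPattern(trigger.casefold(), direction,
                                            int(scope)))
    return patterns


def load_stopwords(path) -> set[str]:
    with open(path, encoding="utf-8") as fh:
        return {w.strip().casefold() for w in fh
                if w.strip() and not w.startswith("#")}


def default_negation_patterns() -> list[NegationPattern]:
    with resources.as_file(_data_path("negation_patterns.tsv")) as p:
        return load_negation_patterns(p)


def default_stopwords() -> set[str]:
    with resources.as_file(_data_path("stopwords_en.txt")) as p:
        return load_stopwords(p)


# ----------------------------------------------------------------------
# fuzzy string measures


def levenshtein(a: str, b: str) -> int:
    """Minimal number of single-character edits turning ``a`` into ``b``.

    Standard dynamic program, two-row formulation.
    """
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1,            # deletion
                           cur[j - 1] + 1,         # insertion
                           prev[j - 1] + (ca != cb)))  # substitution
        prev = cur
    return prev[-1]


def _ngrams(s: str, n: int) -> frozenset[str]:
    return frozenset(s[i:i + n] for i in range(len(s) - n + 1))


def ngram_jaccard(a: str, b: str, n: int = 2) -> float:
    """Jaccard index of the letter n-gram sets of ``a`` and ``b``.

    A string shorter than ``n`` has an empty n-gram set; two empty sets
    count as identical (J = 1), an empty set against a non-empty one as
    completely dissimilar (J = 0).
    """
    A, B = _ngrams(a, n), _ngrams(b, n)
    if not A and not B:
        return 1.0
    union = A | B
    return len(A & B) / len(union)


def correct_term(term: str, vocab: set[str], max_edit: int = 2,
                 min_jaccard: float = 0.5) -> str | None:
    """Resolve a possibly misspelled token against the vocabulary.

    Exact match short-circuits.  Otherwise the vocabulary term with the
    smallest Levenshtein distance wins, provided the distance is at most
    ``max_edit``; failing that, the term with the largest bigram Jaccard
    wins, provided it reaches ``min_jaccard``.  Ties break by higher
    Jaccard, then lexicographically.  Returns ``None`` if nothing
    qualifies.
    """
    if term in vocab:
        return term
    best_edit: tuple[int, float, str] | None = None
    best_jac: tuple[float, str] | None = None
    for cand in vocab:
        d = levenshtein(term, cand)
        j = ngram_jaccard(term, cand, 2)
        if d <= max_edit:
            key = (d, -j, cand)
            if best_edit is None or key < best_edit:
                best_edit = key
        if j >= min_jaccard:
            key2 = (-j, cand)
            if best_jac is None or key2 < best_jac:
                best_jac = key2
    if best_edit is not None:
        return best_edit[2]
    if best_jac is not None:
        return best_jac[1]
    return None


# ----------------------------------------------------------------------
# negation detection


def _match_triggers(tokens: list[Token], patterns: list[NegationPattern]
                    ) -> list[tuple[int, int, NegationPattern]]:
    """Trigger occurrences as (start index, end index) over the token list.

    At each position the longest matching trigger wins; overlapping
    shorter triggers inside it are suppressed.
    """
    trig = sorted(patterns, key=lambda p: -len(p.trigger.split()))
    words = [t.text for t in tokens]
    hits: list[tuple[int, int, NegationPattern]] = []
    i = 0
    while i < len(words):
        matched = None
        for p in trig:
            tw = p.trigger.split()
            if (words[i:i + len(tw)] == tw
                    and all(tokens[i + d].sentence == tokens[i].sentence
                            for d in range(len(tw)))):
                matched = (i, i + len(tw), p)
                break
        if matched:
            hits.append(matched)
            i = matched[1]
        else:
            i += 1
    return hits


def _scope_indices(tokens: list[Token], start: int, end: int,
                   p: NegationPattern) -> range:
    """Token index range negated by a trigger spanning [start, end)."""
    sent = tokens[start].sentence
    if p.direction == "FORWARD":
        stop = end
        while (stop < len(tokens) and stop < end + p.max_scope
               and tokens[stop].sentence == sent):
            stop += 1
        return range(end, stop)
    first = start
    while (first > 0 and start - first < p.max_scope
           and tokens[first - 1].sentence == sent):
        first -= 1
    return range(first, start)


def _vocab_phrase_index(vocab: set[str]) -> tuple[dict[tuple[str, ...], str], int]:
    phrases = {tuple(v.split()): v for v in vocab}
    max_len = max((len(k) for k in phrases), default=1)
    return phrases, max_len


def detect_negations(text: str, patterns: list[NegationPattern] | None = None,
                     vocab: set[str] | frozenset[str] = frozenset()
                     ) -> set[str]:
    """Vocabulary terms mentioned only inside a negation scope.

    A scope runs from a trigger to the sentence boundary, capped at the
    trigger's ``max_scope`` tokens; the longest vocabulary phrase match
    inside the scope wins.  Terms mentioned outside every scope are not
    reported (they remain legitimate query terms).
    """
    if patterns is None:
        patterns = default_negation_patterns()
    toks = tokenize(text).tokens
    if not toks:
        return set()
    phrases, max_len = _vocab_phrase_index(set(vocab))
    negated_idx: set[int] = set()
    for start, end, p in _match_triggers(toks, patterns):
        negated_idx.update(_scope_indices(toks, start, end, p))
    found: set[str] = set()
    i = 0
    while i < len(toks):
        for ln in range(min(max_len, len(toks) - i), 0, -1):
            key = tuple(t.text for t in toks[i:i + ln])
            if key in phrases:
                if any(ix in negated_idx for ix in range(i, i + ln)):
                    found.add(phrases[key])
                i += ln
                break
        else:
            i += 1
    return found


# ----------------------------------------------------------------------
# query construction


def build_query(text: str, g: ConceptGraph,
                patterns: list[NegationPattern] | None = None,
                thresholds: SpellThresholds = SpellThresholds(),
                stopwords: set[str] | None = None) -> QueryProfile:
    """Turn PHR text into the query term multiset Q.

    Token spans are matched against the graph vocabulary longest-phrase
    first; unknown tokens go through spell correction; terms whose
    mention lies inside a negation scope are removed from Q entirely
    (all occurrences) and reported in ``excluded``.  Non-vocabulary
    leftovers are dropped.
    """
    if patterns is None:
        patterns = default_negation_patterns()
    if stopwords is None:
        stopwords = default_stopwords()
    vocab = vocabulary(g)
    toks = tokenize(text).tokens
    phrases, max_len = _vocab_phrase_index(vocab)

    negated_idx: set[int] = set()
    for start, end, p in _match_triggers(toks, patterns):
        negated_idx.update(_scope_indices(toks, start, end, p))

    terms: Counter = Counter()
    excluded: set[str] = set()
    i = 0
    while i < len(toks):
        resolved = None
        span = 1
        for ln in range(min(max_len, len(toks) - i), 0, -1):
            key = tuple(t.text for t in toks[i:i + ln])
            if key in phrases:
                resolved, span = phrases[key], ln
                break
        if resolved is None:
            word = toks[i].text
            if (thresholds.enabled and word not in stopwords
                    and len(word) >= thresholds.min_length):
                resolved = correct_term(word, vocab, thresholds.max_edit,
                                        thresholds.min_jaccard)
        if resolved is not None:
            if any(ix in negated_idx for ix in range(i, i + span)):
                excluded.add(resolved)
            else:
                terms[resolved] += 1
        i += span

    for t in excluded:
        terms.pop(t, None)
    if not terms and text.strip():
        logger.warning("query text yielded no vocabulary terms: %.60r", text)
    return QueryProfile(terms=terms, excluded=excluded)
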