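"""Seeded synthetic fixtures: concept graphs, corpora, cases, gold standards.

No public corpus of discharge letters, laymen health articles and a
matching concept graph exists, so the package generates its own — small,
structured like the real inputs, and fully determined by a seed:

* a concept graph where every concept has a canonical laymen term,
  abbreviation-like REDIRECT synonyms, optionally an ICD-10-style CODE
  node, ARTICLE links between related concepts and a CATEGORY tree;
* a corpus in which laymen articles use only canonical terms plus a
  laymen filler vocabulary, while expert documents use abbreviations,
  codes and a disjoint expert filler vocabulary — so laymen articles
  never contain an abbreviation or code (the property that defeats
  naive term matching);
* query cases that mention their target concepts as abbreviation, code,
  misspelled or canonical term, optionally with a negated decoy; the
  gold standard is the laymen articles of the non-negated targets,
  recorded for two simulated judges.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .graph import ConceptGraph, write_graph
from .retrieval import Artifact, Audience, save_corpus
from .stats import GoldStandard, save_gold_standard

__all__ = ["FixtureSpec", "ConceptInfo", "Benchmark", "generate_graph",
           "generate_corpus", "generate_cases", "generate_benchmark",
           "write_fixture_dir"]

_LAYMEN_SYLLABLES = ["ba", "do", "fe", "gu", "hi", "la", "me", "no", "pa",
                     "re", "si", "tu", "ve", "wo", "ya", "zo", "ca", "di"]
_ABBR_LETTERS = "bcdfghklmnprstvz"
_FILLER_LETTERS = "jqwxz"


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and noise parameters of one synthetic study world.

    The rates mirror the phenomena observed in clinical free text:
    physicians' abbreviations, classification codes, typos, and negated
    findings.  Defaults are the benchmark conditions used throughout
    the test suite.
    """

    seed: int = 11
    n_concepts: int = 30
    synonyms_per_concept: int = 1
    codes_per_concept: int = 1
    category_depth: int = 2
    n_laymen_docs: int = 60
    n_expert_docs: int = 30
    n_cases: int = 60
    misspelling_rate: float = 0.2
    negation_rate: float = 0.3
    abbreviation_rate: float = 0.5
    code_rate: float = 0.15
    phrase_rate: float = 0.2

    def __post_init__(self) -> None:
        for name in ("n_concepts", "synonyms_per_concept", "codes_per_concept",
                     "category_depth", "n_laymen_docs", "n_expert_docs",
                     "n_cases"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.codes_per_concept not in (0, 1):
            raise ValueError("codes_per_concept must be 0 or 1")
        for name in ("misspelling_rate", "negation_rate", "abbreviation_rate",
                     "code_rate", "phrase_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class ConceptInfo:
    """Ground truth for one generated concept."""

    canonical: str
    synonyms: list[str]
    code: str | None
    category: str
    laymen_docs: list[str] = field(default_factory=list)
    expert_docs: list[str] = field(default_factory=list)


@dataclass
class Benchmark:
    """One complete synthetic world: graph, ledger, corpus, cases, gold."""

    spec: FixtureSpec
    graph: ConceptGraph
    ledger: dict[int, ConceptInfo]
    corpus: list[Artifact]
    cases: list[tuple[str, str]]
    gold: GoldStandard


def _make_word(rng: random.Random, n_syll: int, taken: set[str]) -> str:
    while True:
        w = "".join(rng.choice(_LAYMEN_SYLLABLES) for _ in range(n_syll))
        if w not in taken:
            taken.add(w)
            return w


def _make_abbr(rng: random.Random, taken: set[str]) -> str:
    while True:
        w = "".join(rng.choice(_ABBR_LETTERS)
                    for _ in range(rng.randint(3, 5)))
        if w not in taken:
            taken.add(w)
            return w


def _make_code(rng: random.Random, taken: set[str]) -> str:
    while True:
        w = rng.choice("eijk") + f"{rng.randint(10, 99)}"
        if w not in taken:
            taken.add(w)
            return w


def _make_filler(rng: random.Random, taken: set[str]) -> str:
    # long words from a disjoint alphabet: never within spell-correction
    # reach of a vocabulary term
    while True:
        w = "".join(rng.choice(_FILLER_LETTERS)
                    for _ in range(rng.randint(10, 12)))
        if w not in taken:
            taken.add(w)
            return w


def generate_graph(spec: FixtureSpec
                   ) -> tuple[ConceptGraph, dict[int, ConceptInfo]]:
    """Build the synthetic concept graph and its ground-truth ledger.

    Node count is ``n_concepts * (1 + synonyms + codes) + category_depth``;
    edges are one REDIRECT per synonym, one CODE per code, one CATEGORY
    per concept (depth permitting), a CATEGORY chain between categories,
    and an ARTICLE chain linking consecutive concepts.
    """
    rng = random.Random(spec.seed)
    taken: set[str] = set()
    g = ConceptGraph()
    ledger: dict[int, ConceptInfo] = {}

    categories = [f"category {_make_word(rng, 3, taken)}"
                  for _ in range(spec.category_depth)]
    for c in categories:
        g.add_node(c)
    for child, parent in zip(categories, categories[1:]):
        g.add_edge(child, parent, "CATEGORY", 1.0)

    for i in range(spec.n_concepts):
        if rng.random() < spec.phrase_rate:
            canonical = (_make_word(rng, 3, taken) + " "
                         + _make_word(rng, 2, taken))
        else:
            canonical = _make_word(rng, 3, taken)
        g.add_node(canonical)
        syns = [_make_abbr(rng, taken)
                for _ in range(spec.synonyms_per_concept)]
        for s in syns:
            g.add_edge(s, canonical, "REDIRECT", 1.0)
        code = _make_code(rng, taken) if spec.codes_per_concept else None
        if code:
            g.add_edge(code, canonical, "CODE", 1.0)
        if categories:
            g.add_edge(canonical, rng.choice(categories), "CATEGORY", 1.0)
        ledger[i] = ConceptInfo(canonical=canonical, synonyms=syns,
                                code=code, category=categories[0]
                                if categories else "")
    for i in range(spec.n_concepts - 1):
        g.add_edge(ledger[i].canonical, ledger[i + 1].canonical,
                   "ARTICLE", 1.0)
    return g, ledger


def generate_corpus(g: ConceptGraph, ledger: dict[int, ConceptInfo],
                    spec: FixtureSpec) -> list[Artifact]:
    """Laymen and expert artifacts over the generated concepts.

    Laymen docs mention only their concept's canonical term plus laymen
    filler; expert docs mention the abbreviation and code plus expert
    filler from a disjoint alphabet.  Doc ids are recorded in the
    ledger.
    """
    rng = random.Random(spec.seed + 1)
    taken: set[str] = set()
    laymen_filler = [_make_filler(rng, taken) for _ in range(12)]
    expert_filler = [_make_filler(rng, taken) for _ in range(12)]
    corpus: list[Artifact] = []
    if not ledger:
        return corpus
    n_concepts = len(ledger)
    for d in range(spec.n_laymen_docs):
        info = ledger[d % n_concepts]
        doc_id = f"L{d:03d}"
        words = ([info.canonical] * rng.randint(2, 4)
                 + rng.choices(laymen_filler[:6], k=rng.randint(4, 8)))
        rng.shuffle(words)
        corpus.append(Artifact(id=doc_id, title=info.canonical,
                               body=" ".join(words) + ".",
                               audience=Audience.LAYMEN))
        info.laymen_docs.append(doc_id)
    for d in range(spec.n_expert_docs):
        info = ledger[d % n_concepts]
        doc_id = f"E{d:03d}"
        mentions = list(info.synonyms) or [info.canonical]
        if info.code:
            mentions.append(info.code)
        words = (mentions * rng.randint(2, 3)
                 + rng.choices(expert_filler[:6], k=rng.randint(4, 8)))
        rng.shuffle(words)
        corpus.append(Artifact(id=doc_id, title=mentions[0],
                               body=" ".join(words) + ".",
                               audience=Audience.EXPERT))
        info.expert_docs.append(doc_id)
    return corpus


def _misspell(rng: random.Random, word: str) -> str:
    """1-2 random character substitutions; words < 4 chars are left alone."""
    if len(word) < 4:
        return word
    chars = list(word)
    for pos in rng.sample(range(len(chars)), rng.randint(1, 2)):
        old = chars[pos]
        chars[pos] = rng.choice([c for c in "abcdefghijklmnopqrstuvwxyz"
                                 if c != old])
    return "".join(chars)


def _render_mention(rng: random.Random, info: ConceptInfo,
                    spec: FixtureSpec) -> str:
    r = rng.random()
    if info.synonyms and r < spec.abbreviation_rate:
        return rng.choice(info.synonyms)
    if info.code and r < spec.abbreviation_rate + spec.code_rate:
        return info.code
    canonical = info.canonical
    if rng.random() < spec.misspelling_rate:
        head, _, tail = canonical.partition(" ")
        head = _misspell(rng, head)
        return head + (" " + tail if tail else "")
    return canonical


def generate_cases(g: ConceptGraph, ledger: dict[int, ConceptInfo],
                   spec: FixtureSpec
                   ) -> tuple[list[tuple[str, str]], GoldStandard]:
    """Discharge-letter-style cases plus their derived gold standard.

    Each case targets 1-3 concepts, rendered per the spec rates; with
    probability ``negation_rate`` a decoy concept appears under a
    negation trigger and its artifacts are kept out of the gold set.
    Two simulated judges record identical selections (judge noise is a
    deliberate non-feature: the gold standard is defined by concept
    identity).
    """
    rng = random.Random(spec.seed + 2)
    cases: list[tuple[str, str]] = []
    gold = GoldStandard(j=2)
    if not ledger:
        return cases, gold
    ids = sorted(ledger)
    for c in range(spec.n_cases):
        case_id = f"c{c:03d}"
        n_targets = rng.randint(1, min(3, len(ids)))
        targets = rng.sample(ids, n_targets)
        sentences = []
        for t in targets:
            mention = _render_mention(rng, ledger[t], spec)
            sentences.append(rng.choice([
                f"diagnosis {mention}.",
                f"patient presents with {mention}.",
                f"laboratory results consistent with {mention}.",
            ]))
        if rng.random() < spec.negation_rate and len(ids) > n_targets:
            decoy = rng.choice([i for i in ids if i not in targets])
            sentences.append(rng.choice([
                f"no signs of {ledger[decoy].canonical}.",
                f"did not provide evidence of {ledger[decoy].canonical}.",
                f"in the absence of {ledger[decoy].canonical}.",
            ]))
        rng.shuffle(sentences)
        cases.append((case_id, " ".join(sentences)))
        relevant = sorted(doc for t in targets
                          for doc in ledger[t].laymen_docs)
        for judge in ("J1", "J2"):
            for doc in relevant:
                gold.add(case_id, judge, doc)
        if not relevant:
            gold.cases.setdefault(case_id, {"J1": set(), "J2": set()})
    return cases, gold


def generate_benchmark(spec: FixtureSpec = FixtureSpec()) -> Benchmark:
    """Generate the full synthetic world for one spec."""
    g, ledger = generate_graph(spec)
    corpus = generate_corpus(g, ledger, spec)
    cases, gold = generate_cases(g, ledger, spec)
    return Benchmark(spec=spec, graph=g, ledger=ledger, corpus=corpus,
                     cases=cases, gold=gold)


def write_fixture_dir(bench: Benchmark, directory: str | Path) -> None:
    """Write graph TSV, corpus JSONL, cases TSV, gold TSV and a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_graph(bench.graph, directory / "graph.tsv")
    save_corpus(bench.corpus, directory / "corpus.jsonl")
    with open(directory / "cases.tsv", "w", encoding="utf-8") as fh:
        fh.write("# case_id\ttext\n")
        for case_id, text in bench.cases:
            fh.write(f"{case_id}\t{text}\n")
    save_gold_standard(bench.gold, directory / "gold.tsv")
    (directory / "MANIFEST.json").write_text(
        json.dumps({"spec": asdict(bench.spec)}, indent=2), encoding="utf-8")
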