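"""tf-idf indexing, cosine scoring, ranking, and the two pipelines."""

import math
import random

import pytest

from healthrec.expansion import ExpansionParams, Origin, WeightedQuery
from healthrec.retrieval import (Artifact, Audience, build_index,
                                 load_corpus, recommend_advanced,
                                 recommend_naive, save_corpus, score,
                                 search_topk)
from healthrec.textproc import SpellThresholds


def _doc(i, body, title=""):
    return Artifact(id=f"d{i}", title=title, body=body)


def _wq(*terms):
    return WeightedQuery([(t, w, Origin.ORIGINAL) for t, w in terms])


# -- independent dense oracle -----------------------------------------------

def dense_scores(corpus, query_weights, title_boost=2):
    """Brute-force tf-idf cosine over dense dicts, no index involved."""
    import re

    def toks(s):
        return re.findall(r"[^\W_]+", s.casefold())

    counts = []
    for a in corpus:
        c = {}
        for t in toks(a.title):
            c[t] = c.get(t, 0) + title_boost
        for t in toks(a.body):
            c[t] = c.get(t, 0) + 1
        counts.append(c)
    n = len(corpus)
    df = {}
    for c in counts:
        for t in c:
            df[t] = df.get(t, 0) + 1
    idf = {t: math.log(n / d) for t, d in df.items()}
    qv = {}
    for term, boost in query_weights.items():
        for tok in term.split():
            qv[tok] = qv.get(tok, 0.0) + boost
    qv = {t: b * idf.get(t, 0.0) for t, b in qv.items()
          if idf.get(t, 0.0) > 0}
    qn = math.sqrt(sum(v * v for v in qv.values()))
    out = {}
    for a, c in zip(corpus, counts):
        dv = {t: (1 + math.log(tf)) * idf[t] for t, tf in c.items()}
        dn = math.sqrt(sum(v * v for v in dv.values()))
        dot = sum(qv.get(t, 0.0) * w for t, w in dv.items())
        out[a.id] = dot / (qn * dn) if qn > 0 and dn > 0 and dot > 0 else 0.0
    return out


def assert_ranking_matches_oracle(got_ids, expected, topk):
    """got_ids must equal the oracle ranking exactly, except that
    documents whose oracle scores coincide (to 1e-9) may appear in any
    order among themselves — summation order makes mathematically tied
    cosines differ in the last few ulps."""
    keys = {d: round(s, 9) for d, s in expected.items() if s > 0}
    ranked = sorted(keys, key=lambda d: (-keys[d], d))
    k = min(topk, len(ranked))
    assert len(got_ids) == k
    assert [keys[g] for g in got_ids] == [keys[d] for d in ranked[:k]]
    if k:
        kth = keys[ranked[k - 1]]
        strictly_better = {d for d in keys if keys[d] > kth}
        assert strictly_better <= set(got_ids)
        assert set(got_ids) <= {d for d in keys if keys[d] >= kth}


class TestBuildIndex:
    def test_term_frequencies_counted(self):
        idx = build_index([_doc(0, "heart heart attack")], title_boost=1)
        assert idx.postings["heart"] == [("d0", 2)]
        assert idx.postings["attack"] == [("d0", 1)]

    def test_shared_terms_have_zero_idf(self):
        idx = build_index([_doc(0, "a b"), _doc(1, "a b")])
        assert idx.idf("a") == 0.0
        assert score(_wq(("a", 1.0)), "d0", idx) == 0.0

    def test_duplicate_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_index([_doc(0, "x"), _doc(0, "y")])

    def test_empty_corpus(self):
        idx = build_index([])
        assert idx.n_docs == 0 and not idx.postings

    def test_title_tokens_boosted(self):
        idx = build_index([_doc(0, "body", title="heart")], title_boost=2)
        assert idx.postings["heart"] == [("d0", 2)]

    def test_postings_match_counting_oracle(self):
        rng = random.Random(3)
        vocab = [f"w{i}" for i in range(12)]
        corpus = [_doc(i, " ".join(rng.choices(vocab, k=rng.randint(3, 15))))
                  for i in range(20)]
        idx = build_index(corpus, title_boost=1)
        for term in vocab:
            expected = []
            for a in corpus:
                tf = a.body.split().count(term)
                if tf:
                    expected.append((a.id, tf))
            assert idx.postings.get(term, []) == expected


class TestScore:
    def test_disjoint_query_scores_zero(self):
        idx = build_index([_doc(0, "alpha beta"), _doc(1, "gamma delta")])
        assert score(_wq(("zeta", 1.0)), "d0", idx) == 0.0

    def test_unique_vocabulary_self_match_is_top(self):
        corpus = [_doc(0, "alpha beta"), _doc(1, "gamma delta"),
                  _doc(2, "epsilon zeta")]
        idx = build_index(corpus)
        wq = _wq(("gamma", 1.0), ("delta", 1.0))
        scores = {a.id: score(wq, a.id, idx) for a in corpus}
        assert max(scores, key=scores.get) == "d1"

    def test_unknown_artifact_raises(self):
        idx = build_index([_doc(0, "x y")])
        with pytest.raises(KeyError):
            score(_wq(("x", 1.0)), "nope", idx)

    def test_matches_dense_oracle(self):
        rng = random.Random(9)
        vocab = [f"t{i}" for i in range(10)]
        corpus = [_doc(i, " ".join(rng.choices(vocab, k=rng.randint(2, 9))))
                  for i in range(5)]
        idx = build_index(corpus)
        wq = _wq(("t0", 1.0), ("t3", 0.6), ("t7", 0.3))
        expected = dense_scores(corpus, {"t0": 1.0, "t3": 0.6, "t7": 0.3})
        for a in corpus:
            assert score(wq, a.id, idx) == pytest.approx(expected[a.id],
                                                         abs=1e-9)


class TestSearchTopk:
    def test_no_overlap_gives_empty_result(self):
        idx = build_index([_doc(0, "alpha"), _doc(1, "beta")])
        assert not search_topk(_wq(("gamma", 1.0)), idx, 5)

    def test_top_normalized_score_is_one(self):
        idx = build_index([_doc(0, "alpha beta"), _doc(1, "alpha")])
        res = search_topk(_wq(("alpha", 1.0), ("beta", 1.0)), idx, 5)
        assert res and res.entries[0][2] == 1.0

    def test_topk_truncates_to_argmax(self):
        rng = random.Random(1)
        vocab = [f"t{i}" for i in range(8)]
        corpus = [_doc(i, " ".join(rng.choices(vocab, k=6)))
                  for i in range(6)]
        idx = build_index(corpus)
        wq = _wq(("t1", 1.0))
        expected = dense_scores(corpus, {"t1": 1.0})
        res = search_topk(wq, idx, 1)
        assert len(res) == 1
        want = sorted((d for d, s in expected.items() if s > 0),
                      key=lambda d: (-expected[d], d))
        assert res.entries[0][0] == want[0]

    def test_normalized_scores_monotone_in_unit_interval(self,
                                                         benchmark_world):
        laymen = [a for a in benchmark_world.corpus
                  if a.audience == Audience.LAYMEN]
        idx = build_index(laymen)
        for _, text in benchmark_world.cases[:10]:
            res = recommend_naive(text, idx, 10)
            norms = [n for _, _, n in res.entries]
            assert all(0.0 <= n <= 1.0 for n in norms)
            assert norms == sorted(norms, reverse=True)

    def test_order_matches_brute_force_oracle(self):
        rng = random.Random(77)
        vocab = [f"v{i}" for i in range(15)]
        for _ in range(100):
            n = rng.randint(2, 30)
            corpus = [_doc(i, " ".join(rng.choices(vocab,
                                                   k=rng.randint(3, 12))))
                      for i in range(n)]
            idx = build_index(corpus)
            qterms = {t: 1.0 for t in rng.sample(vocab, rng.randint(1, 4))}
            wq = _wq(*qterms.items())
            expected = dense_scores(corpus, qterms)
            assert_ranking_matches_oracle(search_topk(wq, idx, 5).ids(),
                                          expected, 5)

    def test_zero_overlap_artifact_never_reorders_ranking(self):
        corpus = [_doc(0, "alpha beta"), _doc(1, "alpha gamma"),
                  _doc(2, "beta gamma")]
        wq = _wq(("alpha", 1.0), ("beta", 1.0))
        before = search_topk(wq, build_index(corpus), 10).ids()
        widened = corpus + [_doc(9, "omicron upsilon")]
        after = search_topk(wq, build_index(widened), 10).ids()
        assert after == before


class TestPipelines:
    def test_naive_misses_abbreviation(self, cardio_graph):
        corpus = [_doc(0, "myocardial infarction explained simply")]
        idx = build_index(corpus)
        assert not recommend_naive("nstemi", idx, 5)

    def test_advanced_resolves_abbreviation(self, cardio_graph):
        corpus = [_doc(0, "myocardial infarction explained simply"),
                  _doc(1, "sleep and snoring")]
        idx = build_index(corpus)
        res = recommend_advanced("nstemi", cardio_graph, idx, topk=5)
        assert "d0" in res.ids()

    def test_advanced_resolves_code(self, cardio_graph):
        corpus = [_doc(0, "myocardial infarction explained simply"),
                  _doc(1, "sleep and snoring")]
        idx = build_index(corpus)
        res = recommend_advanced("i21", cardio_graph, idx, topk=5)
        assert "d0" in res.ids()

    def test_negation_suppresses_concept(self, cardio_graph):
        corpus = [_doc(0, "stemi details"), _doc(1, "ecg basics")]
        idx = build_index(corpus)
        res = recommend_advanced("no signs of stemi. ecg was done",
                                 cardio_graph, idx, topk=5)
        assert "d0" not in res.ids()
        assert "d1" in res.ids()

    def test_naive_equals_advanced_with_features_disabled(self,
                                                          cardio_graph):
        corpus = [_doc(0, "ecg basics"), _doc(1, "stemi overview"),
                  _doc(2, "diabetes care"), _doc(3, "ecg stemi combined")]
        idx = build_index(corpus)
        text = "ecg stemi diabetes"
        naive = recommend_naive(text, idx, 10)
        advanced = recommend_advanced(
            text, cardio_graph, idx,
            ExpansionParams(cap=0), topk=10, patterns=[],
            thresholds=SpellThresholds(enabled=False))
        assert advanced.entries == naive.entries

    def test_empty_text_empty_result(self, cardio_graph):
        idx = build_index([_doc(0, "anything at all")])
        assert not recommend_advanced("", cardio_graph, idx, topk=5)


def test_corpus_jsonl_round_trip(tmp_path):
    corpus = [Artifact("a1", "Title", "Body text", Audience.LAYMEN),
              Artifact("a2", "", "Other", Audience.EXPERT)]
    p = tmp_path / "corpus.jsonl"
    save_corpus(corpus, p)
    assert load_corpus(p) == corpus
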