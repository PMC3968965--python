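# healthrec

Content-based recommendation of laymen-friendly health information from
personal-health-record (PHR) free text — and the statistical machinery
to evaluate such a recommender in a controlled study.

## The problem

Clinical free text (discharge letters, PHR data entries) is written in
professional language: abbreviations ("NSTEMI"), classification codes
("I21"), expert terms, typos, and negated findings ("no signs of
STEMI"). Plain keyword search over a corpus of patient-friendly health
articles fails on exactly these inputs — the article about myocardial
infarction never contains the token "NSTEMI", and a negated condition
should not drive recommendations at all. `healthrec` implements a
health recommender system (HRS) that closes this vocabulary gap:

1. **Negation removal** — trigger-based scope detection ("no signs of",
   "in the absence of", ...) removes denied conditions from the query
   multiset *Q*.
2. **Fuzzy vocabulary matching** — out-of-vocabulary tokens are
   resolved against the concept-graph vocabulary by Levenshtein
   distance, falling back to letter-bigram Jaccard similarity
   (J(A, B) = |A∩B| / |A∪B|).
3. **Semantic query expansion** — a typed, weighted, directed health
   concept graph *G* (edge types REDIRECT, CODE, CATEGORY, ARTICLE)
   supplies neighbors within *k* hops; synonym-grade candidates
   (REDIRECT/CODE paths) are preferred over topical ones
   (CATEGORY/ARTICLE), and at most `cap` expansion terms are added with
   tier-dependent boosts, yielding the weighted query *Q′*.
4. **Vector-space retrieval** — tf-idf weights (1 + ln tf)·ln(N/df)
   with cosine similarity sc(Q′, D) over an inverted index; results are
   ranked and normalized to [0, 1] (top item = 1.0).
5. **Laymen pre-filter** — a linear soft-margin SVM on tf-idf document
   vectors separates laymen-friendly from expert documents at indexing
   time.

The evaluation harness compares this advanced pipeline against a naive
vector-space baseline (raw tokens, no cleaning, no expansion) by mean
per-case retrieval precision

ρ = (1/|C|) Σᵢ |D_rel,cᵢ ∩ D_cᵢ| / |D_cᵢ| ,

tests H₀: ρ_H ≤ ρ_V against H_a: ρ_H > ρ_V with a one-sided dependent
t-test, and plans study size: for a standardized effect ω₀, α = 0.05
one-sided, power 0.8,

n_c = ⌈((z₀.₉₅ + z₀.₈)/ω₀)² + z₀.₉₅²/2⌉,  n_p = ⌈n_c · j / c_p⌉

(Guenther-corrected normal approximation; a noncentral-*t* iteration is
computed alongside as a cross-check). Because no public corpus pairs
discharge-letter cases with a concept graph and laymen articles, the
`fixtures` module generates seeded synthetic worlds with exactly the
structure above, so the full advanced-vs-naive comparison runs without
any download.

## Worked example

```python
import healthrec as hr

g = hr.ConceptGraph()
g.add_edge("nstemi", "myocardial infarction", "REDIRECT", 1.0)
g.add_edge("i21", "myocardial infarction", "CODE", 1.0)
g.add_edge("myocardial infarction", "coronary disease", "ARTICLE", 1.0)
g.add_edge("cardiogenic shock", "myocardial infarction", "ARTICLE", 1.0)

text = "Discharge diagnosis NSTEMI. No signs of cardiogenic shock."
q = hr.build_query(text, g)
print(dict(q.terms), q.excluded)
# {'nstemi': 1} {'cardiogenic shock'}

print(hr.render_query(hr.expand_query(q, g)))
# nstemi^1.0 i21^0.6 "myocardial infarction"^0.6 "coronary disease"^0.3

corpus = [
    hr.Artifact("hia1", "Myocardial infarction",
                "what happens during a myocardial infarction and how to recover",
                hr.Audience.LAYMEN),
    hr.Artifact("hia2", "Coronary disease",
                "living with coronary disease day to day", hr.Audience.LAYMEN),
    hr.Artifact("hia3", "Healthy sleep",
                "tips for healthy sleep and rest", hr.Audience.LAYMEN),
]
idx = hr.build_index(corpus)

hr.recommend_naive("NSTEMI", idx, 4).entries   # [] — token never occurs
for aid, raw, norm in hr.recommend_advanced(text, g, idx, topk=4).entries:
    print(f"{aid}  raw={raw:.4f}  norm={norm:.3f}")
# hia1  raw=0.6836  norm=1.000
# hia2  raw=0.3571  norm=0.522
```

The naive baseline returns nothing (the abbreviation never appears in
the laymen corpus); the advanced pipeline resolves NSTEMI through the
graph, drops the negated "cardiogenic shock", and ranks the myocardial
infarction article on top with normalized score 1.0.

The same comparison at benchmark scale (30 concepts, 60 cases with
abbreviation/misspelling/negation noise, seed 11):

```python
res = hr.run_benchmark()
print(res.report.rho_h, res.report.rho_v, res.delta_rho)
# 0.7917  0.4333  0.3583   (one-sided paired t: t=6.415, p=1.3e-08)
```

## Command line

The `hrs` console script wires the same functions:

```sh
hrs simulate --seed 11 --out fixture/              # synthetic world
hrs index --corpus fixture/corpus.jsonl --laymen-only --out idx/
hrs recommend --mode advanced --graph fixture/graph.tsv \
    --index idx/ --cases fixture/cases.tsv --topk 4 --out res_h.tsv
hrs recommend --mode naive --index idx/ \
    --cases fixture/cases.tsv --topk 4 --out res_v.tsv
hrs evaluate --gold fixture/gold.tsv --results-h res_h.tsv --results-v res_v.tsv
hrs samplesize --omega 0.1 --alpha 0.05 --power 0.8 --j 2 --cp 50
# {"n_cases": 620, "n_cases_noncentral_t": 620, "n_physicians": 25}
hrs classify train --corpus fixture/corpus.jsonl --out model.tsv
```

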