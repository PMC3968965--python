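# Methods

This note documents the models and procedures implemented in
`healthrec`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic benchmark does
and does not show.

## Concept graph

The controlled vocabulary and expansion substrate is a directed,
weighted graph whose nodes are case-folded, whitespace-normalized term
labels (words, multi-word phrases, classification codes) and whose
edges carry one of four types. REDIRECT (synonym/abbreviation) and
CODE (classification code) edges express near-synonymy — tier 1;
CATEGORY and ARTICLE edges express topical relatedness — tier 2.
Duplicate edges (same endpoints and type) collapse to the maximum
weight; self-loops and non-positive weights are rejected at load time.

Neighborhood search is direction-blind: a REDIRECT from "nstemi" to
"myocardial infarction" must make each endpoint reachable from the
other, and in clinical text either form can be the query. A neighbor's
distance is the minimal hop count (so "within k hops" is a superset of
"at exactly k hops" — the safer reading when k bounds the expansion
radius). A neighbor's *tier* is the worst edge tier along the best
minimal path: a candidate is synonymy-grade only if every hop is a
REDIRECT or CODE edge, because a single topical hop (say
REDIRECT→ARTICLE) already makes the relation topical rather than
synonymous. Among minimal paths, lower tier wins, then larger
first-hop weight. Edge weights play no further role during expansion
— how they should be computed or consumed is not constrained by
anything we implement, so they act only as this tie-breaker.

## Query processing

Tokenization is language-agnostic: maximal alphanumeric runs,
case-folded, with sentence boundaries at `. ! ?` and newlines.
Vocabulary matching is greedy longest-phrase-first, so "chronic sleep
apnea" resolves as one concept before its constituent words can match
anything else.

**Negation.** Trigger phrases are data (a TSV shipped with the
package; replaceable per language without touching code). A FORWARD
trigger negates the tokens that follow it until the sentence ends,
capped at `max_scope` tokens (default 6); BACKWARD triggers mirror
this. At a given position the longest matching trigger wins ("in the
absence of" beats "absence of" beats "no"). A vocabulary term is
excluded when its mention overlaps a scope; exclusion removes *all*
occurrences of the term from the query and the expansion step never
adds an excluded term back. The trigger inventory and scope rule are a
NegEx-style reconstruction — they are validated against the three
canonical clinical sentences in the test suite, not against an
annotated corpus, and conjunction-based scope termination ("but") is
not implemented.

**Spell correction.** Only out-of-vocabulary tokens of length ≥ 4 are
corrected (shorter tokens are almost always abbreviations — ECG, MI —
for which edit distance is meaningless). An exact match short-circuits;
otherwise the vocabulary term with minimal Levenshtein distance wins if
that distance is ≤ `max_edit` (default 2, which covers the classic
Diabedes→1/Diabedis→2 typo distances); failing that, the term with
maximal letter-bigram Jaccard wins if it reaches `min_jaccard` (default
0.5). Ties break by higher Jaccard, then lexicographically. Both
string measures are implemented in-package (two-row dynamic program;
n-gram set Jaccard with J(∅,∅)=1 and J(∅,X)=0) and are checked against
an independent recursive-memo oracle in the tests.

## Expansion

Each query term contributes its ≤ k-hop neighborhood (default k = 2)
as candidates. Candidates are ranked by (tier, distance, −first-hop
weight, term) and the best `cap` of them (default 20, global across the
whole query, since the size limit is a property of Q′ as a whole) are
appended with boosts: originals 1.0, tier-1 expansions 0.6, tier-2
expansions 0.3. The boost values are a design choice — chosen once so
that originals dominate tier 1 and tier 1 dominates tier 2 — and are
exposed in the `[expansion]` config section; nothing in the method
depends on their exact values beyond that ordering. Expansion is fully
deterministic.

## Retrieval

The classic vector-space model: document term weight
(1 + ln tf)·ln(N/df), query weight = boost · idf, cosine similarity.
Terms occurring in every document have idf 0 and cannot contribute; a
query sharing no informative term with a document scores exactly 0 and
such documents are never returned. Title tokens count twice
(`title_boost`, set 1 to disable) to favor on-topic artifacts. Within
a ranking, scores are normalized by the maximum raw score, so the top
item is 1.0 and ties at the top are possible; scores from different
pipelines (advanced vs naive) are never compared numerically — only
retrieved sets and ranks are. Ranking ties break lexicographically by
artifact id for cross-platform determinism.

The naive baseline feeds every raw token with weight 1.0 straight into
the same index — no negation handling, no correction, no expansion —
and is exactly the advanced pipeline with those features disabled
(verified as an equivalence test).

## Laymen classifier

Documents are embedded as tf-idf vectors (same weighting as retrieval,
idf frozen from the training corpus) and separated by a linear
soft-margin SVM (scikit-learn `LinearSVC`, hinge loss, L2 penalty,
C = 1.0, balanced class weights, fixed seed). Linear is the right
kernel family for high-dimensional sparse text; nothing non-linear is
testable at this corpus scale. Prediction returns the signed margin
for threshold tuning; pre-labeled laymen artifacts bypass the
classifier during corpus filtering, which is intended to run at
indexing time so the recommendable candidate set shrinks once rather
than per query.

## Evaluation statistics

Per-case precision is |retrieved ∩ relevant| / |retrieved|; a case
with an empty retrieval scores **0**, not skipped — the quotient is
undefined at |retrieved| = 0, and skipping would reward a system for
returning nothing on hard cases, inverting the comparison the metric
exists to make. ρ is the arithmetic mean over cases. Recall is
deliberately out of scope: the recommender's job is a few highly
relevant items, not coverage.

Multi-judge gold standards merge by majority: relevant iff selected by
≥ ⌈j/2⌉ judges (with j = 2 this is the union); `union` and
`intersection` are available alternatives since the merge rule is a
convention, not a derived fact.

The hypothesis ρ_H > ρ_V is tested by pairing per-case precisions:
d_i = H_i − V_i, t = mean(d)/(sd(d)/√n), df = n − 1, upper-tail p.
Pairing per case is the natural reading of a dependent design in which
both systems answer the same cases. Zero-variance differences are
degenerate and flagged (p = 1 for non-positive mean, p = 0 for positive
mean). The p-value comes from scipy's t distribution and is checked to
1e-6 against a hand-coded incomplete-beta continued-fraction oracle in
the tests, along with simulation checks of the type-I error rate and of
power at the planned sample size.

**Sample-size planning** treats the expected effect ω₀ as a
*standardized* mean difference (no variance for the raw precision
difference is available at planning time, and only this reading makes
the planning well-defined). The defining formula is the normal
approximation with Guenther's small-sample correction for a one-sided
paired t-test, n = ⌈((z₁₋α + z_power)/ω₀)² + z₁₋α²/2⌉, giving 620, 277
and 156 cases at ω₀ = 0.1, 0.15, 0.2 (α = 0.05, power 0.8). The exact
noncentral-t iteration is implemented alongside and agrees to within
one case over this range; both numbers are reported by `hrs
samplesize`. Judge recruitment is n_p = ⌈n_c · j / c_p⌉.

## Synthetic benchmark

The generator emulates the structure of the real inputs — a
Wikipedia-style health graph, a laymen article corpus, expert
documents, and discharge-letter-like cases — at desk scale, as pure
functions of a spec and seed. Key constructions:

* every concept has a canonical laymen term (20% are two-word
  phrases), abbreviation-like REDIRECT synonyms, optionally one
  ICD-10-style CODE node, a CATEGORY link, and ARTICLE links to
  adjacent concepts;
* laymen articles contain only canonical terms plus a laymen filler
  vocabulary; expert documents contain abbreviations, codes and a
  disjoint expert filler vocabulary. Hence laymen articles never
  contain an abbreviation or code (the property that defeats naive
  matching), and the two document classes are linearly separable by
  construction;
* filler words are long (10–12 characters) and drawn from a disjoint
  letter alphabet so they can never fall within spell-correction reach
  of a vocabulary term;
* cases mention 1–3 target concepts rendered as abbreviation (rate
  0.5), code (0.15), or canonical term with misspelling rate 0.2 —
  1–2 character substitutions, matching the edit-distance regime the
  corrector accepts — and with probability 0.3 a negated decoy
  concept. Gold relevance is the laymen articles of the non-negated
  targets, recorded identically by two simulated judges (judge noise
  is deliberately zero: the gold standard is defined by concept
  identity, keeping the benchmark deterministic).

The benchmark conditions (seed 11, 30 concepts, 60 laymen + 30 expert
documents, 60 cases, the rates above) are frozen; the comparison
indexes the laymen subcorpus only — the recommendable item set is by
definition the laymen collection — and retrieves the top 4 items per
case, the length of a short recommendation list. Under these
conditions the advanced pipeline beats the naive baseline by
Δρ ≈ 0.36, comfortably above the 0.1 effect the power analysis plans
for, and the paired test rejects at α = 0.05.

**What this does and does not show.** The synthetic world isolates the
vocabulary-gap mechanism: naive retrieval fails on abbreviation, code
and misspelled mentions *by construction*, and the graph always
contains the resolving edge. Passing therefore demonstrates that the
pipeline's machinery composes correctly end to end — not that the
effect size transfers to real clinical text, where graph coverage is
imperfect, negation is richer than trigger scopes, laymen articles
paraphrase rather than repeat canonical terms, and judges disagree.
Score magnitudes in the benchmark likewise depend on the generator's
corpus statistics and are not comparable to any external system's.

## Numerical and degenerate-input conventions

* Levenshtein/Jaccard: J over empty n-gram sets is 1 (both empty) or 0
  (one empty); strings shorter than n simply have empty n-gram sets.
* Retrieval: a document whose every term has idf 0 has norm 0 and is
  unscorable (score 0); empty queries and empty corpora yield empty
  results rather than errors.
* Classifier: an empty document's decision value is the bias; training
  requires ≥ 2 documents per class.
* t-test: n < 2 is an error; zero-variance branches are handled
  explicitly (see above).
* All randomness (generators, SVM seed) flows from explicit integer
  seeds; identical spec + seed reproduce byte-identical fixture files.

## Known limitations

* Negation handling is trigger/scope-based only — no dependency
  parsing, no conjunction termination, no double negation.
* Stemming/lemmatization is not implemented; the fuzzy matchers absorb
  inflection only incidentally.
* The expansion boosts and cap are conventions, not fitted quantities.
* The SVM uses no feature engineering beyond tf-idf; readability
  formulas are out of scope.
* Index persistence is a plain JSON snapshot, suitable for desk-scale
  corpora, not incremental updates.
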