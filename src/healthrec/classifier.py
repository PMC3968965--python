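"""Laymen-friendliness pre-filter: a linear SVM on tf-idf document vectors.

Health information destined for patients must be understandable without
medical training.  Documents are embedded as tf-idf vectors under the
same weighting the retrieval engine uses, and a linear soft-margin SVM
(hinge loss, L2 penalty) separates laymen-friendly from expert
documents.  The trained weight vector is applied at indexing time to
pre-filter the recommendable corpus.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from sklearn.svm import LinearSVC

from .retrieval import Artifact, Audience, _doc_term_counts

__all__ = ["TrainedClassifier", "train_classifier", "predict",
           "filter_corpus", "save_model", "load_model"]


@dataclass
class TrainedClassifier:
    """Linear decision function w.x + b over a fixed tf-idf vocabulary.

    Positive decision values mean LAYMEN.  ``idf`` is frozen from the
    training corpus so prediction embeds new documents consistently.
    """

    vocab: list[str]
    weights: np.ndarray
    bias: float
    idf: np.ndarray
    C: float = 1.0
    seed: int = 0
    n_docs: int = 0
    metadata: dict = field(default_factory=dict)

    def vocab_hash(self) -> str:
        h = hashlib.sha256("\n".join(self.vocab).encode()).hexdigest()
        return h[:16]

    def weight_hash(self) -> str:
        return hashlib.sha256(self.weights.tobytes()).hexdigest()[:16]


def _embed(docs: list[Artifact], vocab: list[str], idf: np.ndarray,
           title_boost: int = 1) -> sparse.csr_matrix:
    """tf-idf document vectors: (1 + ln tf) * idf over a fixed vocabulary."""
    col = {t: i for i, t in enumerate(vocab)}
    rows, cols, vals = [], [], []
    for r, a in enumerate(docs):
        for term, tf in _doc_term_counts(a, title_boost).items():
            c = col.get(term)
            if c is not None and idf[c] > 0:
                rows.append(r)
                cols.append(c)
                vals.append((1.0 + math.log(tf)) * idf[c])
    return sparse.csr_matrix((vals, (rows, cols)),
                             shape=(len(docs), len(vocab)))


def train_classifier(labeled: list[tuple[Artifact, Audience]],
                     C: float = 1.0, seed: int = 0) -> TrainedClassifier:
    """Fit the linear soft-margin SVM on labeled artifacts.

    Requires at least two documents per class; class weights are
    balanced.  Deterministic for a fixed corpus and seed.
    """
    labels = [lab for _, lab in labeled]
    n_lay = sum(1 for l in labels if l == Audience.LAYMEN)
    n_exp = sum(1 for l in labels if l == Audience.EXPERT)
    if n_lay < 2 or n_exp < 2:
        raise ValueError("degenerate training set: need >= 2 docs per class")
    docs = [a for a, _ in labeled]
    # vocabulary and idf from the training corpus
    df: dict[str, int] = {}
    for a in docs:
        for term in _doc_term_counts(a, 1):
            df[term] = df.get(term, 0) + 1
    vocab = sorted(df)
    n = len(docs)
    idf = np.array([math.log(n / df[t]) for t in vocab])
    X = _embed(docs, vocab, idf)
    y = np.array([1 if l == Audience.LAYMEN else -1 for l in labels])
    svm = LinearSVC(C=C, class_weight="balanced", random_state=seed,
                    max_iter=20000, tol=1e-5)
    svm.fit(X, y)
    clf = TrainedClassifier(
        vocab=vocab, weights=svm.coef_.ravel().copy(),
        bias=float(svm.intercept_[0]), idf=idf, C=C, seed=seed, n_docs=n)
    clf.metadata = {"n_laymen": n_lay, "n_expert": n_exp,
                    "vocab_hash": clf.vocab_hash()}
    return clf


def predict(clf: TrainedClassifier, a: Artifact) -> tuple[Audience, float]:
    """Predicted audience and signed margin for one artifact.

    Out-of-vocabulary terms are ignored; an empty document falls back to
    the bias alone.
    """
    x = _embed([a], clf.vocab, clf.idf)
    value = float((x @ clf.weights).item()) + clf.bias
    label = Audience.LAYMEN if value > 0 else Audience.EXPERT
    return label, value


def filter_corpus(corpus: list[Artifact], clf: TrainedClassifier
                  ) -> tuple[list[Artifact], dict[str, int]]:
    """Keep laymen-friendly artifacts; report kept/dropped counts.

    Artifacts already labeled LAYMEN bypass the classifier; everything
    else is kept only if predicted LAYMEN.
    """
    kept: list[Artifact] = []
    for a in corpus:
        if a.audience == Audience.LAYMEN or predict(clf, a)[0] == Audience.LAYMEN:
            kept.append(a)
    counts = {"kept": len(kept), "dropped": len(corpus) - len(kept)}
    return kept, counts


def save_model(clf: TrainedClassifier, path: str | Path) -> None:
    """Versioned TSV of (term, weight) plus a JSON sidecar."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# healthrec linear model v1\n")
        for term, w, i in zip(clf.vocab, clf.weights, clf.idf):
            fh.write(f"{term}\t{float(w)!r}\t{float(i)!r}\n")
    sidecar = {"bias": clf.bias, "C": clf.C, "seed": clf.seed,
               "n_docs": clf.n_docs, "vocab_hash": clf.vocab_hash(),
               "metadata": clf.metadata}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar), encoding="utf-8")


def load_model(path: str | Path) -> TrainedClassifier:
    path = Path(path)
    vocab, weights, idf = [], [], []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            term, w, i = line.rstrip("\n").split("\t")
            vocab.append(term)
            weights.append(float(w))
            idf.append(float(i))
    sidecar = json.loads(
        path.with_suffix(path.suffix + ".json").read_text(encoding="utf-8"))
    return TrainedClassifier(
        vocab=vocab, weights=np.array(weights), bias=sidecar["bias"],
        idf=np.array(idf), C=sidecar["C"], seed=sidecar["seed"],
        n_docs=sidecar["n_docs"], metadata=sidecar.get("metadata", {}))
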