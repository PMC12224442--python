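"""Semantic scoring of decoded labels: IC, TFIDF, categories, SNR.

Information content of a term t in document d is IC = -ln p(t, d) with
p(t, d) = f(t, d) / N(d); the map-level value averages over the documents
of the meta-analytic sample. TFIDF uses the smooth-idf convention
idf = ln((1 + D) / (1 + d_t)) + 1. Topic-level scores sum the top words'
scores. Expert category annotations yield p(category|word); terms and
topics are classified by the strict > 0.5 rule, and the decoding SNR is
the proportion of Functional to non-functional labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .meta_maps import Corpus

__all__ = [
    "CATEGORIES",
    "AnnotationSet",
    "CategoryModel",
    "ic_word",
    "ic_topic",
    "tfidf_word",
    "tfidf_topic",
    "category_model",
    "classify_word",
    "classify_topic",
    "snr",
    "report_weights",
]

CATEGORIES = ("Anatomical", "Functional", "Clinical", "Non-specific")


@dataclass
class AnnotationSet:
    """word -> {category: vote count} from one or more raters."""

    votes: dict[str, dict[str, int]]

    def __post_init__(self) -> None:
        for word, counts in self.votes.items():
            if any(c not in CATEGORIES for c in counts):
                raise ValueError(f"unknown category in votes for {word!r}")
            if sum(counts.values()) < 1 or any(v < 0 for v in counts.values()):
                raise ValueError(f"word {word!r} needs at least one non-negative vote")


@dataclass
class CategoryModel:
    """word -> p(category|word)."""

    probabilities: dict[str, dict[str, float]]

    def __contains__(self, word: str) -> bool:
        return word in self.probabilities


def _sample_rows(corpus: Corpus, doc_ids: list[str]) -> np.ndarray:
    if not doc_ids:
        raise ValueError("meta-analytic sample is empty")
    return np.array([corpus.doc_row(d) for d in doc_ids])


def ic_word(corpus: Corpus, word: str, doc_ids: list[str], smoothing: bool = False) -> float:
    """Average information content of ``word`` over a document sample.

    Per document, IC = -ln(f / N). Documents where the word is absent are
    skipped by default (an infinite IC would otherwise dominate);
    ``smoothing=True`` uses add-one counts instead.
    """
    rows = _sample_rows(corpus, doc_ids)
    j = corpus.word_column(word)
    counts = corpus.counts[rows]
    f = counts[:, j].astype(float)
    n_tot = counts.sum(axis=1).astype(float)
    if smoothing:
        p = (f + 1.0) / (n_tot + len(corpus.vocabulary))
        return float(np.mean(-np.log(p)))
    present = f > 0
    if not present.any():
        raise ValueError(f"IC undefined: {word!r} absent from every sample document")
    p = f[present] / n_tot[present]
    return float(np.mean(-np.log(p)))


def ic_topic(corpus: Corpus, top_words: list[str], doc_ids: list[str], smoothing: bool = False) -> float:
    """Topic IC: sum of word ICs over the topic's top words."""
    total, defined = 0.0, 0
    for w in top_words:
        try:
            total += ic_word(corpus, w, doc_ids, smoothing=smoothing)
            defined += 1
        except (ValueError, KeyError):
            continue
    if defined == 0:
        raise ValueError("IC undefined for every top word of the topic")
    return total


def tfidf_word(corpus: Corpus, word: str, doc_ids: list[str]) -> float:
    """Average TFIDF over the sample: tf = f(t, d), smooth idf, absent -> 0."""
    rows = _sample_rows(corpus, doc_ids)
    j = corpus.word_column(word)
    big_d = len(corpus.doc_ids)
    d_t = int(np.count_nonzero(corpus.counts[:, j]))
    idf = math.log((1 + big_d) / (1 + d_t)) + 1.0
    tf = corpus.counts[rows, j].astype(float)
    return float(np.mean(tf * idf))


def tfidf_topic(corpus: Corpus, top_words: list[str], doc_ids: list[str]) -> float:
    """Topic TFIDF: sum of the top words' TFIDF values."""
    return float(sum(tfidf_word(corpus, w, doc_ids) for w in top_words))


def category_model(annotations: AnnotationSet) -> CategoryModel:
    """Frequentist p(category|word) = votes / total votes."""
    probs: dict[str, dict[str, float]] = {}
    for word, counts in annotations.votes.items():
        total = sum(counts.values())
        probs[word] = {c: counts.get(c, 0) / total for c in CATEGORIES}
    return CategoryModel(probabilities=probs)


def classify_word(model: CategoryModel, word: str, missing_policy: str = "non_specific") -> str:
    """Category with p > 0.5 (strict), else 'Non-specific'."""
    if word not in model:
        if missing_policy == "non_specific":
            return "Non-specific"
        raise KeyError(f"word {word!r} has no annotation")
    p = model.probabilities[word]
    best = max(CATEGORIES, key=lambda c: p.get(c, 0.0))
    return best if p.get(best, 0.0) > 0.5 else "Non-specific"


def classify_topic(model: CategoryModel, word_probs: dict[str, float]) -> str:
    """Classify a topic from its p(word|topic) weights.

    score(c) = sum_w p(c|w) * p(w|topic); words missing from the model
    contribute their mass to 'Non-specific'. The category must exceed 0.5
    strictly, otherwise the topic is 'Non-specific'.
    """
    scores = dict.fromkeys(CATEGORIES, 0.0)
    for word, weight in word_probs.items():
        if word in model:
            for c in CATEGORIES:
                scores[c] += model.probabilities[word].get(c, 0.0) * weight
        else:
            scores["Non-specific"] += weight
    best = max(CATEGORIES, key=lambda c: scores[c])
    return best if scores[best] > 0.5 else "Non-specific"


def snr(categories: list[str]) -> tuple[float, float]:
    """Decoding signal-to-noise ratio of a label list.

    Returns ``(snr, normalized_snr)``: the ratio of Functional to
    non-functional labels, and the Functional fraction of all labels.
    With no non-functional labels the raw ratio is ``inf``.
    """
    if not categories:
        raise ValueError("empty category list")
    n_fun = sum(1 for c in categories if c == "Functional")
    n_non = len(categories) - n_fun
    ratio = math.inf if n_non == 0 else n_fun / n_non
    return ratio, n_fun / len(categories)


def report_weights(
    word_topic: np.ndarray,
    vocabulary: list[str],
    topic_r: dict[int, float],
) -> dict[str, float]:
    """Word-cloud weights for a set of retained (significant, functional)
    topic maps.

    With a uniform prior over the retained topics, Bayes gives
    p(topic|word) proportional to p(word|topic); each word's weight is
    sum over retained topics of p(topic|word) * r_topic. Filtering of
    non-significant or non-functional topics happens upstream: only the
    topics present in ``topic_r`` contribute.
    """
    retained = sorted(topic_r)
    if not retained:
        return {}
    W = np.asarray(word_topic, dtype=float)[retained]       # (T, V)
    r = np.array([topic_r[t] for t in retained])
    col = W.sum(axis=0)
    weights: dict[str, float] = {}
    for j, word in enumerate(vocabulary):
        if col[j] <= 0:
            continue
        p_topic_given_word = W[:, j] / col[j]
        weights[word] = float(p_topic_given_word @ r)
    return weights
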