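"""Naive word-score classifier.

The comparison model: each word is scored by how frequently it occurs in
the names of each cuisine type ("wok" scores for Southeast & East Asian,
"ocean" for fish and chips); a name's per-class score is the sum of its
words' scores, and the highest-scoring class wins.  Words common to (a
configurable fraction of) all cuisine types — seeded with "and" and
"takeaway" — are treated as stopwords and carry no score.  Scores are
within-class relative frequencies so that class size does not dominate.

Exposed both as :class:`WordScoreClassifier` (scikit-learn estimator) and
as the functional pair :func:`build_word_scores` / :func:`naive_predict`.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .records import LabeledOutlet, OutletRecord
from .textprep import normalize_name

__all__ = [
    "WordScoreModel",
    "build_word_scores",
    "naive_predict",
    "WordScoreClassifier",
]

DEFAULT_SEED_STOPWORDS = frozenset({"and", "takeaway"})


@dataclass
class WordScoreModel:
    """Word -> per-class score table plus stopword set and tie policy.

    ``tie_rule`` is fixed to "first class alphabetically": a name whose
    per-class scores tie (including the all-unknown-words case, where all
    scores are zero) is assigned the alphabetically first tied class.
    """

    scores: dict[str, dict[str, float]]
    stopwords: frozenset[str]
    classes: tuple[str, ...]
    tie_rule: str = "alphabetical_first"

    def score_name(self, name: str) -> dict[str, float]:
        totals = {c: 0.0 for c in self.classes}
        for word in normalize_name(name).split():
            for cls, s in self.scores.get(word, {}).items():
                totals[cls] += s
        return totals


def build_word_scores(
    train: Sequence[LabeledOutlet],
    stopword_fraction: float = 1.0,
    seed_stopwords: frozenset[str] = DEFAULT_SEED_STOPWORDS,
) -> WordScoreModel:
    """Derive word scores from labelled training outlets.

    ``score(word, class)`` is the relative frequency of ``word`` among all
    word occurrences in that class's names.  A word occurring in at least
    ``stopword_fraction`` of the classes (default 1.0 = all of them) is a
    stopword and gets no score, as are the seed stopwords.
    """
    if not train:
        raise ValueError("cannot build word scores from an empty training set")
    if not 0.0 < stopword_fraction <= 1.0:
        raise ValueError("stopword_fraction must be in (0, 1]")
    class_word_counts: dict[str, Counter] = defaultdict(Counter)
    for outlet in train:
        words = normalize_name(outlet.name).split()
        class_word_counts[outlet.cuisine].update(words)
    classes = tuple(sorted(class_word_counts))
    n_classes = len(classes)

    doc_freq = Counter()
    for cls in classes:
        doc_freq.update(class_word_counts[cls].keys())
    stopwords = set(seed_stopwords) | {
        w for w, k in doc_freq.items() if k / n_classes >= stopword_fraction
    }

    scores: dict[str, dict[str, float]] = defaultdict(dict)
    for cls in classes:
        counts = class_word_counts[cls]
        total = sum(n for w, n in counts.items() if w not in stopwords)
        if total == 0:
            continue
        for word, n in counts.items():
            if word not in stopwords:
                scores[word][cls] = n / total
    return WordScoreModel(
        scores=dict(scores), stopwords=frozenset(stopwords), classes=classes
    )


def naive_predict(model: WordScoreModel, name: str) -> str:
    """Predict the class with the highest summed word score; ties (and
    names of only unknown words) go to the alphabetically first tied
    class."""
    totals = model.score_name(name)
    best = max(totals.values())
    return min(c for c, s in totals.items() if s == best)


class WordScoreClassifier(ClassifierMixin, BaseEstimator):
    """The word-frequency baseline as a scikit-learn estimator."""

    def __init__(self, stopword_fraction: float = 1.0,
                 seed_stopwords: frozenset = DEFAULT_SEED_STOPWORDS):
        self.stopword_fraction = stopword_fraction
        self.seed_stopwords = seed_stopwords

    def fit(self, X, y):
        train = [
            LabeledOutlet(OutletRecord(name=normalize_name(str(n), allow_empty=False)),
                          str(c), "owner_label")
            for n, c in zip(X, y)
        ]
        self.model_ = build_word_scores(
            train, self.stopword_fraction, frozenset(self.seed_stopwords)
        )
        self.classes_ = np.array(sorted({str(c) for c in y}))
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise ValueError("this WordScoreClassifier instance is not fitted yet")
        return np.array([naive_predict(self.model_, str(n)) for n in X])

    def to_frame(self) -> pd.DataFrame:
        """Persistable long-format score table (word, class, score)."""
        rows = [
            {"word": w, "class": c, "score": s}
            for w, per_class in sorted(self.model_.scores.items())
            for c, s in sorted(per_class.items())
        ]
        return pd.DataFrame(rows, columns=["word", "class", "score"])
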