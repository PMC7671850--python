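"""Smoking-reasons intent classifier with abstention, and its evaluation.

The classifier maps a free-form utterance to exactly one reason category from
a taxonomy, or abstains when its top softmax score falls below a threshold.
It is a linear model (multinomial logistic regression) over TF-IDF word
1–2-gram features: deterministic for a fixed corpus order and seed, desk-scale,
and inspectable.

Evaluation follows the chatbot's single-label micro scheme: each evaluated
utterance contributes exactly one of

* TP — a detection with the correct category,
* FP — a detection with a wrong category,
* FN — an abstention (the system produced no classification),

and precision, recall, and F1 are pooled globally over these counts:
``P = TP/(TP+FP)``, ``R = TP/(TP+FN)``, ``F1 = TP/(TP + 0.5*(FP+FN))`` (the
harmonic mean of P and R whenever both are defined).
"""

from __future__ import annotations

import hashlib
import pickle
import re
import unicodedata
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression

from .taxonomy import Taxonomy

MODEL_SCHEMA = "mibot-model/1"

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero; never silently reported as 0."""


def normalize_text(text: str) -> list[str]:
    """Lowercase, Unicode-NFC, punctuation-stripped word tokens.

    Punctuation never changes the token sequence ("Yes." and "Yes" normalize
    identically), so downstream matching is punctuation-insensitive.
    """
    text = unicodedata.normalize("NFC", text).casefold()
    return _TOKEN_RE.findall(text)


@dataclass(frozen=True)
class LabeledUtterance:
    """The corpus atom: an utterance with its reason category and polarity."""

    text: str
    category_id: str
    polarity: str  # "pro" | "con"
    source: str = "fixture"  # "fixture" | "synthetic" | "human"


@dataclass(frozen=True)
class Prediction:
    kind: str  # "detected" | "abstained"
    category_id: str | None = None
    confidence: float = 0.0

    @property
    def detected(self) -> bool:
        return self.kind == "detected"

    @property
    def abstained(self) -> bool:
        return self.kind == "abstained"


ABSTAINED = Prediction(kind="abstained", category_id=None, confidence=0.0)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class MicroMetrics:
    precision: float
    recall: float
    f1: float


def micro_metrics(counts: ConfusionCounts) -> MicroMetrics:
    """Micro precision/recall/F1 pooled over TP/FP/FN counts.

    Raises :class:`UndefinedMetricError` when a denominator is zero.
    """
    if counts.total == 0:
        raise UndefinedMetricError("no evaluated utterances (tp+fp+fn == 0)")
    if counts.tp + counts.fp == 0:
        raise UndefinedMetricError("precision undefined: no detections (tp+fp == 0)")
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("recall undefined: tp+fn == 0")
    precision = counts.tp / (counts.tp + counts.fp)
    recall = counts.tp / (counts.tp + counts.fn)
    f1 = counts.tp / (counts.tp + 0.5 * (counts.fp + counts.fn))
    return MicroMetrics(precision, recall, f1)


# ---------------------------------------------------------------------------
# Model

@dataclass(frozen=True)
class ClassifierConfig:
    """Settings for the TF-IDF + logistic-regression classifier.

    ``abstention_threshold`` is the minimum top-class softmax score needed to
    emit a detection; below it the classifier abstains (counted as FN in
    evaluation). ``c`` is the inverse regularization strength — short, nearly
    separable utterances want weak regularization.
    """

    ngram_max: int = 2
    c: float = 50.0
    abstention_threshold: float = 0.5
    max_iter: int = 1000


@dataclass(frozen=True)
class ClassifierModel:
    """A trained smoking-reasons classifier bound to a taxonomy version."""

    vectorizer: TfidfVectorizer
    estimator: LogisticRegression
    labels: tuple[str, ...]
    taxonomy_version: int
    config: ClassifierConfig
    training_fingerprint: str

    @property
    def abstention_threshold(self) -> float:
        return self.config.abstention_threshold

    def with_threshold(self, threshold: float) -> "ClassifierModel":
        return replace(self, config=replace(self.config, abstention_threshold=threshold))

    def classify(self, text: str) -> Prediction:
        return classify(self, text)

    def __call__(self, text: str) -> Prediction:
        return classify(self, text)


def _fingerprint(corpus: Sequence[LabeledUtterance]) -> str:
    h = hashlib.sha256()
    for u in corpus:
        h.update(u.text.encode("utf-8"))
        h.update(b"\x00")
        h.update(u.category_id.encode("utf-8"))
        h.update(b"\x01")
    return h.hexdigest()


def train_classifier(
    corpus: Sequence[LabeledUtterance],
    taxonomy: Taxonomy,
    config: ClassifierConfig | None = None,
    seed: int = 0,
) -> ClassifierModel:
    """Fit the classifier on a labeled corpus.

    Deterministic for a fixed (corpus order, config, seed): the solver is
    deterministic and the vocabulary is built in corpus order.
    """
    config = config or ClassifierConfig()
    corpus = list(corpus)
    if not corpus:
        raise ValueError("empty corpus")
    known = set(taxonomy.ids())
    unknown = sorted({u.category_id for u in corpus} - known)
    if unknown:
        raise ValueError(f"corpus references unknown category ids: {unknown}")

    vectorizer = TfidfVectorizer(
        tokenizer=normalize_text,
        preprocessor=None,
        lowercase=False,
        token_pattern=None,
        ngram_range=(1, config.ngram_max),
        sublinear_tf=True,
    )
    x = vectorizer.fit_transform([u.text for u in corpus])
    y = np.array([u.category_id for u in corpus])
    labels = sorted(set(y))
    if len(labels) == 1:
        # degenerate single-class corpus: nothing to discriminate; the model
        # can only ever emit that category (or abstain on empty input)
        estimator = None
    else:
        estimator = LogisticRegression(
            C=config.c, max_iter=config.max_iter, random_state=seed
        )
        estimator.fit(x, y)
        labels = list(estimator.classes_)
    return ClassifierModel(
        vectorizer=vectorizer,
        estimator=estimator,
        labels=tuple(str(c) for c in labels),
        taxonomy_version=taxonomy.version,
        config=config,
        training_fingerprint=_fingerprint(corpus),
    )


def classify(model: ClassifierModel, text: str) -> Prediction:
    """Predict exactly one category, or abstain.

    The label set is mutually exclusive; score ties break to the
    lexicographically smallest category id. Empty text (after normalization)
    abstains with confidence 0.
    """
    if not normalize_text(text):
        return ABSTAINED
    if model.estimator is None:
        return Prediction(kind="detected", category_id=model.labels[0], confidence=1.0)
    x = model.vectorizer.transform([text])
    proba = model.estimator.predict_proba(x)[0]
    top = float(np.max(proba))
    if top < model.abstention_threshold:
        return Prediction(kind="abstained", category_id=None, confidence=top)
    # ties: np.where picks all argmax indices; classes_ is sorted, so the
    # first one is the lexicographically smallest id
    best = int(np.flatnonzero(proba == np.max(proba))[0])
    return Prediction(
        kind="detected", category_id=str(model.labels[best]), confidence=top
    )


def confusion_counts(
    model: ClassifierModel, test: Sequence[LabeledUtterance]
) -> ConfusionCounts:
    """Pooled TP/FP/FN of a model on a labeled test set (one outcome per
    utterance: correct detection, wrong detection, or abstention)."""
    test = list(test)
    if not test:
        raise ValueError("empty test set")
    unknown = sorted({u.category_id for u in test} - set(model.labels))
    if unknown:
        raise ValueError(f"test set references labels unknown to the model: {unknown}")
    tp = fp = fn = 0
    for u in test:
        pred = classify(model, u.text)
        if pred.abstained:
            fn += 1
        elif pred.category_id == u.category_id:
            tp += 1
        else:
            fp += 1
    return ConfusionCounts(tp, fp, fn)


def evaluate(
    model: ClassifierModel, test: Sequence[LabeledUtterance]
) -> tuple[ConfusionCounts, MicroMetrics]:
    """Score a model on held-out data under the single-label micro scheme."""
    counts = confusion_counts(model, test)
    return counts, micro_metrics(counts)


def split_corpus(
    corpus: Sequence[LabeledUtterance], test_size: int, seed: int
) -> tuple[list[LabeledUtterance], list[LabeledUtterance]]:
    """Seeded, category-stratified split with a fixed-size held-out test set.

    Test slots are allocated to categories proportionally (largest remainder);
    categories with a single member stay in the training set. The two halves
    are a disjoint, exhaustive partition of the input.
    """
    corpus = list(corpus)
    n = len(corpus)
    if not 0 < test_size < n:
        raise ValueError(f"test_size {test_size} out of range for corpus of {n}")
    rng = np.random.default_rng(seed)

    by_cat: dict[str, list[int]] = {}
    for i, u in enumerate(corpus):
        by_cat.setdefault(u.category_id, []).append(i)
    eligible = {c: idx for c, idx in by_cat.items() if len(idx) >= 2}
    n_eligible = sum(len(v) for v in eligible.values())
    if n_eligible == 0 or test_size > n_eligible - len(eligible):
        # cannot stratify while leaving >=1 train member per class; plain split
        order = rng.permutation(n)
        test_idx = set(int(i) for i in order[:test_size])
    else:
        quota: dict[str, int] = {}
        remainders: list[tuple[float, str]] = []
        for cat in sorted(eligible):
            exact = test_size * len(eligible[cat]) / n_eligible
            base = min(int(exact), len(eligible[cat]) - 1)
            quota[cat] = base
            remainders.append((exact - base, cat))
        short = test_size - sum(quota.values())
        remainders.sort(key=lambda t: (-t[0], t[1]))
        for _, cat in remainders:
            if short == 0:
                break
            if quota[cat] < len(eligible[cat]) - 1:
                quota[cat] += 1
                short -= 1
        # if rounding still leaves a shortfall, top up anywhere legal
        for cat in sorted(eligible):
            while short > 0 and quota[cat] < len(eligible[cat]) - 1:
                quota[cat] += 1
                short -= 1
        test_idx = set()
        for cat in sorted(eligible):
            picks = rng.choice(eligible[cat], size=quota[cat], replace=False)
            test_idx.update(int(i) for i in picks)
    train = [u for i, u in enumerate(corpus) if i not in test_idx]
    test = [u for i, u in enumerate(corpus) if i in test_idx]
    return train, test


# ---------------------------------------------------------------------------
# Serialization

def serialize_model(model: ClassifierModel) -> bytes:
    payload = {"schema": MODEL_SCHEMA, "model": model}
    return pickle.dumps(payload, protocol=4)


def deserialize_model(blob: bytes) -> ClassifierModel:
    payload = pickle.loads(blob)
    if not isinstance(payload, dict) or payload.get("schema") != MODEL_SCHEMA:
        raise ValueError(f"unsupported model artifact (expected {MODEL_SCHEMA!r})")
    return payload["model"]


def save_model(model: ClassifierModel, path: str | Path) -> None:
    Path(path).write_bytes(serialize_model(model))


def load_model(path: str | Path) -> ClassifierModel:
    return deserialize_model(Path(path).read_bytes())
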