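"""Cascaded three-class sentiment classification for short survey answers.

The cascade is two sequential binary classifiers: stage A separates
negative from non-negative answers; stage B splits the non-negatives
into positive and neutral.  An answer is therefore labelled negative
if and only if stage A says so — stage B can never produce a negative.
Empty answers are excluded from training and receive the neutral label
at prediction time (an empty answer describes no situation).

The classifier backend is a pluggable contract; the shipped default is
a TF-IDF (1-2 gram) bag-of-words representation feeding an
L2-regularised logistic regression.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from enum import Enum

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline

from .corpus import ResponseSet, _read_text

__all__ = [
    "SentimentLabel",
    "AnnotatedResponse",
    "BagOfWordsLinearBackend",
    "CascadeModel",
    "EvalReport",
    "train_cascade",
    "predict_sentiment",
    "eval_metrics",
    "percent_agreement",
    "load_annotations",
]


class SentimentLabel(str, Enum):
    NEGATIVE = "negative"
    NEUTRAL = "neutral"
    POSITIVE = "positive"


@dataclass(frozen=True)
class AnnotatedResponse:
    respondent_id: str
    question_id: str
    text: str
    label: SentimentLabel
    annotator_id: str = "annotator"

    def __post_init__(self):
        if not self.text.strip():
            raise ValueError(
                f"label defined only for non-empty text: "
                f"{(self.respondent_id, self.question_id)}"
            )

    @property
    def key(self):
        return (self.respondent_id, self.question_id)


class DegenerateTrainingError(ValueError):
    """A cascade stage saw only one class in its training subset."""


class BagOfWordsLinearBackend:
    """Default backend: TF-IDF unigram+bigram features, logistic regression."""

    name = "tfidf-logreg"

    def __init__(self, seed: int = 0, C: float = 10.0):
        self.seed = seed
        self._pipeline = Pipeline(
            [
                ("tfidf", TfidfVectorizer(ngram_range=(1, 2))),
                (
                    "clf",
                    LogisticRegression(
                        C=C, max_iter=1000, random_state=seed, solver="lbfgs"
                    ),
                ),
            ]
        )
        self.is_fitted = False

    def fit(self, texts, labels):
        labels = list(labels)
        if len(set(labels)) < 2:
            raise DegenerateTrainingError(
                f"backend needs two classes, got {sorted(set(labels))}"
            )
        self._pipeline.fit(list(texts), labels)
        self.is_fitted = True
        return self

    def predict(self, texts) -> list:
        if not self.is_fitted:
            raise RuntimeError("backend not fitted")
        return list(self._pipeline.predict(list(texts)))


@dataclass
class EvalReport:
    """Held-out metrics for one cascade stage."""

    stage: str
    per_class: dict[str, dict[str, float]]  # class -> precision/recall/f1
    confusion: dict[tuple[str, str], int]  # (true, pred) -> count
    n_train: int
    n_val: int

    def __post_init__(self):
        assert sum(self.confusion.values()) == self.n_val


class CascadeModel:
    """Two fitted binary stages; applies the negative-first cascade."""

    STAGE_A_CLASSES = ("negative", "non-negative")
    STAGE_B_CLASSES = ("positive", "neutral")

    def __init__(self, stage_a, stage_b):
        self.stage_a = stage_a
        self.stage_b = stage_b

    @property
    def is_fitted(self) -> bool:
        return bool(
            getattr(self.stage_a, "is_fitted", False)
            and getattr(self.stage_b, "is_fitted", False)
        )

    def predict(self, texts) -> list[SentimentLabel]:
        if not self.is_fitted:
            raise RuntimeError("cascade stages not fitted")
        texts = list(texts)
        out: list[SentimentLabel | None] = [None] * len(texts)
        a = self.stage_a.predict(texts)
        rest_idx = [i for i, lab in enumerate(a) if lab != "negative"]
        for i, lab in enumerate(a):
            if lab == "negative":
                out[i] = SentimentLabel.NEGATIVE
        if rest_idx:
            b = self.stage_b.predict([texts[i] for i in rest_idx])
            for i, lab in zip(rest_idx, b):
                out[i] = SentimentLabel(lab)
        return out  # type: ignore[return-value]


def train_cascade(
    annotated: list[AnnotatedResponse],
    backend_factory=None,
    split_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[CascadeModel, EvalReport, EvalReport]:
    """Train both cascade stages on a seeded random split.

    Stage A is trained on all annotated answers relabelled negative vs
    non-negative; stage B only on the answers with non-negative gold
    labels, mirroring the cascade at inference time.  Returns the fitted
    cascade plus one held-out evaluation report per stage.
    """
    if not annotated:
        raise ValueError("no annotated responses")
    if not (0.0 < split_fraction < 1.0):
        raise ValueError("split_fraction must be in (0, 1)")
    if backend_factory is None:
        backend_factory = lambda: BagOfWordsLinearBackend(seed=seed)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(annotated))
    n_train = int(round(split_fraction * len(annotated)))
    train = [annotated[i] for i in order[:n_train]]
    val = [annotated[i] for i in order[n_train:]]
    if not val or not train:
        raise ValueError("split leaves an empty training or validation set")

    def relabel_a(a):
        return "negative" if a.label is SentimentLabel.NEGATIVE else "non-negative"

    stage_a = backend_factory()
    try:
        stage_a.fit([a.text for a in train], [relabel_a(a) for a in train])
    except DegenerateTrainingError as e:
        raise DegenerateTrainingError(f"stage A (negative vs non-negative): {e}")

    train_b = [a for a in train if a.label is not SentimentLabel.NEGATIVE]
    stage_b = backend_factory()
    try:
        stage_b.fit([a.text for a in train_b], [a.label.value for a in train_b])
    except DegenerateTrainingError as e:
        raise DegenerateTrainingError(f"stage B (positive vs neutral): {e}")

    report_a = _evaluate(
        "A:negative-vs-nonnegative",
        stage_a,
        [a.text for a in val],
        [relabel_a(a) for a in val],
        len(train),
    )
    val_b = [a for a in val if a.label is not SentimentLabel.NEGATIVE]
    report_b = _evaluate(
        "B:positive-vs-neutral",
        stage_b,
        [a.text for a in val_b],
        [a.label.value for a in val_b],
        len(train_b),
    )
    return CascadeModel(stage_a, stage_b), report_a, report_b


def _evaluate(stage, backend, texts, gold, n_train) -> EvalReport:
    pred = backend.predict(texts) if texts else []
    confusion: dict[tuple[str, str], int] = {}
    for t, p in zip(gold, pred):
        confusion[(t, p)] = confusion.get((t, p), 0) + 1
    per_class = {}
    for cls in sorted(set(gold) | set(pred)):
        p, r, f = eval_metrics(gold, pred, cls)
        per_class[cls] = {"precision": p, "recall": r, "f1": f}
    return EvalReport(stage, per_class, confusion, n_train, len(texts))


def predict_sentiment(
    model: CascadeModel, responses: ResponseSet
) -> dict[tuple[str, str], SentimentLabel]:
    """Label every response; empty answers are neutral by convention."""
    if not model.is_fitted:
        raise RuntimeError("cascade model is not fitted")
    labels: dict[tuple[str, str], SentimentLabel] = {}
    non_empty = [r for r in responses if not r.is_empty]
    predicted = model.predict([r.text for r in non_empty]) if non_empty else []
    for r, lab in zip(non_empty, predicted):
        labels[r.key] = lab
    for r in responses:
        if r.is_empty:
            labels[r.key] = SentimentLabel.NEUTRAL
    return labels


def eval_metrics(true_labels, predicted_labels, target_class):
    """Precision, recall and F1 for one class (0 on empty denominators)."""
    true_labels, predicted_labels = list(true_labels), list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"length mismatch: {len(true_labels)} vs {len(predicted_labels)}"
        )
    tp = sum(t == target_class == p for t, p in zip(true_labels, predicted_labels))
    fp = sum(
        p == target_class != t for t, p in zip(true_labels, predicted_labels)
    )
    fn = sum(
        t == target_class != p for t, p in zip(true_labels, predicted_labels)
    )
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return precision, recall, f1


def macro_f1(true_labels, predicted_labels, classes=None) -> float:
    classes = classes or sorted(set(true_labels))
    return float(
        np.mean(
            [eval_metrics(true_labels, predicted_labels, c)[2] for c in classes]
        )
    )


def percent_agreement(labels_a: dict, labels_b: dict) -> float:
    """Fraction of aligned (respondent, question) keys with identical labels."""
    if not labels_a or not labels_b:
        raise ValueError("empty label sets")
    if set(labels_a) != set(labels_b):
        diff = sorted(set(labels_a) ^ set(labels_b))
        raise ValueError(f"misaligned keys (symmetric difference): {diff}")
    agree = sum(labels_a[k] == labels_b[k] for k in labels_a)
    return agree / len(labels_a)


def load_annotations(path, responses: ResponseSet) -> list[AnnotatedResponse]:
    """Read annotation CSV: respondent_id, question_id, label, annotator_id."""
    by_key = {r.key: r for r in responses}
    out = []
    for i, rec in enumerate(csv.DictReader(io.StringIO(_read_text(path)))):
        key = (str(rec["respondent_id"]), str(rec["question_id"]))
        if key not in by_key:
            raise ValueError(f"annotation row {i}: unknown response key {key}")
        out.append(
            AnnotatedResponse(
                respondent_id=key[0],
                question_id=key[1],
                text=by_key[key].text,
                label=SentimentLabel(rec["label"]),
                annotator_id=str(rec.get("annotator_id") or "annotator"),
            )
        )
    return out
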