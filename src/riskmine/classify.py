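"""Veracity classification of normalized messages.

Messages are labelled *true information* or *false information*.  The main
model is a parallel-convolution text CNN (widths 3/4/5, global max pooling,
a 128-unit ReLU dense layer with 0.1 dropout and a softmax output), trained
with cross-entropy under Adam (learning rate 1e-4, decay 0.01, batch 32 by
default) with early stopping on validation macro-F.  A bidirectional LSTM
and two classical baselines (linear SVM, multinomial Naive Bayes over
bag-of-words counts) share the same training/evaluation surface.

Downstream causality mining only trusts high-confidence predictions: the
confidence filter keeps predictions whose softmax confidence reaches a
threshold (0.998 by default) and emits a per-class accounting table of how
many messages survive each filter stage.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import (
    confusion_matrix as _sk_confusion,
    precision_recall_fscore_support,
    roc_curve as _sk_roc_curve,
    auc as _sk_auc,
)
from sklearn.naive_bayes import MultinomialNB
from sklearn.svm import LinearSVC

from .embeddings import SubwordEmbeddingTable, pretrain_embeddings
from .nn import AdamState, BiLSTMClassifier, TextCNN
from .normalize import NormalizedMessage, Vocabulary, build_vocabulary

__all__ = [
    "LABEL_TRUE",
    "LABEL_FALSE",
    "DataSplit",
    "ArchitectureSpec",
    "VeracityPrediction",
    "ClassificationMetrics",
    "VeracityClassifier",
    "FilterAccounting",
    "split_and_dedupe",
    "pretrain_embeddings",
    "train_classifier",
    "predict",
    "evaluate",
    "filter_by_confidence",
    "roc_points",
]

LABEL_TRUE = "true_info"
LABEL_FALSE = "false_info"
# canonical class order: index 0 = false information, 1 = true information
_CLASSES = (LABEL_FALSE, LABEL_TRUE)
_RAW_TO_CLASS = {"false": 0, LABEL_FALSE: 0, "true": 1, LABEL_TRUE: 1}

LabeledMessage = tuple[NormalizedMessage, str]


@dataclass(frozen=True)
class DataSplit:
    """Train/validation/test messages, deduplicated within each split."""

    train: tuple[LabeledMessage, ...]
    validation: tuple[LabeledMessage, ...]
    test: tuple[LabeledMessage, ...]
    ratios: tuple[float, float, float]
    dedup_removed: dict = field(default_factory=dict)

    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.validation), len(self.test))


def split_and_dedupe(
    corpus: list[LabeledMessage],
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> DataSplit:
    """Random split at the given ratios, then exact-text dedup per split.

    The order matters: splitting happens on the raw labeled corpus first and
    duplicates are removed *within* each split afterwards, so the final
    split sizes generally deviate from the nominal ratios.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    if len(corpus) < 3:
        raise ValueError("corpus must contain at least 3 messages to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    n = len(corpus)
    n_train = int(n * ratios[0])
    n_val = int(n * ratios[1])
    parts = {
        "train": [corpus[i] for i in order[:n_train]],
        "validation": [corpus[i] for i in order[n_train : n_train + n_val]],
        "test": [corpus[i] for i in order[n_train + n_val :]],
    }
    deduped: dict[str, list[LabeledMessage]] = {}
    removed: dict[str, int] = {}
    for name, msgs in parts.items():
        seen: set[str] = set()
        kept = []
        for msg, label in msgs:
            if msg.text not in seen:
                seen.add(msg.text)
                kept.append((msg, label))
        deduped[name] = kept
        removed[name] = len(msgs) - len(kept)
    ids = [m.id for part in deduped.values() for m, _ in part]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate message ids across splits")
    return DataSplit(
        train=tuple(deduped["train"]),
        validation=tuple(deduped["validation"]),
        test=tuple(deduped["test"]),
        ratios=tuple(ratios),
        dedup_removed=removed,
    )


@dataclass(frozen=True)
class ArchitectureSpec:
    """Hyperparameters of the neural classifiers.

    ``decay`` is interpreted as decoupled weight decay by default
    (``decay_mode='weight'``); set ``decay_mode='lr'`` to read it as a
    learning-rate decay instead.
    """

    embedding_dim: int = 300
    n_filters: int = 256
    kernel_widths: tuple[int, ...] = (3, 4, 5)
    dense_units: int = 128
    dropout: float = 0.1
    learning_rate: float = 1e-4
    decay: float = 0.01
    decay_mode: str = "weight"
    batch_size: int = 32
    max_len: int = 64
    max_epochs: int = 50
    patience: int = 5
    lstm_hidden: int = 64
    train_embeddings: bool = True

    def __post_init__(self):
        positive = (
            self.embedding_dim, self.n_filters, self.dense_units,
            self.batch_size, self.max_len, self.max_epochs,
            self.learning_rate, self.lstm_hidden,
        )
        if any(v <= 0 for v in positive):
            raise ValueError("architecture sizes and rates must be positive")
        if any(w > self.max_len for w in self.kernel_widths):
            raise ValueError("kernel widths must not exceed max sequence length")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    def scaled(self, **overrides) -> "ArchitectureSpec":
        return replace(self, **overrides)


@dataclass(frozen=True)
class VeracityPrediction:
    message_id: str
    label: str  # LABEL_TRUE | LABEL_FALSE
    confidence: float  # predicted-class softmax output, in [0.5, 1] for binary

    def to_record(self) -> dict:
        return {
            "id": self.message_id, "label": self.label,
            "confidence": self.confidence,
        }


@dataclass(frozen=True)
class ClassificationMetrics:
    """Macro-averaged metrics on the 0–100 scale plus confusion counts."""

    accuracy: float
    precision: float
    recall: float
    f_score: float
    confusion: tuple[tuple[int, int], tuple[int, int]]  # rows: actual f/t
    n: int

    def to_record(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f_score": self.f_score,
            "confusion": [list(r) for r in self.confusion], "n": self.n,
        }


def _encode(vocab: Vocabulary, msgs: list[NormalizedMessage], max_len: int) -> np.ndarray:
    out = np.zeros((len(msgs), max_len), dtype=np.int64)
    for i, msg in enumerate(msgs):
        ids = vocab.encode(list(msg.tokens)[:max_len])
        out[i, : len(ids)] = ids
    return out


def _bow(vocab: Vocabulary, msgs: list[NormalizedMessage]) -> np.ndarray:
    out = np.zeros((len(msgs), len(vocab)), dtype=np.float64)
    for i, msg in enumerate(msgs):
        for idx in vocab.encode(list(msg.tokens)):
            out[i, idx] += 1
    return out


def _labels_to_y(labels: list[str]) -> np.ndarray:
    try:
        return np.array([_RAW_TO_CLASS[l] for l in labels], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"unknown veracity label: {exc.args[0]!r}") from None


class VeracityClassifier:
    """A trained veracity model bound to its vocabulary and spec."""

    def __init__(self, kind: str, vocab: Vocabulary, spec: ArchitectureSpec,
                 model, majority_label: str, history: list[dict]):
        self.kind = kind
        self.vocab = vocab
        self.spec = spec
        self.model = model
        self.majority_label = majority_label
        self.history = history  # per-epoch validation metrics (neural kinds)

    # -- inference -------------------------------------------------------
    def predict_proba(self, msgs: list[NormalizedMessage]) -> np.ndarray:
        """Class probabilities in canonical order (false, true)."""
        if self.kind in ("cnn", "bilstm"):
            x = _encode(self.vocab, msgs, self.spec.max_len)
            return self.model.predict_proba(x)
        x = _bow(self.vocab, msgs)
        if self.kind == "naive_bayes":
            return self.model.predict_proba(x)
        # linear SVM: map the signed margin through a logistic link
        margin = self.model.decision_function(x)
        p_true = 1.0 / (1.0 + np.exp(-margin))
        return np.stack([1.0 - p_true, p_true], axis=1)

    def predict(self, msgs: list[NormalizedMessage]) -> list[VeracityPrediction]:
        return predict(self, msgs)


def _validation_f(clf_kind, model, vocab, spec, msgs, y) -> float:
    if not msgs:
        return 0.0
    x = _encode(vocab, msgs, spec.max_len)
    probs = model.predict_proba(x)
    pred = probs.argmax(axis=1)
    _, _, f, _ = precision_recall_fscore_support(
        y, pred, average="macro", zero_division=0
    )
    return float(f)


def train_classifier(
    split: DataSplit,
    spec: ArchitectureSpec | None = None,
    model_kind: str = "cnn",
    seed: int = 0,
    embeddings: SubwordEmbeddingTable | None = None,
) -> VeracityClassifier:
    """Train a veracity classifier of the requested kind.

    Neural kinds train with Adam and early stopping on validation macro-F
    (patience from the spec); the best-validation parameters are restored.
    Deterministic given (data, spec, seed).
    """
    spec = spec or ArchitectureSpec()
    if model_kind not in ("cnn", "bilstm", "svm", "naive_bayes"):
        raise ValueError(f"unknown model_kind: {model_kind!r}")
    if not split.train:
        raise ValueError("training set is empty")
    train_msgs = [m for m, _ in split.train]
    y_train = _labels_to_y([l for _, l in split.train])
    if len(set(y_train.tolist())) < 2:
        raise ValueError("training data contains a single class")
    vocab = build_vocabulary(train_msgs, min_count=1)
    majority = _CLASSES[int(np.bincount(y_train, minlength=2).argmax())]
    history: list[dict] = []

    if model_kind in ("svm", "naive_bayes"):
        x = _bow(vocab, train_msgs)
        if model_kind == "svm":
            model = LinearSVC(random_state=seed)
        else:
            model = MultinomialNB()
        model.fit(x, y_train)
        return VeracityClassifier(model_kind, vocab, spec, model, majority, history)

    emb_matrix = None
    if embeddings is not None:
        emb_matrix = np.zeros((len(vocab), spec.embedding_dim))
        for term, idx in vocab.index.items():
            if idx != 0:
                emb_matrix[idx] = embeddings.vector(term)[: spec.embedding_dim]
    if model_kind == "cnn":
        model = TextCNN(
            vocab_size=len(vocab), embedding_dim=spec.embedding_dim,
            n_filters=spec.n_filters, kernel_widths=spec.kernel_widths,
            dense_units=spec.dense_units, dropout=spec.dropout,
            embeddings=emb_matrix, train_embeddings=spec.train_embeddings,
            seed=seed,
        )
    else:
        model = BiLSTMClassifier(
            vocab_size=len(vocab), embedding_dim=spec.embedding_dim,
            hidden=spec.lstm_hidden, embeddings=emb_matrix,
            train_embeddings=spec.train_embeddings, seed=seed,
        )
    opt = AdamState(lr=spec.learning_rate, decay=spec.decay,
                    decay_mode=spec.decay_mode)
    x_train = _encode(vocab, train_msgs, spec.max_len)
    val_msgs = [m for m, _ in split.validation]
    y_val = (
        _labels_to_y([l for _, l in split.validation]) if split.validation else None
    )
    rng = np.random.default_rng(seed + 1)
    best_f, best_params, patience_left = -1.0, None, spec.patience
    for epoch in range(spec.max_epochs):
        order = rng.permutation(len(x_train))
        for start in range(0, len(order), spec.batch_size):
            idx = order[start : start + spec.batch_size]
            model.train_batch(x_train[idx], y_train[idx], opt, epoch=epoch)
        if y_val is None:
            continue
        val_f = _validation_f(model_kind, model, vocab, spec, val_msgs, y_val)
        history.append({"epoch": epoch, "validation_f": val_f * 100})
        if val_f > best_f + 1e-9:
            best_f = val_f
            best_params = copy.deepcopy(model.params)
            patience_left = spec.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    if best_params is not None:
        model.params.update(best_params)
    return VeracityClassifier(model_kind, vocab, spec, model, majority, history)


def predict(classifier: VeracityClassifier,
            msgs: list[NormalizedMessage]) -> list[VeracityPrediction]:
    """Per-message veracity predictions, independent of batch order.

    Empty token sequences get the training majority label at confidence 0.5
    with a warning (there is nothing to classify).
    """
    out: list[VeracityPrediction | None] = [None] * len(msgs)
    nonempty = [(i, m) for i, m in enumerate(msgs) if m.tokens]
    for i, m in enumerate(msgs):
        if not m.tokens:
            warnings.warn(
                f"message {m.id!r} has no tokens; falling back to majority label",
                stacklevel=2,
            )
            out[i] = VeracityPrediction(m.id, classifier.majority_label, 0.5)
    if nonempty:
        probs = classifier.predict_proba([m for _, m in nonempty])
        for (i, m), p in zip(nonempty, probs):
            cls = int(np.argmax(p))
            out[i] = VeracityPrediction(m.id, _CLASSES[cls], float(p[cls]))
    return [p for p in out if p is not None]


def evaluate(classifier: VeracityClassifier,
             test_set: list[LabeledMessage]) -> ClassificationMetrics:
    """Accuracy/precision/recall/F (macro, 0–100) plus the confusion matrix."""
    if not test_set:
        raise ValueError("test set is empty")
    msgs = [m for m, _ in test_set]
    y = _labels_to_y([l for _, l in test_set])
    preds = predict(classifier, msgs)
    y_hat = _labels_to_y([p.label for p in preds])
    return metrics_from_labels(y, y_hat)


def metrics_from_labels(y: np.ndarray, y_hat: np.ndarray) -> ClassificationMetrics:
    accuracy = float(np.mean(y == y_hat)) * 100
    precision, recall, f, _ = precision_recall_fscore_support(
        y, y_hat, average="macro", zero_division=0, labels=[0, 1]
    )
    conf = _sk_confusion(y, y_hat, labels=[0, 1])
    return ClassificationMetrics(
        accuracy=accuracy, precision=float(precision) * 100,
        recall=float(recall) * 100, f_score=float(f) * 100,
        confusion=tuple(tuple(int(v) for v in row) for row in conf),
        n=len(y),
    )


def roc_points(y_true: np.ndarray, scores: np.ndarray) -> dict:
    """ROC curve points and AUC for the true-information score."""
    fpr, tpr, thresholds = _sk_roc_curve(y_true, scores)
    return {
        "fpr": fpr.tolist(), "tpr": tpr.tolist(),
        "thresholds": thresholds.tolist(), "auc": float(_sk_auc(fpr, tpr)),
    }


@dataclass(frozen=True)
class FilterAccounting:
    """Per-class counts (and percentages of the unfiltered class totals)
    after each filter stage — the shape of a staged filter report."""

    stages: tuple[str, ...]
    counts: dict  # stage -> {"false": int, "true": int, "total": int}

    def percentages(self) -> dict:
        base = self.counts[self.stages[0]]
        out = {}
        for stage in self.stages:
            row = self.counts[stage]
            out[stage] = {
                key: (100.0 * row[key] / base[key] if base[key] else 0.0)
                for key in ("false", "true", "total")
            }
        return out

    def to_record(self) -> dict:
        return {"stages": list(self.stages), "counts": self.counts,
                "percentages": self.percentages()}


def _class_counts(preds: list[VeracityPrediction]) -> dict:
    n_false = sum(1 for p in preds if p.label == LABEL_FALSE)
    return {"false": n_false, "true": len(preds) - n_false, "total": len(preds)}


def filter_by_confidence(
    predictions: list[VeracityPrediction],
    threshold: float = 0.998,
    classes: tuple[str, ...] = (LABEL_FALSE, LABEL_TRUE),
) -> tuple[list[VeracityPrediction], FilterAccounting]:
    """Keep predictions with confidence ≥ threshold (both classes by default).

    Restrict ``classes`` to apply the filter to one class only — predictions
    of other classes are then dropped entirely.  Returns the kept
    predictions and a two-stage accounting table.
    """
    if not 0.5 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0.5, 1]")
    kept = [
        p for p in predictions
        if p.label in classes and p.confidence >= threshold
    ]
    accounting = FilterAccounting(
        stages=("no_filter", "confidence_threshold"),
        counts={
            "no_filter": _class_counts(predictions),
            "confidence_threshold": _class_counts(kept),
        },
    )
    return kept, accounting
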