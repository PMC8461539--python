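"""Splitting, training, prediction, evaluation and the confidence filter."""

import numpy as np
import pytest

from riskmine import classify
from riskmine.classify import (
    ArchitectureSpec,
    LABEL_FALSE,
    LABEL_TRUE,
    VeracityPrediction,
    evaluate,
    filter_by_confidence,
    metrics_from_labels,
    predict,
    split_and_dedupe,
    train_classifier,
)
from riskmine.normalize import normalize_text
from riskmine.synthetic import GeneratorConfig, generate_corpus


def _labeled(texts_labels):
    return [
        (normalize_text(t, f"m{i}"), l) for i, (t, l) in enumerate(texts_labels)
    ]


@pytest.fixture(scope="module")
def separable_split():
    """n=2000 corpus with disjoint class vocabularies, no causal assertions."""
    cfg = GeneratorConfig(n_messages=2000, cue_rate=0.0, seed=11)
    corpus = generate_corpus(cfg)
    labeled = [(normalize_text(m.text, m.id), m.label) for m in corpus.messages]
    return split_and_dedupe(labeled, seed=11)


@pytest.fixture(scope="module")
def bench_spec():
    """Desk-scale architecture for the separable benchmark."""
    return ArchitectureSpec().scaled(
        embedding_dim=48, n_filters=64, dense_units=32,
        learning_rate=1e-3, max_epochs=30, max_len=48,
    )


@pytest.fixture(scope="module")
def trained_cnn(separable_split, bench_spec):
    return train_classifier(separable_split, spec=bench_spec,
                            model_kind="cnn", seed=11)


class TestSplitAndDedupe:
    def test_nominal_sizes(self):
        corpus = _labeled(
            [(f"unique message {chr(97 + i)}", "true") for i in range(10)]
        )
        split = split_and_dedupe(corpus, (0.6, 0.2, 0.2), seed=0)
        assert split.sizes() == (6, 2, 2)

    def test_dedup_inside_split_hand_count(self):
        # all 10 land in train (ratios 1/0/0); 2 duplicate one text
        texts = [f"msg {chr(97 + i)}" for i in range(8)] + ["msg a", "msg b"]
        corpus = _labeled([(t, "true") for t in texts])
        split = split_and_dedupe(corpus, (1.0, 0.0, 0.0), seed=3)
        assert len(split.train) == 8
        assert split.dedup_removed["train"] == 2

    def test_split_before_dedup(self):
        # duplicates split across sets survive: dedup is within-split only
        corpus = _labeled([("same text", "true")] * 50)
        split = split_and_dedupe(corpus, (0.6, 0.2, 0.2), seed=1)
        assert split.sizes() == (1, 1, 1)

    def test_same_seed_identical(self):
        corpus = _labeled([(f"m {i}", "true") for i in range(30)])
        s1 = split_and_dedupe(corpus, seed=5)
        s2 = split_and_dedupe(corpus, seed=5)
        assert [m.id for m, _ in s1.train] == [m.id for m, _ in s2.train]

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_and_dedupe(_labeled([("a", "true")]))


class TestTraining:
    def test_cnn_separable_benchmark(self, trained_cnn, separable_split):
        """Disjoint class vocabularies: held-out macro-F reaches 95."""
        metrics = evaluate(trained_cnn, list(separable_split.test))
        assert metrics.f_score >= 95.0
        assert sum(sum(r) for r in metrics.confusion) == metrics.n

    def test_deterministic_given_seed(self, separable_split, bench_spec):
        spec = bench_spec.scaled(max_epochs=3)
        a = train_classifier(separable_split, spec=spec, model_kind="cnn", seed=4)
        b = train_classifier(separable_split, spec=spec, model_kind="cnn", seed=4)
        assert a.history == b.history
        msgs = [m for m, _ in separable_split.test[:20]]
        assert np.allclose(a.predict_proba(msgs), b.predict_proba(msgs))

    def test_naive_bayes_baseline(self, separable_split, trained_cnn, bench_spec):
        nb = train_classifier(separable_split, spec=bench_spec,
                              model_kind="naive_bayes", seed=11)
        m_nb = evaluate(nb, list(separable_split.test))
        m_cnn = evaluate(trained_cnn, list(separable_split.test))
        assert 0 <= m_nb.f_score <= 100
        assert m_nb.f_score <= m_cnn.f_score + 1e-9

    def test_svm_baseline_valid(self, separable_split, bench_spec):
        svm = train_classifier(separable_split, spec=bench_spec,
                               model_kind="svm", seed=11)
        m = evaluate(svm, list(separable_split.test))
        assert 0 <= m.f_score <= 100

    def test_unknown_kind_and_single_class(self):
        corpus = _labeled([(f"m {i}", "true") for i in range(12)])
        split = split_and_dedupe(corpus, seed=0)
        with pytest.raises(ValueError):
            train_classifier(split, model_kind="transformer")
        with pytest.raises(ValueError):
            train_classifier(split, model_kind="svm")


class TestPredict:
    def test_planted_false_terms_predicted_false(self, trained_cnn):
        msg = normalize_text("danger adverse deadly toxic harmful", "p1")
        (pred,) = predict(trained_cnn, [msg])
        assert pred.label == LABEL_FALSE

    def test_confidence_in_argmax_range(self, trained_cnn, separable_split):
        preds = predict(trained_cnn, [m for m, _ in separable_split.test[:50]])
        assert all(0.5 <= p.confidence <= 1.0 for p in preds)

    def test_batch_order_independence(self, trained_cnn, separable_split):
        msgs = [m for m, _ in separable_split.test[:30]]
        fwd = {p.message_id: p for p in predict(trained_cnn, msgs)}
        rev = {p.message_id: p for p in predict(trained_cnn, msgs[::-1])}
        for mid in fwd:
            assert fwd[mid].label == rev[mid].label
            assert fwd[mid].confidence == pytest.approx(rev[mid].confidence)

    def test_empty_message_fallback(self, trained_cnn):
        empty = normalize_text("", "e1")
        with pytest.warns(UserWarning):
            (pred,) = predict(trained_cnn, [empty])
        assert pred.confidence == 0.5
        assert pred.label == trained_cnn.majority_label


class TestEvaluate:
    def test_all_correct_is_100(self):
        y = np.array([0, 1, 0, 1])
        m = metrics_from_labels(y, y.copy())
        assert m.accuracy == m.precision == m.recall == m.f_score == 100.0

    def test_diagonal_confusion_perfect_scores(self):
        y = np.array([0] * 5 + [1] * 5)
        m = metrics_from_labels(y, y.copy())
        assert m.confusion == ((5, 0), (0, 5))
        assert m.f_score == 100.0

    def test_random_guess_near_fifty(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 500)
        y_hat = rng.integers(0, 2, size=1000)
        m = metrics_from_labels(y, y_hat)
        assert 45.0 <= m.accuracy <= 55.0  # binomial bound at n=1000

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 200)
        y_hat = rng.integers(0, 2, 200)
        perm = rng.permutation(200)
        m1 = metrics_from_labels(y, y_hat)
        m2 = metrics_from_labels(y[perm], y_hat[perm])
        assert m1 == m2

    def test_empty_test_set_rejected(self, trained_cnn):
        with pytest.raises(ValueError):
            evaluate(trained_cnn, [])


class TestConfidenceFilter:
    def _preds(self, confs, label=LABEL_FALSE):
        return [VeracityPrediction(f"m{i}", label, c) for i, c in enumerate(confs)]

    def test_threshold_keeps_strictly_confident(self):
        kept, acc = filter_by_confidence(self._preds([0.999, 0.99]), 0.998)
        assert len(kept) == 1
        assert acc.counts["confidence_threshold"]["false"] == 1

    def test_threshold_half_keeps_all(self):
        preds = self._preds([0.5, 0.7, 0.998])
        kept, _ = filter_by_confidence(preds, 0.5)
        assert kept == preds

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        preds = [
            VeracityPrediction(
                f"m{i}", LABEL_FALSE if rng.random() < 0.5 else LABEL_TRUE,
                float(0.5 + 0.5 * rng.random()),
            )
            for i in range(300)
        ]
        kept_sets = []
        for t in (0.5, 0.9, 0.998):
            kept, _ = filter_by_confidence(preds, t)
            kept_sets.append({p.message_id for p in kept})
        assert kept_sets[0] >= kept_sets[1] >= kept_sets[2]

    def test_accounting_matches_brute_recount(self):
        rng = np.random.default_rng(9)
        preds = [
            VeracityPrediction(
                f"m{i}", LABEL_FALSE if rng.random() < 0.4 else LABEL_TRUE,
                float(0.5 + 0.5 * rng.random()),
            )
            for i in range(200)
        ]
        kept, acc = filter_by_confidence(preds, 0.9)
        brute_false = sum(
            1 for p in preds if p.label == LABEL_FALSE and p.confidence >= 0.9
        )
        assert acc.counts["confidence_threshold"]["false"] == brute_false
        pct = acc.percentages()["confidence_threshold"]
        n_false = sum(1 for p in preds if p.label == LABEL_FALSE)
        assert pct["false"] == pytest.approx(100.0 * brute_false / n_false)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            filter_by_confidence([], threshold=0.3)


def test_seed_variability_reporting(separable_split, bench_spec):
    """Mean (SD) reporting across seeds: the protocol, not any fixed value."""
    spec = bench_spec.scaled(max_epochs=4)
    scores = []
    for seed in (0, 1, 2):
        clf = train_classifier(separable_split, spec=spec, model_kind="cnn",
                               seed=seed)
        scores.append(evaluate(clf, list(separable_split.test)).f_score)
    mean, sd = float(np.mean(scores)), float(np.std(scores, ddof=1))
    assert 0 <= mean <= 100 and sd >= 0
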