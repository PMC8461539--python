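"""Effect-phrase embedding, clustering, collapsing, scoring and ranking."""

import math

import numpy as np
import pytest

from riskmine.causal import CandidatePair, build_phrase_vocabularies
from riskmine.collapse import (
    EffectEmbedding,
    EffectPhrase,
    cluster_effect_phrases,
    collapse_to_representatives,
    cumulative_category_score,
    embed_effect_phrase,
    rank_effects,
    score_effect,
)
from riskmine.cooccurrence import build_cooccurrence_model
from riskmine.embeddings import HashingEmbeddingProvider


def _emb(surface, vector, frequency=1):
    return EffectEmbedding(
        phrase=EffectPhrase(frozenset([surface]), surface, frequency),
        vector=np.asarray(vector, dtype=float),
    )


class TestEmbedPhrase:
    provider = HashingEmbeddingProvider(dim=16, seed=0)

    def test_single_token_equals_token_vector(self):
        phrase = EffectPhrase.from_term("pain")
        e = embed_effect_phrase(phrase, self.provider)
        assert np.allclose(e.vector, self.provider.vector("pain"))

    def test_opposite_vectors_cancel(self):
        class PM:
            dim = 4

            def vector(self, token):
                v = np.ones(4)
                return v if token == "a" else -v

        e = embed_effect_phrase(EffectPhrase(frozenset(["a_b"]), "a_b"), PM())
        assert np.allclose(e.vector, 0.0)

    def test_mean_against_hand_average(self):
        phrase = EffectPhrase(frozenset(["premature_ovarian_failure"]),
                              "premature_ovarian_failure")
        e = embed_effect_phrase(phrase, self.provider)
        hand = (
            self.provider.vector("failure")
            + self.provider.vector("ovarian")
            + self.provider.vector("premature")
        ) / 3.0
        assert np.allclose(e.vector, hand)

    def test_provider_failure_names_token(self):
        class Bad:
            dim = 2

            def vector(self, token):
                raise KeyError(token)

        with pytest.raises(RuntimeError, match="pain"):
            embed_effect_phrase(EffectPhrase.from_term("pain"), Bad())


class TestClustering:
    def test_identical_vectors_one_cluster(self):
        embs = [_emb(f"p{i}", [1.0, 2.0, 0.5]) for i in range(5)]
        clustering = cluster_effect_phrases(embs)
        assert clustering.n_clusters == 1

    def test_orthogonal_vectors_two_clusters(self):
        embs = [_emb("a", [1.0, 0.0]), _emb("b", [0.0, 1.0])]
        clustering = cluster_effect_phrases(embs, eps=0.1)
        assert clustering.n_clusters == 2

    def test_planted_duplicates_recover_distinct_count(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((20, 24))
        base /= np.linalg.norm(base, axis=1, keepdims=True)
        embs = []
        for i, v in enumerate(base):
            for j in range(10):  # 10 sub-eps perturbed copies each
                w = v + 1e-4 * rng.standard_normal(24)
                embs.append(_emb(f"p{i}_{j}", w))
        clustering = cluster_effect_phrases(embs, eps=0.1, min_points=1)
        assert clustering.n_clusters == 20
        reps = collapse_to_representatives(clustering)
        assert len(reps) == 20

    def test_min_points_one_no_noise(self):
        rng = np.random.default_rng(1)
        embs = [_emb(f"x{i}", rng.standard_normal(8)) for i in range(30)]
        clustering = cluster_effect_phrases(embs, eps=0.01, min_points=1)
        assert len(clustering.labels) == 30
        assert all(l >= 0 for l in clustering.labels)

    def test_shrinking_eps_never_decreases_clusters(self):
        rng = np.random.default_rng(2)
        embs = [_emb(f"x{i}", rng.standard_normal(8)) for i in range(40)]
        counts = [
            cluster_effect_phrases(embs, eps=e, min_points=1).n_clusters
            for e in (0.5, 0.2, 0.1, 0.05, 0.01)
        ]
        assert counts == sorted(counts)

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            cluster_effect_phrases([_emb("a", [1, 2]), _emb("b", [1, 2, 3])])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cluster_effect_phrases([])


class TestRepresentatives:
    def test_singleton_cluster_is_itself(self):
        clustering = cluster_effect_phrases([_emb("only", [1.0, 1.0])])
        assert collapse_to_representatives(clustering)[0].surface == "only"

    def test_medoid_by_exhaustive_distance_check(self):
        # three co-clustered vectors; medoid = min summed cosine distance
        vecs = [[1.0, 0.0], [0.98, 0.21], [0.9, 0.44]]
        embs = [_emb(f"v{i}", v) for i, v in enumerate(vecs)]
        clustering = cluster_effect_phrases(embs, eps=0.2)
        assert clustering.n_clusters == 1
        rep = collapse_to_representatives(clustering)[0]
        from sklearn.metrics.pairwise import cosine_distances

        d = cosine_distances(np.array(vecs)).sum(axis=1)
        assert rep.surface == f"v{int(np.argmin(d))}"

    def test_bijection_with_clusters(self):
        rng = np.random.default_rng(3)
        embs = [_emb(f"x{i}", rng.standard_normal(6)) for i in range(25)]
        clustering = cluster_effect_phrases(embs, eps=0.15)
        reps = collapse_to_representatives(clustering)
        assert len(reps) == clustering.n_clusters

    def test_tie_broken_by_frequency_then_surface(self):
        v = [1.0, 0.5]
        embs = [_emb("bbb", v, frequency=1), _emb("aaa", v, frequency=5),
                _emb("ccc", v, frequency=5)]
        clustering = cluster_effect_phrases(embs)
        rep = collapse_to_representatives(clustering)[0]
        assert rep.surface == "aaa"  # highest frequency, then lexicographic


def _toy_model():
    pairs = [
        CandidatePair(f"m{i}", "causes", 0, frozenset(c), frozenset(e))
        for i, (c, e) in enumerate(
            [({"q1"}, {"pain"})] * 6
            + [({"q1"}, {"rash"})] * 2
            + [({"q2"}, {"rash"})] * 4
            + [({"q2"}, {"pain"})] * 2
        )
    ]
    from riskmine.causal import PhraseVocabularies

    vocab = PhraseVocabularies(
        cause_terms=frozenset({"q1", "q2"}), effect_terms=frozenset({"pain", "rash"}),
        cause_freq={"q1": 8, "q2": 6}, effect_freq={"pain": 8, "rash": 6},
    )
    return build_cooccurrence_model(pairs, vocab, alpha=0.0)


class TestScoring:
    def test_single_pair_equals_npmi(self):
        model = _toy_model()
        s = score_effect(["q1"], EffectPhrase.from_term("pain"), model)
        assert s.score == pytest.approx(model.npmi("q1", "pain"))
        assert s.n_pairs == 1

    def test_mean_over_enumerated_pairs(self):
        model = _toy_model()
        effect = EffectPhrase(frozenset({"pain", "rash"}), "pain rash")
        s = score_effect(["q1", "q2"], effect, model)
        hand = np.mean([
            model.npmi("q1", "pain"), model.npmi("q1", "rash"),
            model.npmi("q2", "pain"), model.npmi("q2", "rash"),
        ])
        assert s.score == pytest.approx(float(hand), abs=1e-12)
        assert s.n_pairs == 4

    def test_fully_oov_flagged_undefined(self):
        s = score_effect(["q1"], EffectPhrase.from_term("unknown"), _toy_model())
        assert not s.defined and math.isnan(s.score)

    def test_oov_zero_mode(self):
        model = _toy_model()
        effect = EffectPhrase(frozenset({"pain", "unknown"}), "pain unknown")
        skip = score_effect(["q1"], effect, model, oov_mode="skip")
        zero = score_effect(["q1"], effect, model, oov_mode="zero")
        assert skip.n_pairs == 1
        assert zero.n_pairs == 2
        assert zero.score == pytest.approx(skip.score / 2)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            score_effect([], EffectPhrase.from_term("pain"), _toy_model())


class TestRanking:
    def test_single_effect(self):
        ranked = rank_effects(["q1"], [EffectPhrase.from_term("pain")], _toy_model())
        assert len(ranked.ranking) == 1

    def test_scores_non_increasing_and_permutation_invariant(self):
        model = _toy_model()
        effects = [EffectPhrase.from_term("pain"), EffectPhrase.from_term("rash")]
        r1 = rank_effects(["q1"], effects, model)
        r2 = rank_effects(["q1"], effects[::-1], model)
        assert r1.surfaces() == r2.surfaces()
        scores = [s.score for s in r1.ranking]
        assert scores == sorted(scores, reverse=True)

    def test_k_larger_than_effects(self):
        effects = [EffectPhrase.from_term("pain")]
        ranked = rank_effects(["q1"], effects, _toy_model(), k=10)
        assert len(ranked.ranking) == 1  # no padding

    def test_all_undefined_raises(self):
        with pytest.raises(ValueError):
            rank_effects(["q1"], [EffectPhrase.from_term("zz")], _toy_model())

    def test_collapsing_does_not_change_scores(self, mined_pairs):
        """Scores depend only on the co-occurrence model, not on clustering."""
        vocab = build_phrase_vocabularies(mined_pairs)
        model = build_cooccurrence_model(mined_pairs, vocab, alpha=1.0)
        provider = HashingEmbeddingProvider(dim=16, seed=0)
        phrases = [EffectPhrase.from_term(t, vocab.effect_freq[t])
                   for t in sorted(vocab.effect_terms)]
        clustering = cluster_effect_phrases(
            [embed_effect_phrase(p, provider) for p in phrases]
        )
        survivors = collapse_to_representatives(clustering)
        before = {
            p.surface: score_effect(["gardasil"], p, model).score for p in phrases
        }
        for p in survivors:
            after = score_effect(["gardasil"], p, model).score
            assert after == pytest.approx(before[p.surface], nan_ok=True)


class TestCategoryScores:
    def test_single_effect_category(self):
        model = _toy_model()
        pain = EffectPhrase.from_term("pain")
        out = cumulative_category_score(["q1"], {pain: "aches"}, model)
        assert out["aches"]["total"] == pytest.approx(
            score_effect(["q1"], pain, model).score
        )

    def test_totals_conserve_contributions(self):
        model = _toy_model()
        cats = {
            EffectPhrase.from_term("pain"): "aches",
            EffectPhrase.from_term("rash"): "skin",
            EffectPhrase.from_term("zz"): "skin",  # undefined, contributes 0
        }
        out = cumulative_category_score(["q1"], cats, model)
        for cat, rec in out.items():
            assert rec["total"] == pytest.approx(sum(rec["contributions"].values()))
        assert out["skin"]["undefined"] == ["zz"]

    def test_two_category_hand_sums(self):
        model = _toy_model()
        cats = {
            EffectPhrase.from_term("pain"): "a",
            EffectPhrase.from_term("rash"): "b",
        }
        out = cumulative_category_score(["q1", "q2"], cats, model)
        hand_a = np.mean([model.npmi("q1", "pain"), model.npmi("q2", "pain")])
        hand_b = np.mean([model.npmi("q1", "rash"), model.npmi("q2", "rash")])
        assert out["a"]["total"] == pytest.approx(float(hand_a))
        assert out["b"]["total"] == pytest.approx(float(hand_b))
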