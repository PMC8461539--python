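"""Collapsing near-duplicate effect phrases and ranking effects for a query.

Retweet-heavy corpora yield many near-duplicate candidate effect phrases.
Each phrase is embedded as the arithmetic mean of its token vectors, the
embeddings are clustered with DBSCAN under cosine distance (reachability
ε = 0.1, minimum points 1 — so no phrase is ever noise), and each cluster is
collapsed to one representative: its medoid (minimum summed cosine distance
to the cluster's members; ties broken by higher phrase frequency, then
lexicographically).

Ranking is a retrieval problem: for a query ``q`` (a term set naming a
cause) each surviving effect phrase ``e`` receives the mean NPMI over all
pairs ``(w_q, w_e) ∈ (q ∩ V_c) × (e ∩ V_e)``; out-of-vocabulary pairs are
skipped (or zeroed via ``oov_mode='zero'``), and an effect with no scorable
pair is flagged undefined and excluded from the ranking.  Per-category
cumulative scores sum the member effects' scores, keeping the per-effect
contributions for stacked-decomposition reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.metrics.pairwise import cosine_distances

from .cooccurrence import CooccurrenceModel
from .embeddings import EmbeddingProvider

__all__ = [
    "EffectPhrase",
    "EffectEmbedding",
    "EffectClustering",
    "ScoredEffect",
    "RankedEffects",
    "embed_effect_phrase",
    "cluster_effect_phrases",
    "collapse_to_representatives",
    "score_effect",
    "rank_effects",
    "cumulative_category_score",
]


@dataclass(frozen=True)
class EffectPhrase:
    """A candidate effect phrase: V_e-level terms plus a surface form."""

    terms: frozenset[str]
    surface: str
    frequency: int = 1

    @classmethod
    def from_term(cls, term: str, frequency: int = 1) -> "EffectPhrase":
        return cls(terms=frozenset([term]), surface=term, frequency=frequency)

    @property
    def tokens(self) -> list[str]:
        """Constituent word tokens (underscore-joined terms split up)."""
        return [w for t in sorted(self.terms) for w in t.split("_")]


@dataclass(frozen=True)
class EffectEmbedding:
    phrase: EffectPhrase
    vector: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.vector)):
            raise ValueError(f"non-finite embedding for {self.phrase.surface!r}")


def embed_effect_phrase(phrase: EffectPhrase, provider: EmbeddingProvider) -> EffectEmbedding:
    """Mean of the per-token vectors of the phrase's constituent words."""
    tokens = phrase.tokens
    if not tokens:
        raise ValueError("cannot embed an empty effect phrase")
    vectors = []
    for tok in tokens:
        try:
            vectors.append(np.asarray(provider.vector(tok), dtype=float))
        except Exception as exc:
            raise RuntimeError(f"embedding provider failed on token {tok!r}") from exc
    return EffectEmbedding(phrase=phrase, vector=np.mean(vectors, axis=0))


@dataclass(frozen=True)
class EffectClustering:
    embeddings: tuple[EffectEmbedding, ...]
    labels: tuple[int, ...]
    representatives: dict[int, EffectPhrase]
    eps: float
    min_points: int

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels))

    def members(self, cluster: int) -> list[EffectEmbedding]:
        return [e for e, l in zip(self.embeddings, self.labels) if l == cluster]


def _medoid(members: list[EffectEmbedding]) -> EffectPhrase:
    vectors = np.stack([m.vector for m in members])
    dist = cosine_distances(vectors)
    summed = dist.sum(axis=1)
    order = sorted(
        range(len(members)),
        key=lambda i: (
            summed[i],
            -members[i].phrase.frequency,
            members[i].phrase.surface,
        ),
    )
    return members[order[0]].phrase


def cluster_effect_phrases(
    embeddings: Sequence[EffectEmbedding],
    eps: float = 0.1,
    min_points: int = 1,
) -> EffectClustering:
    """DBSCAN over phrase embeddings under cosine distance.

    With ``min_points=1`` every phrase is a core point, so nothing is
    labelled noise and identical vectors always share a cluster.  Cluster
    representatives are medoids.
    """
    if not embeddings:
        raise ValueError("no embeddings to cluster")
    if eps <= 0:
        raise ValueError("reachability eps must be positive")
    if min_points < 1:
        raise ValueError("min_points must be >= 1")
    lengths = {len(e.vector) for e in embeddings}
    if len(lengths) > 1:
        raise ValueError(f"mixed embedding lengths: {sorted(lengths)}")
    x = np.stack([e.vector for e in embeddings])
    labels = DBSCAN(eps=eps, min_samples=min_points, metric="cosine").fit(x).labels_
    # with min_points > 1 DBSCAN may emit noise (-1); give each noise point
    # its own singleton cluster so every phrase stays assigned
    labels = labels.copy()
    next_label = labels.max() + 1 if len(labels) else 0
    for i, l in enumerate(labels):
        if l == -1:
            labels[i] = next_label
            next_label += 1
    clustering_labels = tuple(int(l) for l in labels)
    reps = {
        c: _medoid([e for e, l in zip(embeddings, clustering_labels) if l == c])
        for c in sorted(set(clustering_labels))
    }
    return EffectClustering(
        embeddings=tuple(embeddings), labels=clustering_labels,
        representatives=reps, eps=eps, min_points=min_points,
    )


def collapse_to_representatives(clustering: EffectClustering) -> list[EffectPhrase]:
    """One representative phrase per cluster, in deterministic order."""
    return [
        clustering.representatives[c]
        for c in sorted(clustering.representatives)
    ]


@dataclass(frozen=True)
class ScoredEffect:
    phrase: EffectPhrase
    score: float
    defined: bool = True
    n_pairs: int = 0


def score_effect(
    query: Iterable[str],
    effect: EffectPhrase,
    model: CooccurrenceModel,
    oov_mode: str = "skip",
) -> ScoredEffect:
    """Mean NPMI over all (query term, effect term) pairs.

    ``oov_mode='skip'`` drops pairs whose member is missing from the model's
    vocabularies; ``'zero'`` counts them as 0.  An effect with no remaining
    pair is returned with ``defined=False``.
    """
    q = sorted(set(query))
    if not q:
        raise ValueError("query must be nonempty")
    if oov_mode not in ("skip", "zero"):
        raise ValueError(f"unknown oov_mode: {oov_mode!r}")
    values: list[float] = []
    n_total = 0
    for w_q in q:
        for w_e in sorted(effect.terms):
            n_total += 1
            if model.has_cause(w_q) and model.has_effect(w_e):
                values.append(model.npmi(w_q, w_e))
            elif oov_mode == "zero":
                values.append(0.0)
    if not values:
        return ScoredEffect(phrase=effect, score=float("nan"), defined=False)
    return ScoredEffect(
        phrase=effect, score=float(np.mean(values)), defined=True, n_pairs=len(values)
    )


@dataclass(frozen=True)
class RankedEffects:
    query: tuple[str, ...]
    ranking: tuple[ScoredEffect, ...]  # defined scores, non-increasing
    undefined: tuple[ScoredEffect, ...] = ()
    category_scores: dict = field(default_factory=dict)

    def top(self, k: int) -> list[ScoredEffect]:
        return list(self.ranking[:k])

    def surfaces(self) -> list[str]:
        return [s.phrase.surface for s in self.ranking]


def rank_effects(
    query: Iterable[str],
    effects: Sequence[EffectPhrase],
    model: CooccurrenceModel,
    k: int | None = None,
    oov_mode: str = "skip",
) -> RankedEffects:
    """Rank collapsed effects for a query by mean NPMI, descending.

    Ties break lexicographically on the surface form, so the ranking is
    deterministic and invariant to the input order of the effect list.
    """
    if not effects:
        raise ValueError("no effects to rank")
    scored = [score_effect(query, e, model, oov_mode=oov_mode) for e in effects]
    defined = [s for s in scored if s.defined]
    undefined = [s for s in scored if not s.defined]
    if not defined:
        raise ValueError(
            f"all {len(scored)} effects have undefined scores for query "
            f"{sorted(set(query))!r} (every pair out of vocabulary)"
        )
    defined.sort(key=lambda s: (-s.score, s.phrase.surface))
    if k is not None:
        defined = defined[:k]
    return RankedEffects(
        query=tuple(sorted(set(query))),
        ranking=tuple(defined),
        undefined=tuple(undefined),
    )


def cumulative_category_score(
    query: Iterable[str],
    categories: Mapping[EffectPhrase, str],
    model: CooccurrenceModel,
    oov_mode: str = "skip",
) -> dict[str, dict]:
    """Per-category cumulative NPMI scores with per-effect contributions.

    Each effect contributes its query score to its (single) category; effects
    with undefined scores are recorded but contribute nothing.  The result
    maps category → {"total", "contributions": {surface: score}}.
    """
    out: dict[str, dict] = {}
    for effect, category in categories.items():
        entry = out.setdefault(
            category, {"total": 0.0, "contributions": {}, "undefined": []}
        )
        scored = score_effect(query, effect, model, oov_mode=oov_mode)
        if scored.defined:
            entry["contributions"][effect.surface] = scored.score
            entry["total"] += scored.score
        else:
            entry["undefined"].append(effect.surface)
    return out
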