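"""End-to-end orchestration: simulate → normalize → classify → filter →
cue-screen → extract → co-occurrence → collapse → rank → match.

Stages communicate through files in a working directory (JSONL/TSV/CSV), so
any stage can be inspected or re-run in isolation; the run report carries
per-stage record counts in the shape of a staged filter table (messages
before filtering, after the confidence threshold, after requiring a causal
cue — per predicted class), the ranked effects per query, the gold-lexicon
match report, and run metadata.  Given a seed the whole run is
deterministic; wall-clock timings live in a separate report key so the rest
of the report is reproducible byte for byte.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import causal, collapse, classify, cooccurrence, synthetic
from .embeddings import HashingEmbeddingProvider
from .io import read_gold_lexicon_csv, read_messages, write_jsonl, write_gold_lexicon_csv
from .lexicon import GoldLexicon, MATCH_TYPES, classify_match, match_statistics
from .normalize import normalize_text

__all__ = [
    "PipelineConfig",
    "PipelineReport",
    "PipelineError",
    "run_pipeline",
    "mine_and_rank",
]


class PipelineError(RuntimeError):
    """A stage failure, named after the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    workdir: str = "riskmine_run"
    corpus_path: str | None = None  # JSONL input; None -> simulate
    gold_lexicon_path: str | None = None  # CSV; None -> simulate's lexicon
    simulate: bool = True
    n_messages: int = 500
    train: bool = True
    model_kind: str = "cnn"
    confidence_threshold: float = 0.998
    filter_classes: tuple[str, ...] = (classify.LABEL_FALSE, classify.LABEL_TRUE)
    alpha: float = 1.0
    eps: float = 0.1
    min_points: int = 1
    embedding_dim: int = 32
    queries: tuple[str, ...] = ()
    top_k: int = 10
    oov_mode: str = "skip"
    seed: int = 0
    # desk-scale architecture for the run's classifier
    arch: dict = field(default_factory=lambda: {
        "embedding_dim": 48, "n_filters": 32, "dense_units": 32,
        "learning_rate": 1e-3, "max_epochs": 10, "max_len": 48,
    })

    def validate(self) -> None:
        if not 0.5 <= self.confidence_threshold <= 1.0:
            raise PipelineError("config", "confidence_threshold must lie in [0.5, 1]")
        if self.eps <= 0 or self.min_points < 1 or self.alpha < 0:
            raise PipelineError("config", "eps/min_points/alpha out of range")
        for path_attr in ("corpus_path", "gold_lexicon_path"):
            p = getattr(self, path_attr)
            if p is not None and not Path(p).exists():
                raise PipelineError("config", f"{path_attr} does not exist: {p}")
        if self.corpus_path is None and not self.simulate:
            raise PipelineError("config", "no corpus_path and simulation disabled")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for name in ("filter_classes", "queries"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_yaml(self, path) -> None:
        rec = asdict(self)
        rec["filter_classes"] = list(self.filter_classes)
        rec["queries"] = list(self.queries)
        with open(path, "w") as fh:
            yaml.safe_dump(rec, fh, sort_keys=True)


@dataclass
class PipelineReport:
    stage_counts: dict
    filter_table: dict
    classifier_metrics: dict | None
    rankings: dict
    category_scores: dict
    match_report: dict | None
    metadata: dict
    timings: dict

    def to_record(self) -> dict:
        return {
            "stage_counts": self.stage_counts,
            "filter_table": self.filter_table,
            "classifier_metrics": self.classifier_metrics,
            "rankings": self.rankings,
            "category_scores": self.category_scores,
            "match_report": self.match_report,
            "metadata": self.metadata,
            "timings": self.timings,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_record(), fh, indent=1, sort_keys=True)


def _categorize_effects(effects, gold: GoldLexicon):
    """Assign each collapsed effect to the category of the gold phrase it
    matches best (precedence exact > proper > reverse > partial)."""
    order = {t: i for i, t in enumerate(MATCH_TYPES)}
    assignment = {}
    for eff in effects:
        best = None
        terms = frozenset(eff.tokens)
        for cat, gs in zip(gold.categories, gold.term_sets):
            m = classify_match(gs, terms) if terms else "none"
            if m != "none" and (best is None or order[m] < order[best[0]]):
                best = (m, cat)
        if best is not None:
            assignment[eff] = best[1]
    return assignment


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute every enabled stage; persist all intermediate artifacts.

    Raises :class:`PipelineError` naming the failing stage; artifacts
    written before the failure stay on disk.
    """
    config.validate()
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    stage_counts: dict[str, int] = {}

    def _timed(stage):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, exc_type, exc, tb):
                timings[stage] = round(time.perf_counter() - self_inner.t0, 4)
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(stage, str(exc)) from exc

        return _Ctx()

    # -- simulate --------------------------------------------------------
    gen_config = None
    with _timed("simulate"):
        if config.corpus_path is None:
            gen_config = synthetic.GeneratorConfig(
                n_messages=config.n_messages, seed=config.seed
            )
            corpus = synthetic.generate_corpus(gen_config)
            corpus_path = workdir / "corpus.jsonl"
            corpus.to_jsonl(corpus_path)
            gold_rows = [
                (g.phrase, g.category)
                for g in synthetic.generate_gold_lexicon(gen_config)
            ]
            write_gold_lexicon_csv(gold_rows, workdir / "gold_lexicon.csv")
            gold_path = workdir / "gold_lexicon.csv"
        else:
            corpus_path = Path(config.corpus_path)
            gold_path = (
                Path(config.gold_lexicon_path)
                if config.gold_lexicon_path
                else None
            )

    # -- normalize -------------------------------------------------------
    with _timed("normalize"):
        raw = read_messages(corpus_path)
        stage_counts["raw"] = len(raw)
        normalized = [
            (normalize_text(m.text, message_id=m.id), m.label) for m in raw
        ]
        write_jsonl(
            (
                {"id": n.id, "text": n.text, "label": label}
                for n, label in normalized
            ),
            workdir / "normalized.jsonl",
        )
        stage_counts["normalized"] = len(normalized)

    # -- train -----------------------------------------------------------
    classifier = None
    metrics_record = None
    with _timed("train"):
        labeled = [(n, l) for n, l in normalized if l in ("true", "false")]
        if config.train and labeled:
            split = classify.split_and_dedupe(labeled, seed=config.seed)
            spec = classify.ArchitectureSpec().scaled(**config.arch)
            classifier = classify.train_classifier(
                split, spec=spec, model_kind=config.model_kind, seed=config.seed
            )
            metrics = classify.evaluate(classifier, list(split.test))
            metrics_record = metrics.to_record()
            with open(workdir / "metrics.json", "w") as fh:
                json.dump(metrics_record, fh, indent=1, sort_keys=True)

    # -- predict + confidence filter ------------------------------------
    with _timed("predict"):
        msgs = [n for n, _ in normalized]
        if classifier is not None:
            predictions = classify.predict(classifier, msgs)
        else:  # no classifier: trust provided labels at full confidence
            predictions = [
                classify.VeracityPrediction(
                    n.id,
                    classify.LABEL_FALSE if l == "false" else classify.LABEL_TRUE,
                    1.0,
                )
                for n, l in normalized
            ]
        write_jsonl((p.to_record() for p in predictions),
                    workdir / "predictions.jsonl")
        stage_counts["predicted"] = len(predictions)
    with _timed("confidence_filter"):
        kept, accounting = classify.filter_by_confidence(
            predictions, threshold=config.confidence_threshold,
            classes=tuple(config.filter_classes),
        )
        stage_counts["confident"] = len(kept)

    # -- cue screening + extraction --------------------------------------
    with _timed("extract"):
        lexicon = causal.default_cue_lexicon()
        boundary = {t for cue in lexicon for t in cue.split()}
        chunker = causal.RuleBasedChunker(boundary_words=boundary)
        kept_ids = {p.message_id for p in kept}
        by_id = {n.id: n for n, _ in normalized}
        pairs = []
        cue_messages = 0
        for mid in sorted(kept_ids):
            tokens = by_id[mid].tokens
            found = causal.extract_all_pairs(tokens, lexicon, chunker, mid)
            if found:
                cue_messages += 1
                pairs.extend(found)
        stage_counts["contains_causal_cue"] = cue_messages
        stage_counts["candidate_pairs"] = len(pairs)
        write_jsonl((p.to_record() for p in pairs), workdir / "pairs.jsonl")
        usable = [p for p in pairs if p.cause and p.effect]
        if not usable:
            raise PipelineError(
                "extract", "no non-degenerate candidate pairs were mined"
            )

    # -- co-occurrence model ---------------------------------------------
    with _timed("cooccurrence"):
        vocabularies = causal.build_phrase_vocabularies(usable)
        model = cooccurrence.build_cooccurrence_model(
            usable, vocabularies, alpha=config.alpha
        )
        model.save(workdir / "cooccurrence")

    # -- collapse ---------------------------------------------------------
    with _timed("collapse"):
        provider = HashingEmbeddingProvider(
            dim=config.embedding_dim, seed=config.seed
        )
        phrases = [
            collapse.EffectPhrase.from_term(t, vocabularies.effect_freq[t])
            for t in sorted(vocabularies.effect_terms)
        ]
        embeddings = [collapse.embed_effect_phrase(p, provider) for p in phrases]
        clustering = collapse.cluster_effect_phrases(
            embeddings, eps=config.eps, min_points=config.min_points
        )
        collapsed = collapse.collapse_to_representatives(clustering)
        stage_counts["effects_before_collapse"] = len(phrases)
        stage_counts["effects_after_collapse"] = len(collapsed)
        write_jsonl(
            ({"surface": p.surface, "terms": sorted(p.terms),
              "frequency": p.frequency} for p in collapsed),
            workdir / "collapsed_effects.jsonl",
        )

    # -- rank -------------------------------------------------------------
    rankings: dict[str, list] = {}
    category_scores: dict[str, dict] = {}
    gold = None
    with _timed("rank"):
        if gold_path is not None:
            gold = GoldLexicon.from_rows(read_gold_lexicon_csv(gold_path))
        queries = list(config.queries)
        if not queries and gen_config is not None:
            queries = [a.cause for a in gen_config.planted_associations]
        for q in queries:
            q_terms = [t for t in normalize_text(q).tokens]
            try:
                ranked = collapse.rank_effects(
                    q_terms, collapsed, model, k=config.top_k,
                    oov_mode=config.oov_mode,
                )
            except ValueError:
                rankings[q] = []
                continue
            rankings[q] = [
                {"effect": s.phrase.surface, "score": s.score}
                for s in ranked.ranking
            ]
            if gold is not None:
                assignment = _categorize_effects(collapsed, gold)
                category_scores[q] = {
                    cat: {"total": rec["total"],
                          "contributions": rec["contributions"]}
                    for cat, rec in collapse.cumulative_category_score(
                        q_terms, assignment, model, oov_mode=config.oov_mode
                    ).items()
                }
        with open(workdir / "rankings.json", "w") as fh:
            json.dump(rankings, fh, indent=1, sort_keys=True)

    # -- match -------------------------------------------------------------
    match_record = None
    with _timed("match"):
        if gold is not None:
            report = match_statistics(gold, collapsed)
            report.to_json(workdir / "match_report.json")
            report.to_tsv(workdir / "match_report.tsv")
            match_record = report.to_record()

    three_stage = classify.FilterAccounting(
        stages=("no_filter", "confidence_threshold", "contains_causal_cue"),
        counts={
            **accounting.counts,
            "contains_causal_cue": _cue_stage_counts(
                kept, stage_counts["contains_causal_cue"], pairs
            ),
        },
    )
    filter_table = three_stage.to_record()
    report = PipelineReport(
        stage_counts=stage_counts,
        filter_table=filter_table,
        classifier_metrics=metrics_record,
        rankings=rankings,
        category_scores=category_scores,
        match_report=match_record,
        metadata={
            "seed": config.seed,
            "model_kind": config.model_kind if config.train else None,
            "confidence_threshold": config.confidence_threshold,
            "alpha": config.alpha,
            "eps": config.eps,
            "min_points": config.min_points,
        },
        timings=timings,
    )
    report.save(workdir / "report.json")
    return report


def mine_and_rank(
    texts: list[tuple[str, str]],
    cue_lexicon: causal.CausalCueLexicon | None = None,
    queries: list[str] | None = None,
    alpha: float = 1.0,
    eps: float = 0.1,
    min_points: int = 1,
    embedding_dim: int = 32,
    top_k: int = 10,
    seed: int = 0,
):
    """Mine, collapse and rank effects from raw (id, text) messages in memory.

    The in-memory counterpart of the mining half of :func:`run_pipeline`
    (no classifier): normalize → cue screen → extract → co-occurrence model
    → collapse → rank.  ``cue_lexicon`` defaults to the shipped list; pass a
    corpus-matched lexicon when the cue inventory is known.  Returns
    ``(rankings, model, collapsed, pairs)`` where rankings maps each query
    to its ranked (surface, score) list.
    """
    lexicon = cue_lexicon or causal.default_cue_lexicon()
    chunker = causal.RuleBasedChunker(
        boundary_words={t for cue in lexicon for t in cue.split()}
    )
    pairs = []
    for mid, text in texts:
        tokens = normalize_text(text, mid).tokens
        pairs.extend(causal.extract_all_pairs(tokens, lexicon, chunker, mid))
    usable = [p for p in pairs if p.cause and p.effect]
    if not usable:
        raise PipelineError("extract", "no non-degenerate candidate pairs mined")
    vocabularies = causal.build_phrase_vocabularies(usable)
    model = cooccurrence.build_cooccurrence_model(usable, vocabularies, alpha=alpha)
    provider = HashingEmbeddingProvider(dim=embedding_dim, seed=seed)
    phrases = [
        collapse.EffectPhrase.from_term(t, vocabularies.effect_freq[t])
        for t in sorted(vocabularies.effect_terms)
    ]
    clustering = collapse.cluster_effect_phrases(
        [collapse.embed_effect_phrase(p, provider) for p in phrases],
        eps=eps, min_points=min_points,
    )
    collapsed = collapse.collapse_to_representatives(clustering)
    rankings: dict[str, list[tuple[str, float]]] = {}
    for q in queries or []:
        q_terms = list(normalize_text(q).tokens)
        ranked = collapse.rank_effects(q_terms, collapsed, model, k=top_k)
        rankings[q] = [(s.phrase.surface, s.score) for s in ranked.ranking]
    return rankings, model, collapsed, pairs


def _cue_stage_counts(kept, n_cue_messages: int, pairs) -> dict:
    cue_ids = {p.message_id for p in pairs}
    by_label = {"false": 0, "true": 0}
    for p in kept:
        if p.message_id in cue_ids:
            key = "false" if p.label == classify.LABEL_FALSE else "true"
            by_label[key] += 1
    return {
        "false": by_label["false"],
        "true": by_label["true"],
        "total": n_cue_messages,
    }
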