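"""Synthetic corpus generator with analytic oracles.

Real annotated vaccine-discourse corpora (and the consumer risk-perception
lexicon used to validate mining) are not redistributable, so every stage of
the pipeline is exercised against corpora generated here.  The generator
emulates the statistical structure the pipeline assumes:

* two veracity classes whose discriminative vocabularies are disjoint
  (true-information messages over-sample terms like "prevent", "protect",
  "effective"; false-information messages over-sample "danger", "adverse",
  "deadly") on top of a shared topical vocabulary;
* a fraction of messages carrying a causal cue, each asserting a
  cause → effect relation: with probability ``joint_boost`` the effect is the
  association's planted effect phrase, otherwise a background distractor
  effect, which gives every planted (cause, effect) pair a known population
  joint probability and hence a closed-form NPMI (:func:`expected_npmi`);
* retweet-style exact duplicates emitted after the originals;
* lexical noise — URLs, @-mentions, retweet markers, hashtags, numerals,
  random casing and punctuation — so the normalizer has real work to do.

All randomness flows through one ``numpy`` Generator seeded from the config;
draws happen in documented order, so a fixed config yields byte-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io import write_jsonl

__all__ = [
    "PlantedAssociation",
    "GeneratorConfig",
    "SyntheticMessage",
    "SyntheticCorpus",
    "GoldEntry",
    "generate_corpus",
    "generate_gold_lexicon",
    "expected_npmi",
]


@dataclass(frozen=True)
class PlantedAssociation:
    """A planted cause → effect relation with known joint probability.

    ``joint_boost`` is the probability that a cue message built from this
    association asserts the planted effect phrase rather than a background
    distractor effect.
    """

    cause: str
    effect: tuple[str, ...]
    joint_boost: float

    def __post_init__(self):
        if not self.effect:
            raise ValueError("planted effect phrase must be nonempty")
        if not 0.0 <= self.joint_boost <= 1.0:
            raise ValueError("joint_boost must lie in [0, 1]")


_DEFAULT_TRUE = (
    "prevent", "protect", "effective", "safe", "prevention",
    "immunity", "recommended", "evidence",
)
_DEFAULT_FALSE = (
    "danger", "adverse", "deadly", "toxic", "harmful",
    "injury", "scandal", "coverup",
)
_DEFAULT_SHARED = (
    "shot", "girls", "teens", "doctor", "media", "online",
    "health", "news", "study", "report", "people", "school", "year",
    "cervical", "cancer", "parents", "children", "dose", "clinic",
)
_DEFAULT_CUES = (
    "causes", "caused", "cause", "leads to", "lead to",
    "due to", "linked to", "results in", "triggers",
)
_DEFAULT_ASSOCIATIONS = (
    PlantedAssociation("gardasil", ("premature", "ovarian", "failure"), 0.8),
    PlantedAssociation("hpvvaccine", ("early", "onset", "menopause"), 0.7),
    PlantedAssociation("hpvshot", ("chronic", "pain"), 0.6),
    PlantedAssociation("cervarix", ("sudden", "paralysis"), 0.5),
    PlantedAssociation("silgard", ("lasting", "allergy"), 0.4),
)
# background effect phrases a causal assertion may name instead of the
# planted effect; disjoint from every planted term so planted associations
# have exactly their configured joint probability
_DEFAULT_DISTRACTOR_TERMS = (
    "soreness", "redness", "swelling", "bruising", "itching", "dizziness",
    "headache", "nausea", "drowsiness", "rash", "chills", "cramps",
    "stiffness", "tingling", "weakness", "sweating", "faintness", "aching",
    "tenderness", "irritation",
)


def _default_distractors() -> tuple[tuple[str, ...], ...]:
    terms = _DEFAULT_DISTRACTOR_TERMS
    out = []
    for i in range(30):
        a = terms[i % len(terms)]
        b = terms[(i * 7 + 3) % len(terms)]
        out.append((a,) if a == b else (a, b))
    # de-duplicate while preserving order
    seen: set[tuple[str, ...]] = set()
    uniq = [p for p in out if not (p in seen or seen.add(p))]
    return tuple(uniq)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic corpus.

    Defaults model a misinformation-heavy vaccine discourse: roughly 43% of
    messages carry false information, a fifth of messages assert an explicit
    causal relation, and a quarter of the stream is retweet-style exact
    duplicates.
    """

    n_messages: int = 5000
    class_balance: float = 0.43  # fraction of false-information messages
    vocab_true: tuple[str, ...] = _DEFAULT_TRUE
    vocab_false: tuple[str, ...] = _DEFAULT_FALSE
    vocab_shared: tuple[str, ...] = _DEFAULT_SHARED
    cue_list: tuple[str, ...] = _DEFAULT_CUES
    planted_associations: tuple[PlantedAssociation, ...] = _DEFAULT_ASSOCIATIONS
    distractor_effects: tuple[tuple[str, ...], ...] = field(
        default_factory=_default_distractors
    )
    cue_rate: float = 0.2  # fraction of original messages bearing a causal cue
    class_term_rate: float = 0.35  # per-token prob. of a class-discriminative term
    duplicate_rate: float = 0.25
    noise: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("class_balance", "cue_rate", "class_term_rate", "duplicate_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_messages < 0:
            raise ValueError("n_messages must be non-negative")
        if self.n_messages > 0 and not (
            self.vocab_true and self.vocab_false and self.vocab_shared
        ):
            raise ValueError("vocabulary lists must be nonempty")
        planted = {t for a in self.planted_associations for t in (a.cause, *a.effect)}
        background = set(self.vocab_true) | set(self.vocab_false) | set(self.vocab_shared)
        background |= {t for p in self.distractor_effects for t in p}
        if planted & background:
            raise ValueError(
                "planted cause/effect terms must be disjoint from background "
                f"vocabularies; overlap: {sorted(planted & background)}"
            )

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SyntheticMessage:
    id: str
    text: str
    label: str  # "true" | "false"
    is_duplicate: bool = False
    source_id: str | None = None
    association: int | None = None  # index of planted association, if cue-bearing
    asserts_planted_effect: bool = False

    def to_record(self) -> dict:
        return {"id": self.id, "text": self.text, "label": self.label}


@dataclass(frozen=True)
class SyntheticCorpus:
    messages: tuple[SyntheticMessage, ...]
    config: GeneratorConfig

    def __len__(self) -> int:
        return len(self.messages)

    def to_jsonl(self, path) -> int:
        return write_jsonl((m.to_record() for m in self.messages), path)

    def records(self) -> list[dict]:
        return [m.to_record() for m in self.messages]


def _noise_wrap(tokens: list[str], rng: np.random.Generator, cfg: GeneratorConfig,
                protect_tail: bool) -> str:
    """Inject URL/mention/RT/casing/punctuation noise around a token list.

    When ``protect_tail`` is set (cue messages) insertions only happen at the
    front so the cause → cue → effect structure stays contiguous.
    """
    toks = list(tokens)
    if not cfg.noise:
        return " ".join(toks)
    if rng.random() < 0.3:  # mentions (before the RT marker so "rt" stays leading)
        n_m = int(rng.integers(1, 4))
        mentions = [f"@user{rng.integers(100)}" for _ in range(n_m)]
        pos = 0 if protect_tail else int(rng.integers(0, len(toks) + 1))
        toks[pos:pos] = mentions
    if rng.random() < 0.3:  # leading retweet marker
        toks.insert(0, f"RT @user{rng.integers(100)}:")
    if not protect_tail and rng.random() < 0.2:  # numeral / alphanumeric pairing
        tok = "2x" if rng.random() < 0.5 else str(rng.integers(1990, 2030))
        toks.insert(int(rng.integers(0, len(toks) + 1)), tok)
    if rng.random() < 0.2 and toks:  # hashtag an existing token
        i = int(rng.integers(len(toks)))
        if toks[i].isalpha():
            toks[i] = "#" + toks[i]
    if rng.random() < 0.3 and toks:  # random casing
        i = int(rng.integers(len(toks)))
        toks[i] = toks[i].upper() if rng.random() < 0.5 else toks[i].capitalize()
    if rng.random() < 0.3:  # trailing URL
        toks.append(f"https://t.co/{rng.integers(10**6)}")
    if rng.random() < 0.4:  # punctuation
        toks[-1] = toks[-1] + str(rng.choice(["!", ".", "!!", "?", ","]))
    return " ".join(toks)


def _filler_tokens(rng: np.random.Generator, cfg: GeneratorConfig, label: str) -> list[str]:
    n = int(rng.integers(6, 16))
    class_vocab = cfg.vocab_false if label == "false" else cfg.vocab_true
    toks = []
    for _ in range(n):
        if rng.random() < cfg.class_term_rate:
            toks.append(str(rng.choice(class_vocab)))
        else:
            toks.append(str(rng.choice(cfg.vocab_shared)))
    return toks


def _cue_tokens(rng: np.random.Generator, cfg: GeneratorConfig) -> tuple[list[str], int, bool]:
    k = len(cfg.planted_associations)
    a = int(rng.integers(k))
    assoc = cfg.planted_associations[a]
    planted = bool(rng.random() < assoc.joint_boost)
    if planted:
        effect = assoc.effect
    else:
        effect = cfg.distractor_effects[int(rng.integers(len(cfg.distractor_effects)))]
    cue = str(rng.choice(cfg.cue_list))
    toks = ["the", assoc.cause, cue, *effect]
    return toks, a, planted


def generate_corpus(config: GeneratorConfig) -> SyntheticCorpus:
    """Generate a corpus under the configured study conditions.

    Draw order per original message: label, cue-bearing?, then the
    message-specific draws; duplicates are sampled afterwards and appended
    with fresh ids referencing their source message.
    """
    rng = np.random.default_rng(config.seed)
    n_dup = int(round(config.duplicate_rate * config.n_messages))
    n_orig = config.n_messages - n_dup
    if n_dup > 0 and n_orig == 0:
        raise ValueError("duplicate_rate leaves no original message to copy")
    originals: list[SyntheticMessage] = []
    for i in range(n_orig):
        label = "false" if rng.random() < config.class_balance else "true"
        is_cue = bool(
            config.planted_associations and rng.random() < config.cue_rate
        )
        if is_cue:
            toks, assoc, planted = _cue_tokens(rng, config)
            text = _noise_wrap(toks, rng, config, protect_tail=True)
        else:
            assoc, planted = None, False
            toks = _filler_tokens(rng, config, label)
            text = _noise_wrap(toks, rng, config, protect_tail=False)
        originals.append(
            SyntheticMessage(
                id=f"m{i:06d}", text=text, label=label,
                association=assoc, asserts_planted_effect=planted,
            )
        )
    duplicates: list[SyntheticMessage] = []
    for j in range(n_dup):
        src = originals[int(rng.integers(n_orig))]
        duplicates.append(
            SyntheticMessage(
                id=f"d{j:06d}", text=src.text, label=src.label,
                is_duplicate=True, source_id=src.id,
                association=src.association,
                asserts_planted_effect=src.asserts_planted_effect,
            )
        )
    return SyntheticCorpus(messages=tuple(originals + duplicates), config=config)


@dataclass(frozen=True)
class GoldEntry:
    """One gold-lexicon row plus the match type it is engineered to yield."""

    phrase: str
    category: str
    engineered_match: str  # exact | proper | reverse | partial

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.phrase.split())


def generate_gold_lexicon(config: GeneratorConfig) -> list[GoldEntry]:
    """Engineer a gold risk-perception lexicon from the planted associations.

    For each planted effect phrase E the lexicon gains four phrases: E itself
    (exact match), a strict subset of E (so the mined phrase is a *proper*
    match: a more specific instance of the gold phrase), a strict superset
    (mined phrase is a *reverse* match: more general than gold), and an
    overlapping-but-incomparable phrase (*partial* match).  Each association
    defines one perception category.
    """
    if not config.planted_associations:
        raise ValueError("no planted associations to build a gold lexicon from")
    entries: list[GoldEntry] = []
    for i, assoc in enumerate(config.planted_associations):
        cat = f"category_{i}_{assoc.cause}"
        e = list(assoc.effect)
        entries.append(GoldEntry(" ".join(e), cat, "exact"))
        subset = e[:-1] if len(e) > 1 else e
        entries.append(GoldEntry(" ".join(subset), cat, "proper"))
        entries.append(GoldEntry(" ".join([*e, "extreme"]), cat, "reverse"))
        entries.append(GoldEntry(" ".join([e[0], f"related{i}"]), cat, "partial"))
    return entries


def _population_tables(config: GeneratorConfig):
    """Population (cause, effect-phrase) distribution over cue messages."""
    assocs = config.planted_associations
    if not assocs:
        raise ValueError("config has no planted associations")
    k = len(assocs)
    d = len(config.distractor_effects)
    boosts = np.array([a.joint_boost for a in assocs])
    p_cause = {a.cause: 1.0 / k for a in assocs}
    p_effect: dict[tuple[str, ...], float] = {}
    joint: dict[tuple[str, tuple[str, ...]], float] = {}
    for a, b in zip(assocs, boosts):
        p_effect[a.effect] = b / k
        joint[(a.cause, a.effect)] = b / k
    mean_miss = float(np.mean(1.0 - boosts))
    for phr in config.distractor_effects:
        p_effect[phr] = p_effect.get(phr, 0.0) + mean_miss / d
    for a, b in zip(assocs, boosts):
        for phr in config.distractor_effects:
            joint[(a.cause, phr)] = (1.0 - b) / (k * d)
    return p_cause, p_effect, joint


def _resolve_effect(config: GeneratorConfig, effect_term: str) -> tuple[str, ...]:
    """Map a term, an underscore-joined phrase, or a space-joined phrase to
    the generated effect phrase containing it."""
    phrases = [a.effect for a in config.planted_associations]
    phrases += list(config.distractor_effects)
    for phr in phrases:
        if (
            effect_term in phr
            or effect_term == "_".join(phr)
            or effect_term == " ".join(phr)
        ):
            return phr
    raise KeyError(f"effect term {effect_term!r} is not generated by this config")


def expected_npmi(config: GeneratorConfig, cause_term: str, effect_term: str) -> float:
    """Closed-form population NPMI implied by the generative probabilities.

    Computed from the cue-message model without smoothing: NPMI =
    PMI / (−ln p_joint), with the conventions NPMI = −1 for a never
    co-occurring pair and NPMI = 1 when the joint probability is 1.
    ``effect_term`` may name a single planted term or a whole effect phrase
    (space- or underscore-joined); terms of one phrase always co-occur, so
    the value is the same.
    """
    p_cause, p_effect, joint = _population_tables(config)
    if cause_term not in p_cause:
        raise KeyError(f"cause term {cause_term!r} is not generated by this config")
    phr = _resolve_effect(config, effect_term)
    p_c = p_cause[cause_term]
    p_e = p_effect[phr]
    p_ce = joint.get((cause_term, phr), 0.0)
    if p_ce == 0.0:
        return -1.0
    if p_ce >= 1.0:
        return 1.0
    pmi = math.log(p_ce / (p_c * p_e))
    return pmi / (-math.log(p_ce))
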