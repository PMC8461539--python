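"""Causal-cue screening and candidate cause/effect phrase extraction.

A message asserts a causal relation when it contains a lexical causal cue
("causes", "leads to", "due to", ...).  For every cue occurrence the tokens
to the left of the cue supply the candidate *cause* phrase and the tokens to
the right the candidate *effect* phrase: noun phrases are chunked, multi-word
expressions merged into single underscore-joined terms, and every phrase in
the message is kept regardless of whether it has a syntactic dependency on
the cue.

Parsing is a provider contract: any object with a ``chunk(tokens)`` method
returning noun-phrase chunks can serve.  The default provider is a
deterministic rule-based chunker (maximal runs of content tokens between
stopwords, special tokens and cue words), which needs no model download and
makes extraction reproducible byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Protocol, Sequence

from .normalize import SPECIAL_TOKENS, load_stopwords

__all__ = [
    "CausalCueLexicon",
    "CueOccurrence",
    "CandidatePair",
    "PhraseVocabularies",
    "ParseProvider",
    "RuleBasedChunker",
    "default_cue_lexicon",
    "find_causal_cues",
    "extract_candidate_pair",
    "extract_all_pairs",
    "build_phrase_vocabularies",
]


@dataclass(frozen=True)
class CausalCueLexicon:
    """Ordered list of lower-case causal cue expressions."""

    cues: tuple[str, ...]

    def __post_init__(self):
        if not self.cues:
            raise ValueError("cue lexicon must be nonempty")
        if any(c != c.lower() for c in self.cues):
            raise ValueError("cues must be lower-case")
        if len(set(self.cues)) != len(self.cues):
            raise ValueError("cue lexicon contains duplicates")

    def __iter__(self):
        return iter(self.cues)

    def __len__(self):
        return len(self.cues)

    def tokenized(self) -> list[tuple[str, ...]]:
        return [tuple(c.split()) for c in self.cues]


def default_cue_lexicon() -> CausalCueLexicon:
    """The shipped stand-in cue list (user-replaceable plain-text file)."""
    text = resources.files("riskmine.data").joinpath("causal_cues.txt").read_text()
    cues = []
    for line in text.splitlines():
        line = line.strip().lower()
        if line and not line.startswith("#") and line not in cues:
            cues.append(line)
    return CausalCueLexicon(tuple(cues))


@dataclass(frozen=True)
class CueOccurrence:
    cue: str
    position: int  # token index of the cue's first token

    @property
    def n_tokens(self) -> int:
        return len(self.cue.split())


def find_causal_cues(tokens: Sequence[str], lexicon: CausalCueLexicon) -> list[CueOccurrence]:
    """All non-overlapping cue occurrences, longest match first.

    At each position the longest cue starting there wins; matching then
    resumes after it, so "lead to" suppresses a bare "to" inside it.
    """
    cue_tokens = sorted(lexicon.tokenized(), key=len, reverse=True)
    out: list[CueOccurrence] = []
    i = 0
    n = len(tokens)
    while i < n:
        matched = None
        for ct in cue_tokens:
            k = len(ct)
            if i + k <= n and tuple(tokens[i : i + k]) == ct:
                matched = ct
                break
        if matched:
            out.append(CueOccurrence(cue=" ".join(matched), position=i))
            i += len(matched)
        else:
            i += 1
    return out


class ParseProvider(Protocol):
    """Contract for noun-phrase chunking over a normalized token sequence."""

    def chunk(self, tokens: Sequence[str]) -> list[tuple[int, int]]:
        """Return (start, end) half-open spans of noun-phrase chunks."""
        ...


class RuleBasedChunker:
    """Deterministic chunker: maximal runs of content tokens.

    Stopwords, special tokens (NUMBER/MENTION/RT) and causal cue words act
    as chunk boundaries; what remains between boundaries is treated as one
    noun phrase and later merged into an underscore-joined multi-word term.
    """

    def __init__(self, stopwords: frozenset[str] | None = None,
                 boundary_words: Iterable[str] = ()):
        self.stopwords = stopwords if stopwords is not None else load_stopwords()
        self.boundaries = set(SPECIAL_TOKENS) | set(boundary_words)

    def chunk(self, tokens: Sequence[str]) -> list[tuple[int, int]]:
        spans: list[tuple[int, int]] = []
        start = None
        for i, tok in enumerate(tokens):
            is_boundary = tok in self.stopwords or tok in self.boundaries
            if is_boundary:
                if start is not None:
                    spans.append((start, i))
                    start = None
            elif start is None:
                start = i
        if start is not None:
            spans.append((start, len(tokens)))
        return spans


@dataclass(frozen=True)
class CandidatePair:
    """One causal cue occurrence with its candidate cause and effect sets.

    ``cause``/``effect`` hold underscore-joined phrase terms; either may be
    empty only when ``degenerate`` is set (e.g. a cue at the message start).
    """

    message_id: str
    cue: str
    position: int
    cause: frozenset[str]
    effect: frozenset[str]
    degenerate: bool = False
    surface: dict = field(default_factory=dict, compare=False, hash=False)

    def to_record(self) -> dict:
        return {
            "id": self.message_id,
            "cue": self.cue,
            "position": self.position,
            "cause": sorted(self.cause),
            "effect": sorted(self.effect),
            "degenerate": self.degenerate,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "CandidatePair":
        return cls(
            message_id=rec["id"], cue=rec["cue"], position=rec.get("position", 0),
            cause=frozenset(rec["cause"]), effect=frozenset(rec["effect"]),
            degenerate=rec.get("degenerate", False),
        )


def _phrases_in(spans, tokens, lo, hi) -> frozenset[str]:
    out = set()
    for s, e in spans:
        s2, e2 = max(s, lo), min(e, hi)
        if s2 < e2:
            out.add("_".join(tokens[s2:e2]))
    return frozenset(out)


def extract_candidate_pair(
    tokens: Sequence[str],
    occurrence: CueOccurrence,
    provider: ParseProvider,
    message_id: str = "",
) -> CandidatePair:
    """Extract the candidate pair for one cue occurrence.

    Noun phrases entirely (or partly, clipped) left of the cue populate the
    cause set; phrases right of the cue populate the effect set.  A side
    with no phrase yields a degenerate (but retained) pair.
    """
    cue_tokens = occurrence.cue.split()
    pos, k = occurrence.position, len(cue_tokens)
    if tuple(tokens[pos : pos + k]) != tuple(cue_tokens):
        raise ValueError(
            f"cue {occurrence.cue!r} not found at position {pos} of message "
            f"{message_id!r}"
        )
    try:
        spans = provider.chunk(tokens)
    except Exception as exc:  # parse failure: degenerate pair, not silence
        return CandidatePair(
            message_id=message_id, cue=occurrence.cue, position=pos,
            cause=frozenset(), effect=frozenset(), degenerate=True,
            surface={"parse_error": str(exc)},
        )
    cause = _phrases_in(spans, tokens, 0, pos)
    effect = _phrases_in(spans, tokens, pos + k, len(tokens))
    return CandidatePair(
        message_id=message_id, cue=occurrence.cue, position=pos,
        cause=cause, effect=effect,
        degenerate=not cause or not effect,
    )


def extract_all_pairs(
    tokens: Sequence[str],
    lexicon: CausalCueLexicon,
    provider: ParseProvider,
    message_id: str = "",
) -> list[CandidatePair]:
    """One candidate pair per cue occurrence in the message."""
    return [
        extract_candidate_pair(tokens, occ, provider, message_id)
        for occ in find_causal_cues(tokens, lexicon)
    ]


@dataclass(frozen=True)
class PhraseVocabularies:
    """Cause-side and effect-side term vocabularies with frequencies.

    Stopword terms never enter; hapax terms (corpus frequency 1) are
    excluded.
    """

    cause_terms: frozenset[str]
    effect_terms: frozenset[str]
    cause_freq: dict
    effect_freq: dict


def build_phrase_vocabularies(
    pairs: Iterable[CandidatePair],
    stopwords: frozenset[str] | None = None,
    min_count: int = 2,
) -> PhraseVocabularies:
    """Build ``V_c``/``V_e`` from candidate pairs.

    ``min_count=2`` implements the exclusion of frequency-1 terms; stopwords
    (relevant for single-token phrases) are removed.  Raises ``ValueError``
    with a diagnostic if filtering removes everything.
    """
    stop = stopwords if stopwords is not None else load_stopwords()
    c_freq: dict[str, int] = {}
    e_freq: dict[str, int] = {}
    n = 0
    for pair in pairs:
        n += 1
        for t in pair.cause:
            if t not in stop:
                c_freq[t] = c_freq.get(t, 0) + 1
        for t in pair.effect:
            if t not in stop:
                e_freq[t] = e_freq.get(t, 0) + 1
    if n == 0:
        raise ValueError("no candidate pairs supplied")
    cause_terms = frozenset(t for t, f in c_freq.items() if f >= min_count)
    effect_terms = frozenset(t for t, f in e_freq.items() if f >= min_count)
    if not cause_terms and not effect_terms:
        raise ValueError(
            f"all terms filtered: {len(c_freq)} cause / {len(e_freq)} effect "
            f"terms seen but none reached min_count={min_count}"
        )
    return PhraseVocabularies(
        cause_terms=cause_terms,
        effect_terms=effect_terms,
        cause_freq={t: c_freq[t] for t in cause_terms},
        effect_freq={t: e_freq[t] for t in effect_terms},
    )
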