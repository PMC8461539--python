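"""Matching mined effect phrases against a gold risk-perception lexicon.

A gold lexicon is a curated list of phrases (each in a perception category)
describing how laypeople phrase vaccine risk perceptions.  A mined candidate
effect phrase ``e`` is compared with a gold phrase ``g`` on normalized,
stopword-free term sets under a strict precedence:

* **exact**   — the term sets are equal;
* **proper**  — ``g ⊂ e``: the candidate is a more specific instance of the
  gold phrase (mined "early onset menopause" vs gold "menopause");
* **reverse** — ``e ⊂ g``: the candidate is more general (mined "fatigue"
  vs gold "extreme fatigue");
* **partial** — the sets merely intersect (mined "prevent throat cancer"
  vs gold "prevent cervical cancer");
* **none**    — disjoint sets.

Coverage statistics are non-exclusive per gold phrase across candidates: a
gold phrase counts toward every match type some candidate achieves against
it, so the per-type tallies may overlap and sum to more than the
partial-or-proper union count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .collapse import EffectPhrase
from .normalize import load_stopwords, normalize_text

__all__ = [
    "GoldLexicon",
    "MATCH_TYPES",
    "classify_match",
    "match_statistics",
    "MatchReport",
]

MATCH_TYPES = ("exact", "proper", "reverse", "partial")


def _phrase_terms(phrase: str, stopwords: frozenset[str]) -> frozenset[str]:
    tokens = normalize_text(phrase.replace("_", " ")).tokens
    return frozenset(t for t in tokens if t not in stopwords)


@dataclass(frozen=True)
class GoldLexicon:
    """Gold phrases with their categories, normalized for matching."""

    phrases: tuple[str, ...]
    categories: tuple[str, ...]
    term_sets: tuple[frozenset[str], ...]

    def __post_init__(self):
        if not self.phrases:
            raise ValueError("gold lexicon must be nonempty")
        if any(not c for c in self.categories):
            raise ValueError("gold categories must be nonempty strings")
        if any(not ts for ts in self.term_sets):
            raise ValueError("gold phrases must normalize to nonempty term sets")

    def __len__(self) -> int:
        return len(self.phrases)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str]],
                  stopwords: frozenset[str] | None = None) -> "GoldLexicon":
        stop = stopwords if stopwords is not None else load_stopwords()
        phrases, categories, term_sets = [], [], []
        for phrase, category in rows:
            phrases.append(phrase)
            categories.append(category)
            term_sets.append(_phrase_terms(phrase, stop))
        return cls(tuple(phrases), tuple(categories), tuple(term_sets))


def classify_match(g: frozenset[str] | Sequence[str],
                   e: frozenset[str] | Sequence[str]) -> str:
    """Classify one (gold, candidate) pair; exclusive under precedence.

    Precedence: exact > proper > reverse > partial > none.  Both inputs are
    term sets (already normalized and stopword-free).
    """
    gs, es = frozenset(g), frozenset(e)
    if not gs or not es:
        raise ValueError("cannot match an empty phrase")
    if gs == es:
        return "exact"
    if gs < es:
        return "proper"
    if es < gs:
        return "reverse"
    if gs & es:
        return "partial"
    return "none"


@dataclass(frozen=True)
class MatchReport:
    """Coverage of a gold lexicon by a candidate effect set."""

    n_gold: int
    per_phrase: dict  # gold phrase -> sorted list of achieved match types
    counts: dict  # match type -> number of gold phrases achieving it
    union_partial_or_proper: int
    warnings: tuple[str, ...] = field(default=())

    def percentages(self) -> dict:
        out = {
            t: round(100.0 * self.counts[t] / self.n_gold, 1)
            for t in MATCH_TYPES
        }
        out["partial_or_proper"] = round(
            100.0 * self.union_partial_or_proper / self.n_gold, 1
        )
        return out

    def to_record(self) -> dict:
        return {
            "n_gold": self.n_gold,
            "per_phrase": self.per_phrase,
            "counts": self.counts,
            "union_partial_or_proper": self.union_partial_or_proper,
            "percentages": self.percentages(),
            "warnings": list(self.warnings),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_record(), fh, indent=1, sort_keys=True)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("match_type\tcount\tpercent\n")
            pct = self.percentages()
            for t in MATCH_TYPES:
                fh.write(f"{t}\t{self.counts[t]}\t{pct[t]}\n")
            fh.write(
                f"partial_or_proper\t{self.union_partial_or_proper}\t"
                f"{pct['partial_or_proper']}\n"
            )


def match_statistics(
    gold: GoldLexicon,
    candidates: Sequence[EffectPhrase | frozenset[str]],
    stopwords: frozenset[str] | None = None,
) -> MatchReport:
    """Coverage counts and percentages of the gold lexicon.

    A gold phrase counts toward match type X if *any* candidate achieves X
    against it; a single phrase can therefore count toward several types.
    An empty candidate set yields a report of zeros with a warning.
    """
    stop = stopwords if stopwords is not None else load_stopwords()
    cand_sets: list[frozenset[str]] = []
    for c in candidates:
        if isinstance(c, EffectPhrase):
            cand_sets.append(_phrase_terms(" ".join(c.tokens), stop))
        else:
            cand_sets.append(frozenset(c))
    cand_sets = [c for c in cand_sets if c]
    warnings_: list[str] = []
    if not cand_sets:
        warnings_.append("empty candidate effect set; all coverage counts are zero")
    per_phrase: dict[str, list[str]] = {}
    counts = {t: 0 for t in MATCH_TYPES}
    union = 0
    for phrase, gs in zip(gold.phrases, gold.term_sets):
        achieved = {
            m
            for cs in cand_sets
            if (m := classify_match(gs, cs)) != "none"
        }
        per_phrase[phrase] = sorted(achieved)
        for t in achieved:
            counts[t] += 1
        if achieved & {"partial", "proper"}:
            union += 1
    return MatchReport(
        n_gold=len(gold),
        per_phrase=per_phrase,
        counts=counts,
        union_partial_or_proper=union,
        warnings=tuple(warnings_),
    )
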