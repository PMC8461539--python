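"""Cause–effect co-occurrence model with Laplace-smoothed PMI/NPMI.

Given the candidate pairs mined from cue-bearing messages — pair ``i``
holding a cause phrase ``c_i`` (a set of terms from the cause vocabulary
``V_c``) and an effect phrase ``e_j`` (terms from ``V_e``) — the model
maintains a joint count table over ``V_c × V_e``.  Each pair increments the
cell ``(w_c, w_e)`` once for every ``w_c ∈ c_i ∩ V_c`` and
``w_e ∈ e_j ∩ V_e`` (set semantics: within-phrase multiplicity is ignored).

Probabilities come from the smoothed joint table, normalized to sum to one,
with marginals derived as row/column sums — which guarantees the marginals
are consistent with the joint.  With smoothing constant α > 0 every
probability is strictly positive and PMI is finite.

PMI(w_c, w_e)  = log p(w_c, w_e) / (p(w_c) p(w_e))
NPMI(w_c, w_e) = PMI / (−log p(w_c, w_e)) ∈ [−1, 1]

NPMI is −1 for a pair that never co-occurs (α = 0 convention), 0 for a
statistically independent pair, and 1 for complete co-occurrence (guarded as
the p → 1 limit).  NPMI is invariant to the log base; the base only rescales
PMI.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .causal import CandidatePair, PhraseVocabularies

__all__ = ["CooccurrenceModel", "build_cooccurrence_model"]


@dataclass
class CooccurrenceModel:
    """Joint/marginal probability tables over ``V_c × V_e``.

    Attributes
    ----------
    cause_terms, effect_terms
        Sorted vocabularies; row/column order of ``counts``.
    counts
        Raw (unsmoothed) joint count table, shape ``(|V_c|, |V_e|)``.
    n_pairs
        Number of candidate pairs counted (``m``).
    alpha
        Laplace smoothing constant added to every joint cell.
    base
        Log base for PMI (NPMI is base-invariant).
    """

    cause_terms: tuple[str, ...]
    effect_terms: tuple[str, ...]
    counts: np.ndarray
    n_pairs: int
    alpha: float = 1.0
    base: float = math.e

    def __post_init__(self):
        self._ci = {t: i for i, t in enumerate(self.cause_terms)}
        self._ei = {t: i for i, t in enumerate(self.effect_terms)}
        self._refresh()

    def _refresh(self) -> None:
        smoothed = self.counts.astype(float) + self.alpha
        total = smoothed.sum()
        if total <= 0:
            raise ValueError("co-occurrence table is empty and unsmoothed")
        self.p_joint = smoothed / total
        self.p_cause = self.p_joint.sum(axis=1)
        self.p_effect = self.p_joint.sum(axis=0)

    # -- lookups ---------------------------------------------------------
    def _idx(self, w_c: str, w_e: str) -> tuple[int, int]:
        if w_c not in self._ci:
            raise KeyError(f"unknown cause term: {w_c!r}")
        if w_e not in self._ei:
            raise KeyError(f"unknown effect term: {w_e!r}")
        return self._ci[w_c], self._ei[w_e]

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair[0] in self._ci and pair[1] in self._ei

    def has_cause(self, term: str) -> bool:
        return term in self._ci

    def has_effect(self, term: str) -> bool:
        return term in self._ei

    # -- information measures -------------------------------------------
    def pmi(self, w_c: str, w_e: str) -> float:
        """Pointwise mutual information in the model's log base."""
        i, j = self._idx(w_c, w_e)
        p_ce = self.p_joint[i, j]
        p_c, p_e = self.p_cause[i], self.p_effect[j]
        if p_ce == 0.0:
            return -math.inf
        return math.log(p_ce / (p_c * p_e), self.base)

    def npmi(self, w_c: str, w_e: str) -> float:
        """Normalized PMI in [−1, 1]; base-invariant.

        Conventions: a zero joint probability (possible only with α = 0)
        yields −1; a joint probability of exactly 1 yields 1 (the limit of
        PMI / −log p as p → 1, guarding the division by zero).
        """
        i, j = self._idx(w_c, w_e)
        p_ce = self.p_joint[i, j]
        if p_ce == 0.0:
            return -1.0
        if p_ce >= 1.0:
            return 1.0
        p_c, p_e = self.p_cause[i], self.p_effect[j]
        value = math.log(p_ce / (p_c * p_e)) / (-math.log(p_ce))
        # clip floating-point overshoot at the boundaries
        return min(1.0, max(-1.0, value))

    # -- persistence -----------------------------------------------------
    def save(self, prefix) -> None:
        """Persist as sparse triplets (TSV) plus a JSON header."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        with open(prefix.with_suffix(".counts.tsv"), "w") as fh:
            fh.write("cause\teffect\tcount\n")
            rows, cols = np.nonzero(self.counts)
            for i, j in zip(rows.tolist(), cols.tolist()):
                fh.write(
                    f"{self.cause_terms[i]}\t{self.effect_terms[j]}\t"
                    f"{int(self.counts[i, j])}\n"
                )
        header = {
            "alpha": self.alpha,
            "base": self.base,
            "n_pairs": self.n_pairs,
            "cause_terms": list(self.cause_terms),
            "effect_terms": list(self.effect_terms),
            "vocab_hash": _vocab_hash(self.cause_terms, self.effect_terms),
        }
        with open(prefix.with_suffix(".header.json"), "w") as fh:
            json.dump(header, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, prefix) -> "CooccurrenceModel":
        prefix = Path(prefix)
        with open(prefix.with_suffix(".header.json")) as fh:
            header = json.load(fh)
        cause_terms = tuple(header["cause_terms"])
        effect_terms = tuple(header["effect_terms"])
        if header["vocab_hash"] != _vocab_hash(cause_terms, effect_terms):
            raise ValueError("vocabulary hash mismatch in persisted model")
        ci = {t: i for i, t in enumerate(cause_terms)}
        ei = {t: i for i, t in enumerate(effect_terms)}
        counts = np.zeros((len(cause_terms), len(effect_terms)), dtype=np.int64)
        with open(prefix.with_suffix(".counts.tsv")) as fh:
            next(fh)
            for line in fh:
                c, e, n = line.rstrip("\n").split("\t")
                counts[ci[c], ei[e]] = int(n)
        return cls(
            cause_terms=cause_terms, effect_terms=effect_terms, counts=counts,
            n_pairs=header["n_pairs"], alpha=header["alpha"], base=header["base"],
        )


def _vocab_hash(cause_terms: Sequence[str], effect_terms: Sequence[str]) -> str:
    h = hashlib.sha256()
    for t in cause_terms:
        h.update(t.encode() + b"\0")
    h.update(b"\1")
    for t in effect_terms:
        h.update(t.encode() + b"\0")
    return h.hexdigest()


def build_cooccurrence_model(
    pairs: Iterable[CandidatePair],
    vocabularies: PhraseVocabularies,
    alpha: float = 1.0,
    base: float = math.e,
) -> CooccurrenceModel:
    """Count (cause term, effect term) co-occurrences over candidate pairs.

    Raises ``ValueError`` if the vocabularies are empty or no pair
    contributes a single counted (w_c, w_e) combination while α = 0.
    """
    cause_terms = tuple(sorted(vocabularies.cause_terms))
    effect_terms = tuple(sorted(vocabularies.effect_terms))
    if not cause_terms or not effect_terms:
        raise ValueError("cause/effect vocabularies must be nonempty")
    ci = {t: i for i, t in enumerate(cause_terms)}
    ei = {t: i for i, t in enumerate(effect_terms)}
    counts = np.zeros((len(cause_terms), len(effect_terms)), dtype=np.int64)
    m = 0
    for pair in pairs:
        m += 1
        for w_c in set(pair.cause) & vocabularies.cause_terms:
            for w_e in set(pair.effect) & vocabularies.effect_terms:
                counts[ci[w_c], ei[w_e]] += 1
    if m == 0:
        raise ValueError("no candidate pairs supplied")
    if counts.sum() == 0 and alpha == 0:
        raise ValueError(
            "no pair contributed any counted (cause, effect) combination "
            "and alpha=0 leaves the table degenerate"
        )
    return CooccurrenceModel(
        cause_terms=cause_terms, effect_terms=effect_terms,
        counts=counts, n_pairs=m, alpha=alpha, base=base,
    )
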