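"""Rule-based lexical normalization for short social-media health messages.

The normalizer reduces the surface variety of informal short text (tweets and
tweet-like messages) before any downstream modelling: casing, URLs, numerals,
user mentions, retweet markers, contractions, punctuation and whitespace are
all canonicalised by a fixed, ordered sequence of rules.  Three special tokens
survive normalization in upper case — ``NUMBER``, ``MENTION`` and ``RT`` — so
that the classifier and the causality miner can treat them as vocabulary terms
while never confusing them with ordinary words (ordinary text is lower-cased).

The rule order is part of the contract and is applied by :func:`normalize_text`:

1. lower-case (special tokens exempt);
2. remove URLs;
3. map retweet markers to ``RT``, user mentions to ``MENTION`` and numeral
   runs to ``NUMBER`` (letter–digit pairings such as ``2x`` are split first);
4. expand contractions from the shipped, editable table (``can't``→``cannot``,
   ``&``→``and``, ...);
5. replace hyphens and forward slashes with spaces;
6. strip hashtag marks and all remaining punctuation;
7. collapse runs of two or more ``MENTION`` tokens to exactly two;
8. collapse whitespace.

The function is total (never raises on a string) and idempotent.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

__all__ = [
    "NormalizedMessage",
    "Vocabulary",
    "normalize_text",
    "tokenize",
    "build_vocabulary",
    "frequency_odds_ratio",
    "load_contractions",
    "load_stopwords",
    "SPECIAL_TOKENS",
    "PAD_TOKEN",
    "OOV_TOKEN",
]

#: Tokens with reserved vocabulary indices, in index order.
PAD_TOKEN = "<pad>"
OOV_TOKEN = "<oov>"
SPECIAL_TOKENS = ("NUMBER", "MENTION", "RT")
RESERVED_TOKENS = (PAD_TOKEN, OOV_TOKEN) + SPECIAL_TOKENS

_URL_RE = re.compile(r"(?:https?://\S+|www\.\S+)", re.IGNORECASE)
_MENTION_RE = re.compile(r"@\w+")
_RT_LEADING_RE = re.compile(r"^(?:rt)\b[:\s]*")
_LETTER_DIGIT_RE = re.compile(r"(?<=[a-z])(?=\d)|(?<=\d)(?=[a-z])")
_NUMERAL_RE = re.compile(r"\d+(?:[.,]\d+)*")
_HYPHEN_SLASH_RE = re.compile(r"[-/]+")
_MENTION_RUN_RE = re.compile(r"\bMENTION(?:\s+MENTION)+\b")
_PUNCT_RE = re.compile(r"[^a-zA-Z0-9 ]+")
_WS_RE = re.compile(r"\s+")
_SPECIAL_OR_OTHER_RE = re.compile(
    r"(?<![A-Za-z0-9])(?:NUMBER|MENTION|RT)(?![A-Za-z0-9])|.", re.DOTALL
)


def load_contractions() -> dict[str, str]:
    """Load the shipped contraction table (editable CSV, column pair)."""
    text = resources.files("riskmine.data").joinpath("contractions.csv").read_text()
    reader = csv.DictReader(text.splitlines())
    return {row["contraction"]: row["expansion"] for row in reader}


def load_stopwords() -> frozenset[str]:
    """Load the shipped English stopword list."""
    text = resources.files("riskmine.data").joinpath("stopwords.txt").read_text()
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


_CONTRACTIONS = load_contractions()
_CONTRACTION_RE = re.compile(
    "|".join(
        # longest first so "can't" wins over a hypothetical "can"
        re.escape(c)
        for c in sorted(_CONTRACTIONS, key=len, reverse=True)
    )
)


@dataclass(frozen=True)
class NormalizedMessage:
    """A message after lexical normalization."""

    id: str
    text: str
    tokens: tuple[str, ...] = field(default=())
    special_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)


def _lowercase_preserving_specials(text: str) -> str:
    # Exact upper-case NUMBER/MENTION/RT tokens are already normalized output
    # and must survive a second pass (idempotence); everything else lower-cases.
    def repl(m: re.Match[str]) -> str:
        s = m.group(0)
        return s if len(s) > 1 else s.lower()

    return _SPECIAL_OR_OTHER_RE.sub(repl, text)


def _expand_contractions(text: str) -> str:
    def repl(m: re.Match[str]) -> str:
        s = m.group(0)
        # word-ish contractions need word boundaries; symbol ones ("&") do not
        start, end = m.start(), m.end()
        if s[0].isalnum() and start > 0 and (text[start - 1].isalnum()):
            return s
        if s[-1].isalnum() and end < len(text) and text[end].isalnum():
            return s
        # padded so a symbol expansion ("&"->"and") never glues onto a
        # neighbouring token; whitespace collapses later
        return f" {_CONTRACTIONS[s]} "

    return _CONTRACTION_RE.sub(repl, text)


def normalize_text(raw: str, message_id: str = "") -> NormalizedMessage:
    """Apply the full ordered normalization rule set to a raw message.

    Total function: any input string yields a (possibly empty) normalized
    message.  See the module docstring for the rule order.
    """
    text = _lowercase_preserving_specials(raw)
    text = _URL_RE.sub(" ", text)
    # retweet marker: leading "rt" token (incl. "rt @user:" dialect)
    text = _RT_LEADING_RE.sub("RT ", text)
    # pad the special token so a mention glued to a word stays separable
    text = _MENTION_RE.sub(" MENTION ", text)
    text = _LETTER_DIGIT_RE.sub(" ", text)
    text = _NUMERAL_RE.sub("NUMBER", text)
    text = _expand_contractions(text)
    text = _HYPHEN_SLASH_RE.sub(" ", text)
    text = _PUNCT_RE.sub(" ", text)
    # run collapse last so mentions separated only by punctuation also merge
    text = _MENTION_RUN_RE.sub("MENTION MENTION", text)
    text = _WS_RE.sub(" ", text).strip()
    tokens = tuple(text.split(" ")) if text else ()
    counts = {t: 0 for t in SPECIAL_TOKENS}
    for tok in tokens:
        if tok in counts:
            counts[tok] += 1
    return NormalizedMessage(id=message_id, text=text, tokens=tokens, special_counts=counts)


def tokenize(msg: NormalizedMessage | str) -> list[str]:
    """Whitespace tokenization of a normalized message (specials kept whole)."""
    text = msg.text if isinstance(msg, NormalizedMessage) else msg
    return text.split(" ") if text else []


@dataclass(frozen=True)
class Vocabulary:
    """Term → contiguous integer index plus corpus frequencies.

    Indices 0..4 are reserved for padding, out-of-vocabulary and the three
    special tokens; content terms follow ordered by frequency (descending)
    then lexicographically, which makes index assignment deterministic.
    """

    index: dict[str, int]
    frequency: dict[str, int]

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, term: str) -> bool:
        return term in self.index

    def encode(self, tokens: Sequence[str]) -> list[int]:
        oov = self.index[OOV_TOKEN]
        return [self.index.get(t, oov) for t in tokens]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("term\tindex\tfrequency\n")
            for term, idx in sorted(self.index.items(), key=lambda kv: kv[1]):
                fh.write(f"{term}\t{idx}\t{self.frequency.get(term, 0)}\n")

    @classmethod
    def from_tsv(cls, path) -> "Vocabulary":
        index: dict[str, int] = {}
        frequency: dict[str, int] = {}
        with open(path) as fh:
            next(fh)
            for line in fh:
                term, idx, freq = line.rstrip("\n").split("\t")
                index[term] = int(idx)
                frequency[term] = int(freq)
        return cls(index=index, frequency=frequency)


def build_vocabulary(corpus: Iterable[NormalizedMessage], min_count: int = 1) -> Vocabulary:
    """Build the term vocabulary from a normalized corpus.

    Every term with corpus frequency >= ``min_count`` is included, after the
    five reserved tokens.  Raises ``ValueError`` on an empty corpus.
    """
    freq: dict[str, int] = {}
    n_msgs = 0
    for msg in corpus:
        n_msgs += 1
        for tok in msg.tokens:
            freq[tok] = freq.get(tok, 0) + 1
    if n_msgs == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    index: dict[str, int] = {t: i for i, t in enumerate(RESERVED_TOKENS)}
    content = [
        t
        for t in freq
        if t not in index and freq[t] >= min_count
    ]
    content.sort(key=lambda t: (-freq[t], t))
    for t in content:
        index[t] = len(index)
    return Vocabulary(index=index, frequency=freq)


def frequency_odds_ratio(
    messages: Iterable[tuple[NormalizedMessage, str]],
    term: str,
    true_label: str = "true",
    false_label: str = "false",
) -> float:
    """Odds ratio of a term's per-message occurrence in true vs false messages.

    Counts messages (not token multiplicity) containing the term in each
    veracity category and forms the 2x2 odds ratio with the Haldane–Anscombe
    +0.5 correction on all four cells.  Values above 1 mean the term is
    over-represented in the true-information category.
    """
    a = b = c = d = 0  # a: true & present, b: true & absent, c/d: false
    seen = False
    labels_seen: set[str] = set()
    for msg, label in messages:
        labels_seen.add(label)
        present = term in msg.tokens
        seen = seen or present
        if label == true_label:
            a, b = a + present, b + (not present)
        elif label == false_label:
            c, d = c + present, d + (not present)
    if not {true_label, false_label} <= labels_seen:
        raise ValueError("both veracity categories must be present in the corpus")
    if not seen:
        raise KeyError(f"term {term!r} does not occur in the corpus")
    return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))


def log_frequency_odds_ratio(messages, term, **kw) -> float:
    """Natural log of :func:`frequency_odds_ratio` (symmetric around 0)."""
    return math.log(frequency_odds_ratio(messages, term, **kw))
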