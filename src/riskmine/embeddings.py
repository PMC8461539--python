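"""Word-embedding providers.

Two kinds of providers back the pipeline, both satisfying the same
token → vector contract:

* :class:`HashingEmbeddingProvider` — a seeded, fully deterministic provider
  that derives a unit vector from a hash of the token.  It carries no
  semantics but is stable across runs and machines, which is exactly what
  clustering and arithmetic tests need.
* :func:`pretrain_embeddings` — an unsupervised, subword-augmented
  word-embedding trainer: it factorises the positive PMI word–context
  co-occurrence matrix of the corpus with a truncated SVD, and represents
  each word as the sum of its character n-gram (subword) vectors plus its
  own vector, so out-of-vocabulary words still resolve to finite vectors by
  subword composition.  Words appearing in similar contexts end up with
  similar vectors.

Any other object implementing ``vector(token) -> ndarray`` (for instance a
contextual-transformer wrapper) can be dropped in.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from sklearn.utils.extmath import randomized_svd

__all__ = [
    "EmbeddingProvider",
    "HashingEmbeddingProvider",
    "SubwordEmbeddingTable",
    "pretrain_embeddings",
]


class EmbeddingProvider(Protocol):
    dim: int

    def vector(self, token: str) -> np.ndarray: ...


@dataclass
class HashingEmbeddingProvider:
    """Deterministic unit vectors from a salted hash of the token.

    Identical tokens always map to identical vectors regardless of process,
    platform or call order; different seeds give independent tables.
    """

    dim: int = 32
    seed: int = 0

    def vector(self, token: str) -> np.ndarray:
        if not token:
            raise ValueError("cannot embed an empty token")
        digest = hashlib.sha256(f"{self.seed}\0{token}".encode()).digest()
        sub_seed = int.from_bytes(digest[:8], "little") % (2**31)
        rng = np.random.default_rng(sub_seed)
        v = rng.standard_normal(self.dim)
        return v / np.linalg.norm(v)


def _char_ngrams(word: str, n_min: int = 3, n_max: int = 5) -> list[str]:
    padded = f"<{word}>"
    grams = []
    for n in range(n_min, n_max + 1):
        grams.extend(padded[i : i + n] for i in range(len(padded) - n + 1))
    return grams


class SubwordEmbeddingTable:
    """Word vectors composable from character n-gram vectors.

    ``vector(token)`` returns the stored vector for an in-vocabulary token;
    for an out-of-vocabulary token it averages the vectors of the token's
    known character n-grams, falling back to a deterministic hash vector if
    no subword is known.
    """

    def __init__(self, dim: int, word_vectors: dict[str, np.ndarray],
                 subword_vectors: dict[str, np.ndarray], seed: int = 0):
        self.dim = dim
        self.word_vectors = word_vectors
        self.subword_vectors = subword_vectors
        self._fallback = HashingEmbeddingProvider(dim=dim, seed=seed)

    def __contains__(self, token: str) -> bool:
        return token in self.word_vectors

    def __len__(self) -> int:
        return len(self.word_vectors)

    def vector(self, token: str) -> np.ndarray:
        if not token:
            raise ValueError("cannot embed an empty token")
        if token in self.word_vectors:
            return self.word_vectors[token]
        known = [
            self.subword_vectors[g]
            for g in _char_ngrams(token)
            if g in self.subword_vectors
        ]
        if known:
            return np.mean(known, axis=0)
        return self._fallback.vector(token)

    def matrix(self, tokens: Sequence[str]) -> np.ndarray:
        return np.stack([self.vector(t) for t in tokens])

    def cosine(self, a: str, b: str) -> float:
        va, vb = self.vector(a), self.vector(b)
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0 or nb == 0:
            return 0.0
        return float(va @ vb / (na * nb))


def pretrain_embeddings(
    corpus_tokens: Iterable[Sequence[str]],
    dim: int = 300,
    window: int = 3,
    min_count: int = 1,
    seed: int = 0,
) -> SubwordEmbeddingTable:
    """Train subword-augmented word embeddings on a tokenized corpus.

    Pipeline: symmetric word–context counts within ``window`` → positive
    PMI weighting → truncated SVD to ``dim`` factors (scaled by the square
    root of the singular values).  Subword (character 3–5-gram) vectors are
    the average of the vectors of all vocabulary words containing the gram,
    enabling composition for unseen words.
    """
    if dim <= 0:
        raise ValueError("embedding dimension must be positive")
    freq: dict[str, int] = {}
    sents = []
    for toks in corpus_tokens:
        toks = list(toks)
        sents.append(toks)
        for t in toks:
            freq[t] = freq.get(t, 0) + 1
    vocab = sorted(t for t, f in freq.items() if f >= min_count)
    if not vocab:
        raise ValueError("empty vocabulary after min_count filtering")
    index = {t: i for i, t in enumerate(vocab)}
    rows, cols = [], []
    for toks in sents:
        ids = [index[t] for t in toks if t in index]
        for i, wi in enumerate(ids):
            lo, hi = max(0, i - window), min(len(ids), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    rows.append(wi)
                    cols.append(ids[j])
    n = len(vocab)
    if rows:
        counts = coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        ).toarray()
    else:
        counts = np.zeros((n, n))
    total = counts.sum()
    if total > 0:
        p_joint = counts / total
        p_word = p_joint.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            pmi = np.log(p_joint / (p_word * p_word.T))
        ppmi = np.where(np.isfinite(pmi), np.maximum(pmi, 0.0), 0.0)
    else:
        ppmi = counts
    k = min(dim, n)
    u, s, _ = randomized_svd(ppmi, n_components=k, random_state=seed)
    vecs = u * np.sqrt(s)
    if k < dim:  # pad so every vector has the requested length
        vecs = np.pad(vecs, ((0, 0), (0, dim - k)))
    word_vectors = {t: vecs[i].copy() for t, i in index.items()}
    gram_members: dict[str, list[np.ndarray]] = {}
    for t in vocab:
        for g in _char_ngrams(t):
            gram_members.setdefault(g, []).append(word_vectors[t])
    subword_vectors = {g: np.mean(vs, axis=0) for g, vs in gram_members.items()}
    return SubwordEmbeddingTable(
        dim=dim, word_vectors=word_vectors, subword_vectors=subword_vectors, seed=seed
    )
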