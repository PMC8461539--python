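"""Shared fixtures: small synthetic corpora and mined-pair fixtures."""

from pathlib import Path

import numpy as np
import pytest

from riskmine import causal
from riskmine.normalize import normalize_text
from riskmine.synthetic import GeneratorConfig, generate_corpus

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(n_messages=600, seed=42)


@pytest.fixture(scope="session")
def small_corpus(small_config):
    return generate_corpus(small_config)


@pytest.fixture(scope="session")
def mined_pairs(small_config, small_corpus):
    """Non-degenerate candidate pairs mined with the corpus-matched cues."""
    lexicon = causal.CausalCueLexicon(tuple(small_config.cue_list))
    chunker = causal.RuleBasedChunker(
        boundary_words={t for cue in lexicon for t in cue.split()}
    )
    pairs = []
    for m in small_corpus.messages:
        tokens = normalize_text(m.text, m.id).tokens
        pairs.extend(causal.extract_all_pairs(tokens, lexicon, chunker, m.id))
    return [p for p in pairs if p.cause and p.effect]


def random_pair_fixture(rng: np.random.Generator, n_pairs: int = 100):
    """Random candidate pairs over small vocabularies, for recount oracles."""
    causes = [f"c{i}" for i in range(6)]
    effects = [f"e{i}" for i in range(7)]
    pairs = []
    for k in range(n_pairs):
        c = rng.choice(causes, size=rng.integers(1, 4), replace=False)
        e = rng.choice(effects, size=rng.integers(1, 4), replace=False)
        pairs.append(
            causal.CandidatePair(
                message_id=f"m{k}", cue="causes", position=0,
                cause=frozenset(str(x) for x in c),
                effect=frozenset(str(x) for x in e),
            )
        )
    return pairs, causes, effects
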