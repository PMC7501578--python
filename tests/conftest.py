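import numpy as np
import pytest

from lattice_ner.lexicon import build_lexicon
from lattice_ner.synthetic import (DEFAULT_CATEGORIES, FixtureConfig,
                                   generate_corpus,
                                   generate_embedding_tables,
                                   generate_lexicon)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_fixture():
    """A small seeded corpus + lexicon + tables shared across tests."""
    cfg = FixtureConfig(n_sentences=30, categories=DEFAULT_CATEGORIES[:3],
                        entity_density=1.5, lexicon_size=12,
                        sentence_len=(8, 16), seed=7)
    lexicon, cats = generate_lexicon(cfg)
    corpus = generate_corpus(lexicon, cats, cfg)
    char_table, word_table = generate_embedding_tables(
        lexicon, cfg.alphabet(), dim=10, seed=7)
    return dict(config=cfg, lexicon=lexicon, categories=cats, corpus=corpus,
                char_table=char_table, word_table=word_table)


@pytest.fixture
def mini_lexicon():
    """The worked three-term example: gastric / mucosa / gastric-mucosa."""
    return build_lexicon(["胃体", "粘膜", "胃体粘膜"])
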