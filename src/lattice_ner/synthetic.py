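"""Seeded synthetic corpora, lexicons and embedding tables.

The generator emulates the *structural* properties of Chinese clinical NER
corpora — short punctuation-split sentences of single characters, a fixed
set of entity categories, entities that are exact terms of a domain
lexicon, and ambiguous filler that shares characters with entity terms —
without any real clinical language.  Synthetic characters are drawn from a
private-use Unicode block so fixtures can never collide with real text.

Ambiguity is the property the lattice encoder exists to exploit: with
``ambiguity_rate > 0`` the filler text contains *decoy* fragments — proper
prefixes of lexicon terms that are not themselves terms — so a character-
only model sees entity-like contexts tagged O, while the lexicon tells the
lattice model that no complete term is present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import AnnotatedSentence
from .embeddings import EmbeddingTable
from .lexicon import Lexicon, build_lexicon

#: private-use-area code point the synthetic alphabet starts at
_PUA_BASE = 0xE000

DEFAULT_CATEGORIES = ["anatomy", "disease", "drug",
                      "image", "laboratory", "operation"]


@dataclass
class FixtureConfig:
    alphabet_size: int = 20
    n_sentences: int = 200
    sentence_len: tuple[int, int] = (10, 25)
    categories: list[str] = field(
        default_factory=lambda: list(DEFAULT_CATEGORIES))
    entity_density: float = 1.5
    lexicon_size: int = 30
    ambiguity_rate: float = 0.3
    max_len: int = 200
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.sentence_len[0] <= self.sentence_len[1] <= 200):
            raise ValueError("sentence_len must lie within [1, 200]")
        if self.entity_density < 0:
            raise ValueError("entity_density must be >= 0")

    def alphabet(self) -> list[str]:
        return [chr(_PUA_BASE + i) for i in range(self.alphabet_size)]


def generate_lexicon(config: FixtureConfig
                     ) -> tuple[Lexicon, dict[str, str]]:
    """Seeded lexicon of 2–5-character terms with a category per term.

    With ``ambiguity_rate == 0`` terms are built over pairwise-disjoint
    character sets, so no two terms share a character bigram; at positive
    rates, that fraction of terms is constructed to share a prefix or
    suffix with an earlier term.
    """
    if config.alphabet_size < 4:
        raise ValueError("alphabet_size must be >= 4")
    rng = np.random.default_rng(config.seed)
    alpha = config.alphabet()
    terms: list[str] = []
    if config.ambiguity_rate == 0.0:
        # partition the alphabet: disjoint character sets => disjoint bigrams
        lengths = [int(rng.integers(2, 4)) for _ in range(config.lexicon_size)]
        if sum(lengths) > config.alphabet_size:
            raise ValueError(
                f"cannot build {config.lexicon_size} bigram-disjoint terms "
                f"from an alphabet of {config.alphabet_size}")
        pool = list(rng.permutation(alpha))
        for L in lengths:
            terms.append("".join(pool[:L]))
            pool = pool[L:]
    else:
        seen: set[str] = set()
        guard = 0
        while len(terms) < config.lexicon_size:
            guard += 1
            if guard > 100 * max(config.lexicon_size, 1):
                raise ValueError("lexicon_size infeasible for this alphabet")
            if terms and rng.random() < config.ambiguity_rate:
                base = terms[int(rng.integers(len(terms)))]
                extra = "".join(rng.choice(alpha, size=int(rng.integers(1, 3))))
                term = base[: int(rng.integers(1, len(base)))] + extra \
                    if rng.random() < 0.5 else extra + base[-2:]
            else:
                L = int(rng.integers(2, 6))
                term = "".join(rng.choice(alpha, size=L))
            if 2 <= len(term) <= 5 and term not in seen:
                seen.add(term)
                terms.append(term)
    cats = {t: config.categories[int(rng.integers(len(config.categories)))]
            for t in terms}
    return build_lexicon(terms), cats


def _decoy(term: str, lexicon: Lexicon,
           rng: np.random.Generator) -> str | None:
    """A proper prefix of ``term`` that contains no complete lexicon term."""
    for L in rng.permutation(range(1, len(term))):
        piece = term[:int(L)]
        if not lexicon.match(list(piece)):
            return piece
    return None


def generate_corpus(lexicon: Lexicon, term_categories: dict[str, str],
                    config: FixtureConfig) -> list[AnnotatedSentence]:
    """Seeded corpus: filler characters with lexicon terms inserted as
    B/I-tagged entities at an expected ``entity_density`` per sentence.

    Every inserted entity is exactly a lexicon term (so the lattice path
    always exists), no two entities overlap, and — at positive ambiguity —
    O-tagged decoy fragments of terms are sprinkled into the filler.
    """
    rng = np.random.default_rng(config.seed + 1)
    alpha = config.alphabet()
    terms = lexicon.terms
    sentences: list[AnnotatedSentence] = []
    for _ in range(config.n_sentences):
        target = int(rng.integers(config.sentence_len[0],
                                  config.sentence_len[1] + 1))
        n_ent = int(rng.poisson(config.entity_density)) if terms else 0
        chars: list[str] = []
        tags: list[str] = []
        # entity slots interleaved with filler; build left to right
        slots = sorted(rng.random(n_ent)) if n_ent else []
        positions = [int(s * target) for s in slots]
        pi = 0
        while len(chars) < target:
            if pi < len(positions) and len(chars) >= positions[pi]:
                term = terms[int(rng.integers(len(terms)))]
                pi += 1
                if len(chars) + len(term) > config.max_len:
                    break
                cat = term_categories[term]
                chars.extend(term)
                tags.extend(["B-" + cat] + ["I-" + cat] * (len(term) - 1))
            elif (terms and config.ambiguity_rate > 0
                    and rng.random() < config.ambiguity_rate * 0.2):
                piece = _decoy(terms[int(rng.integers(len(terms)))],
                               lexicon, rng)
                if piece is None:
                    continue
                chars.extend(piece)
                tags.extend(["O"] * len(piece))
            else:
                chars.append(str(rng.choice(alpha)))
                tags.append("O")
        sentences.append(AnnotatedSentence(chars[:config.max_len],
                                           tags[:config.max_len]))
    return sentences


def generate_embedding_tables(lexicon: Lexicon, alphabet: list[str],
                              dim: int = 100, seed: int = 0,
                              scale: float = 0.5
                              ) -> tuple[EmbeddingTable, EmbeddingTable]:
    """Seeded Gaussian character and word tables covering every lexicon
    term (no UNK rows needed on fixture data).

    The default component scale 0.5 gives 100-dim vectors of norm ~5,
    matching the magnitudes word2vec-trained tables typically have.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(seed)
    char_vocab = {c: i for i, c in enumerate(sorted(set(alphabet)))}
    char_vecs = rng.normal(0, scale, size=(len(char_vocab), dim))
    word_vocab = {t: i for i, t in enumerate(lexicon.terms)}
    word_vecs = rng.normal(0, scale, size=(len(word_vocab), dim))
    return (EmbeddingTable(char_vocab, char_vecs, unk_seed=seed),
            EmbeddingTable(word_vocab, word_vecs, unk_seed=seed + 1))


def unlabeled_sentences(sentences: list[AnnotatedSentence]) -> list[list[str]]:
    """Strip tags: pretraining text drawn from the same distribution."""
    return [list(s.chars) for s in sentences]


def generate_memorization_corpus(n_sentences: int = 50, pattern_len: int = 4,
                                 sentence_len: int = 40, seed: int = 0
                                 ) -> list[list[str]]:
    """Language-model sanity benchmark: cyclic-pattern sentences.

    Each sentence repeats a fixed character cycle starting at a random
    phase, so the corpus is deterministic except for the phase — the
    irreducible per-token entropy is ~2*ln(pattern_len)/sentence_len and
    an adequate language model can drive the per-token NLL close to it.
    """
    rng = np.random.default_rng(seed)
    pattern = [chr(_PUA_BASE + i) for i in range(pattern_len)]
    out = []
    for _ in range(n_sentences):
        off = int(rng.integers(pattern_len))
        out.append([pattern[(off + i) % pattern_len]
                    for i in range(sentence_len)])
    return out
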