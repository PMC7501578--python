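"""Trie-backed lexicon and word-lattice matching.

The lattice encoder consumes, for every sentence, the set of contiguous
character subsequences that are terms of a domain lexicon D.  Matching
enumerates *all* such subsequences — overlapping and nested matches are
deliberately retained; choosing between competing words is the encoder's
job, not the matcher's.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

_END = "\0"  # terminal marker inside trie nodes

#: lattice words must span at least this many characters; a 1-character
#: "word" would duplicate the character path and add nothing
MIN_TERM_LEN = 2


@dataclass(frozen=True)
class LatticeMatch:
    """A lexicon term found at sentence positions ``[begin, end)``."""

    begin: int
    end: int
    term_id: int

    def __post_init__(self):
        if self.end - self.begin < MIN_TERM_LEN:
            raise ValueError("lattice match shorter than 2 characters")


class Lexicon:
    """Immutable term dictionary with a prefix-trie index.

    Term ids are assigned densely by sorted order, so they are stable
    across runs and usable as rows of a word-embedding table.
    """

    def __init__(self, terms: Iterable[str]):
        uniq = sorted({t for t in terms if len(t) >= MIN_TERM_LEN})
        self.terms: list[str] = uniq
        self.term_ids: dict[str, int] = {t: i for i, t in enumerate(uniq)}
        self._trie: dict = {}
        for term in uniq:
            node = self._trie
            for ch in term:
                node = node.setdefault(ch, {})
            node[_END] = self.term_ids[term]

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.term_ids

    def match(self, chars: Sequence[str],
              max_word_len: int | None = None) -> list[LatticeMatch]:
        """All lexicon subsequences of ``chars``, sorted by (end, begin).

        One trie walk per start position; a walk stops as soon as the
        prefix leaves the trie.
        """
        n = len(chars)
        out: list[LatticeMatch] = []
        for b in range(n):
            node = self._trie
            e = b
            while e < n:
                node = node.get(chars[e])
                if node is None:
                    break
                e += 1
                if max_word_len is not None and e - b > max_word_len:
                    break
                tid = node.get(_END)
                if tid is not None:
                    out.append(LatticeMatch(b, e, tid))
        out.sort(key=lambda m: (m.end, m.begin))
        return out


def build_lexicon(terms: Iterable[str]) -> Lexicon:
    """Build a :class:`Lexicon`; duplicates collapse, 1-char terms drop."""
    return Lexicon(terms)


def read_lexicon(path: str | Path) -> Lexicon:
    """Read a one-term-per-line UTF-8 lexicon file."""
    with open(path, encoding="utf-8") as fh:
        return build_lexicon(line.strip() for line in fh if line.strip())


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in lexicon.terms:
            fh.write(term + "\n")
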