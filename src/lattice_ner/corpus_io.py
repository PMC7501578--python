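"""Reading, writing and span arithmetic for character-per-line BIO corpora.

The unit of annotation is the single Unicode code point: Chinese clinical
text has no whitespace word boundaries, so tagging operates directly on
characters.  Tags follow the BIO schema — ``B-<CAT>`` opens an entity of
category ``CAT``, ``I-<CAT>`` continues it, ``O`` is outside any entity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

DEFAULT_MAX_LEN = 200
#: sentence-final punctuation used to split raw EMR text (configurable)
DEFAULT_DELIMITERS = "。；！？"

_TAG_RE = re.compile(r"^(O|[BI]-\S+)$")


class CorpusFormatError(ValueError):
    """Malformed BIO corpus file (carries the offending line number)."""


@dataclass(frozen=True)
class EntitySpan:
    """Half-open character span ``[begin, end)`` with an entity category."""

    begin: int
    end: int
    category: str

    def __post_init__(self):
        if not (0 <= self.begin < self.end):
            raise ValueError(f"invalid span [{self.begin},{self.end})")
        if not self.category:
            raise ValueError("empty category")


@dataclass
class AnnotatedSentence:
    """A character sequence with aligned BIO tags."""

    chars: list[str]
    tags: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.tags is None:
            self.tags = ["O"] * len(self.chars)
        if len(self.chars) != len(self.tags):
            raise ValueError("chars and tags length mismatch")
        if len(self.chars) == 0:
            raise ValueError("empty sentence")

    def __len__(self) -> int:
        return len(self.chars)

    @property
    def text(self) -> str:
        return "".join(self.chars)

    def spans(self) -> list[EntitySpan]:
        return spans_from_tags(self.tags)


def _check_tag(tag: str, lineno: int | None = None) -> None:
    if not _TAG_RE.match(tag):
        where = f" at line {lineno}" if lineno is not None else ""
        raise CorpusFormatError(f"unknown tag {tag!r}{where}")


def repair_bio(tags: Sequence[str]) -> list[str]:
    """Repair a tag sequence to BIO consistency.

    A bare ``I-X`` following ``O``, start of sentence, or a different
    category is relabeled ``B-X`` (entity mass is preserved, nothing is
    dropped).
    """
    out: list[str] = []
    prev = "O"
    for tag in tags:
        _check_tag(tag)
        if tag.startswith("I-"):
            cat = tag[2:]
            if prev == "O" or prev[2:] != cat:
                tag = "B-" + cat
        out.append(tag)
        prev = tag
    return out


def is_bio_consistent(tags: Sequence[str]) -> bool:
    return list(tags) == repair_bio(tags)


def spans_from_tags(tags: Sequence[str]) -> list[EntitySpan]:
    """Extract entity spans from a BIO-consistent tag sequence.

    Every maximal ``B-X (I-X)*`` run yields exactly one span.  Inconsistent
    input raises; callers holding decoder output should :func:`repair_bio`
    first.
    """
    if not is_bio_consistent(tags):
        raise ValueError("tags are not BIO-consistent; repair first")
    spans: list[EntitySpan] = []
    start = None
    cat = None
    for i, tag in enumerate(tags):
        if tag.startswith("B-"):
            if start is not None:
                spans.append(EntitySpan(start, i, cat))
            start, cat = i, tag[2:]
        elif tag == "O":
            if start is not None:
                spans.append(EntitySpan(start, i, cat))
                start = None
    if start is not None:
        spans.append(EntitySpan(start, len(tags), cat))
    return spans


def tags_from_spans(spans: Iterable[EntitySpan], length: int) -> list[str]:
    """Inverse of :func:`spans_from_tags` for non-overlapping spans."""
    tags = ["O"] * length
    for s in sorted(spans, key=lambda s: s.begin):
        if s.end > length:
            raise ValueError(f"span {s} exceeds length {length}")
        if any(t != "O" for t in tags[s.begin:s.end]):
            raise ValueError(f"overlapping span {s}")
        tags[s.begin] = "B-" + s.category
        for i in range(s.begin + 1, s.end):
            tags[i] = "I-" + s.category
    return tags


def _split_tagged(chars: list[str], tags: list[str],
                  max_len: int) -> Iterator[tuple[list[str], list[str]]]:
    """Split an over-long tagged sentence at ``max_len`` boundaries,
    moving each cut left to the nearest ``O`` so no entity is severed."""
    start = 0
    n = len(chars)
    while n - start > max_len:
        cut = start + max_len
        while cut > start + 1 and tags[cut] .startswith("I-"):
            cut -= 1
        yield chars[start:cut], tags[start:cut]
        start = cut
    yield chars[start:], tags[start:]


def read_bio_corpus(path: str | Path, max_len: int = DEFAULT_MAX_LEN,
                    schema_repair: bool = True) -> list[AnnotatedSentence]:
    """Read a UTF-8 ``char<TAB>tag`` corpus, one character per line,
    blank lines separating sentences.

    Sentences longer than ``max_len`` are split, never inside an entity.
    With ``schema_repair`` (default) stray ``I-`` tags are relabeled to
    ``B-``; otherwise inconsistent sentences raise.
    """
    sentences: list[AnnotatedSentence] = []
    chars: list[str] = []
    tags: list[str] = []

    def flush():
        if not chars:
            return
        fixed = repair_bio(tags)
        if not schema_repair and fixed != tags:
            raise CorpusFormatError("BIO-inconsistent sentence (repair disabled)")
        for c, t in _split_tagged(chars, fixed, max_len):
            sentences.append(AnnotatedSentence(c, t))
        chars.clear()
        tags.clear()

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            fields = line.split()
            if len(fields) != 2:
                raise CorpusFormatError(
                    f"line {lineno}: expected 2 fields, got {len(fields)}")
            char, tag = fields
            _check_tag(tag, lineno)
            chars.append(char)
            tags.append(tag)
    flush()
    return sentences


def write_bio_corpus(sentences: Iterable[AnnotatedSentence],
                     path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sent in sentences:
            for c, t in zip(sent.chars, sent.tags):
                fh.write(f"{c}\t{t}\n")
            fh.write("\n")


def write_predictions(sentences: Sequence[AnnotatedSentence],
                      pred_tags: Sequence[Sequence[str]],
                      path: str | Path) -> None:
    """Write the 3-column ``char<TAB>gold<TAB>pred`` interchange format."""
    with open(path, "w", encoding="utf-8") as fh:
        for sent, preds in zip(sentences, pred_tags):
            for c, g, p in zip(sent.chars, sent.tags, preds):
                fh.write(f"{c}\t{g}\t{p}\n")
            fh.write("\n")


def read_predictions(path: str | Path) -> tuple[list[list[str]], list[list[str]]]:
    """Read the 3-column format back as (gold, pred) tag sequences."""
    gold: list[list[str]] = []
    pred: list[list[str]] = []
    cur_g: list[str] = []
    cur_p: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                if cur_g:
                    gold.append(cur_g)
                    pred.append(cur_p)
                    cur_g, cur_p = [], []
                continue
            fields = line.split()
            if len(fields) != 3:
                raise CorpusFormatError(
                    f"line {lineno}: expected 3 fields, got {len(fields)}")
            cur_g.append(fields[1])
            cur_p.append(fields[2])
    if cur_g:
        gold.append(cur_g)
        pred.append(cur_p)
    return gold, pred


def split_sentences(text: str, max_len: int = DEFAULT_MAX_LEN,
                    delimiters: str = DEFAULT_DELIMITERS) -> list[str]:
    """Split raw EMR text into sentences at sentence-final punctuation,
    keeping each delimiter with the preceding piece, with a hard split at
    ``max_len`` for punctuation-free stretches.  Concatenating the output
    reproduces the input exactly.
    """
    pieces: list[str] = []
    cur: list[str] = []
    for ch in text:
        cur.append(ch)
        if ch in delimiters or len(cur) >= max_len:
            pieces.append("".join(cur))
            cur = []
    if cur:
        pieces.append("".join(cur))
    return pieces
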