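"""Static embedding tables in word2vec text format, with seeded OOV rows."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np


class EmbeddingTable:
    """token -> dense vector map with a deterministic UNK policy.

    Unknown tokens resolve to a single UNK row drawn uniformly from
    ``[-0.5/dim, 0.5/dim]`` with a fixed seed, so repeated lookups — and
    repeated runs — give identical vectors.
    """

    def __init__(self, vocab: dict[str, int], vectors: np.ndarray,
                 unk_seed: int = 0):
        vectors = np.asarray(vectors, dtype=np.float64)
        if vectors.ndim != 2 or vectors.shape[0] != len(vocab):
            raise ValueError("vectors shape inconsistent with vocab")
        if vectors.shape[1] < 1:
            raise ValueError("embedding dim must be positive")
        self.vocab = dict(vocab)
        self.vectors = vectors
        rng = np.random.default_rng(unk_seed)
        scale = 0.5 / self.dim
        self.unk_vector = rng.uniform(-scale, scale, size=self.dim)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.vocab)

    def __contains__(self, token: str) -> bool:
        return token in self.vocab

    def lookup(self, token: str) -> np.ndarray:
        row = self.vocab.get(token)
        return self.vectors[row] if row is not None else self.unk_vector

    def rows(self, tokens) -> np.ndarray:
        return np.stack([self.lookup(t) for t in tokens])


def load_word2vec_text(path: str | Path, unk_seed: int = 0) -> EmbeddingTable:
    """Load a word2vec *text*-format table.

    The first line is either a ``"count dim"`` header or a normal entry
    (dim is then inferred).  Duplicate tokens keep the first occurrence
    with a warning; a row with the wrong number of values is an error.
    """
    vocab: dict[str, int] = {}
    rows: list[np.ndarray] = []
    dim: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            if lineno == 1 and len(parts) == 2:
                try:
                    dim = int(parts[1])
                    continue  # header line
                except ValueError:
                    pass
            token, values = parts[0], parts[1:]
            if dim is None:
                dim = len(values)
            if len(values) != dim:
                raise ValueError(
                    f"line {lineno}: expected {dim} values, got {len(values)}")
            if token in vocab:
                warnings.warn(f"duplicate token {token!r} at line {lineno}; "
                              "keeping first occurrence")
                continue
            vocab[token] = len(rows)
            rows.append(np.array([float(v) for v in values]))
    if dim is None:
        raise ValueError(f"empty embedding file: {path}")
    vectors = np.stack(rows) if rows else np.zeros((0, dim))
    return EmbeddingTable(vocab, vectors)


def save_word2vec_text(table: EmbeddingTable, path: str | Path,
                       precision: int = 6) -> None:
    inv = sorted(table.vocab, key=table.vocab.get)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(inv)} {table.dim}\n")
        for token in inv:
            vals = " ".join(f"{v:.{precision}f}" for v in table.lookup(token))
            fh.write(f"{token} {vals}\n")
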