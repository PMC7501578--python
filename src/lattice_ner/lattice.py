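"""Lattice LSTM encoder: a character LSTM augmented with lexicon word cells.

The character path is a standard LSTM.  Every lexicon match (b, e) spawns a
*word cell* from the character state at its first character b — an LSTM
memory with forget and input gates but **no output gate**, since labels are
only predicted on characters.  At the word's last character, all word cells
ending there compete with the character path's own candidate through an
extra sigmoid *combine gate* per word; the competing gate logits (the word
combine gates and the character input gate) are normalized elementwise with
a softmax so the merged cell is a convex combination:

    c_t = sum_b alpha_{b,t} * c^w_{b,t} + alpha_t * candidate_t

The hidden state is then the usual h_t = o_t * tanh(c_t).  At positions
with no incoming word cell, the update is exactly the standard LSTM — an
empty lexicon makes the encoder a plain character LSTM.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

import numpy as np

from .autodiff import Linear, Tensor, concat, stack
from .embeddings import EmbeddingTable
from .lexicon import LatticeMatch


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    s = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-s, s, size=shape)


class LatticeParams:
    """Parameters of one lattice LSTM direction.

    char gates are fused into one (4H, D+H) matrix ordered (forget,
    output, input, candidate); word gates into (3H, Dw+H) ordered
    (forget, input, candidate); the combine gate maps [x_char, c_word]
    (D+H) to H.
    """

    def __init__(self, input_dim: int, hidden_dim: int, word_dim: int,
                 seed: int = 0):
        self.input_dim = input_dim
        self.hidden_dim = hidden_dim
        self.word_dim = word_dim
        rng = np.random.default_rng(seed)
        H, D, Dw = hidden_dim, input_dim, word_dim
        self.W_char = Tensor(_glorot(rng, (4 * H, H + D)), requires_grad=True)
        self.b_char = Tensor(np.zeros(4 * H), requires_grad=True)
        self.W_word = Tensor(_glorot(rng, (3 * H, Dw + H)), requires_grad=True)
        self.b_word = Tensor(np.zeros(3 * H), requires_grad=True)
        self.W_comb = Tensor(_glorot(rng, (H, D + H)), requires_grad=True)
        self.b_comb = Tensor(np.zeros(H), requires_grad=True)
        self.char_lin = Linear(self.W_char, self.b_char)
        self.word_lin = Linear(self.W_word, self.b_word)
        self.comb_lin = Linear(self.W_comb, self.b_comb)

    def params(self) -> list[Tensor]:
        return [self.W_char, self.b_char, self.W_word, self.b_word,
                self.W_comb, self.b_comb]


def word_cell(x_w: Tensor, h_b: Tensor, c_b: Tensor,
              params: LatticeParams) -> Tensor:
    """Word memory for a lexicon match, from the state at its first char.

    c^w = sigmoid(f) * c_b + sigmoid(i) * tanh(candidate); gates are linear
    in [x_w, h_b].  No hidden output is produced.
    """
    H = params.hidden_dim
    z = concat([x_w, h_b])
    a = params.word_lin(z)
    f = a[:H].sigmoid()
    i = a[H:2 * H].sigmoid()
    g = a[2 * H:].tanh()
    return f * c_b + i * g


def char_step(x_c: Tensor, h_prev: Tensor, c_prev: Tensor,
              incoming: Sequence[Tensor], params: LatticeParams
              ) -> tuple[Tensor, Tensor, np.ndarray | None]:
    """One character position update.

    With no incoming word cells this is the standard LSTM update.  With m
    incoming word cells, the m combine-gate logits and the character
    input-gate logit are softmax-normalized elementwise into weights
    alpha that sum to one per hidden unit, and the new cell is their
    convex combination of the word cells and the candidate.

    Returns (h, c, alphas) with alphas of shape (m+1, H) — the last row is
    the character path's weight — or None when there is no merge.
    """
    H = params.hidden_dim
    z = concat([h_prev, x_c])
    a = params.char_lin(z)
    f = a[:H].sigmoid()
    o = a[H:2 * H].sigmoid()
    i_logit = a[2 * H:3 * H]
    g = a[3 * H:].tanh()
    if not incoming:
        c = f * c_prev + i_logit.sigmoid() * g
        alphas = None
    else:
        logits = [params.comb_lin(concat([x_c, cw]))
                  for cw in incoming]
        logits.append(i_logit)
        logit_mat = stack(logits, axis=0)          # (m+1, H)
        alpha = logit_mat.softmax(axis=0)
        parts = list(incoming) + [g]
        c = (alpha * stack(parts, axis=0)).sum(axis=0)
        alphas = alpha.data
    h = o * c.tanh()
    return h, c, alphas


def encode(inputs: Sequence[Tensor], matches: Sequence[LatticeMatch],
           word_vectors: Sequence[Tensor], params: LatticeParams,
           direction: str = "forward", collect_alphas: list | None = None
           ) -> list[Tensor]:
    """Run one lattice LSTM direction over per-character input vectors.

    ``word_vectors[i]`` is the embedding for ``matches[i]``.  For the
    backward direction the characters and match coordinates are reversed
    first; outputs are returned in original sentence order.
    """
    n = len(inputs)
    if direction == "backward":
        inputs = list(inputs)[::-1]
        matches = [LatticeMatch(n - m.end, n - m.begin, m.term_id)
                   for m in matches]
    if n == 0:
        return []
    by_start: dict[int, list[int]] = defaultdict(list)
    for idx, m in enumerate(matches):
        by_start[m.begin].append(idx)
    pending: dict[int, list[Tensor]] = defaultdict(list)
    H = params.hidden_dim
    h = Tensor(np.zeros(H))
    c = Tensor(np.zeros(H))
    hs: list[Tensor] = []
    for t in range(n):
        h, c, alphas = char_step(inputs[t], h, c, pending.pop(t, []), params)
        if alphas is not None and collect_alphas is not None:
            collect_alphas.append(alphas)
        hs.append(h)
        # a word (b, e) spawns from the state at its first character b and
        # merges into the cell at its last character e-1
        for idx in by_start.get(t, ()):  # type: ignore[union-attr]
            m = matches[idx]
            pending[m.end - 1].append(
                word_cell(word_vectors[idx], h, c, params))
    if direction == "backward":
        hs = hs[::-1]
    return hs


def encode_bidirectional(inputs: Sequence[Tensor],
                         matches: Sequence[LatticeMatch],
                         word_vectors: Sequence[Tensor],
                         params_fwd: LatticeParams,
                         params_bwd: LatticeParams) -> list[Tensor]:
    """Concatenated [forward ; backward] hidden vectors per position."""
    fw = encode(inputs, matches, word_vectors, params_fwd, "forward")
    bw = encode(inputs, matches, word_vectors, params_bwd, "backward")
    return [concat([f, b]) for f, b in zip(fw, bw)]


def build_input_representation(chars: Sequence[str],
                               static_table: EmbeddingTable,
                               elmo: np.ndarray | None = None,
                               dropout_rate: float = 0.0,
                               rng: np.random.Generator | None = None,
                               training: bool = False) -> np.ndarray:
    """Per-character input vectors: [static ; contextual] or static alone.

    Inverted dropout is applied to the concatenated vector at training
    time only; evaluation is deterministic.
    """
    x = static_table.rows(chars)
    if elmo is not None:
        if len(elmo) != len(chars):
            raise ValueError("contextual embedding length mismatch")
        x = np.concatenate([x, np.asarray(elmo)], axis=1)
    if training and dropout_rate > 0.0:
        if rng is None:
            raise ValueError("dropout at training time needs an rng")
        keep = 1.0 - dropout_rate
        x = x * (rng.random(x.shape) < keep) / keep
    return x
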