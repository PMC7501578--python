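"""Character-input bidirectional language model with scalar layer mixing.

This is the contextualized-embedding component: a two-layer bidirectional
LSTM language model that takes character embeddings directly as input
(there is no convolutional character encoder — the character *is* the
token), projects each direction's hidden state to 50 dimensions, and is
trained to jointly maximize the forward and backward log-likelihood of the
corpus.  After pretraining, a sentence yields L+1 layers of 100-dim
per-character representations (layer 0 = the character embedding, layers
1..L = [forward_50 ; backward_50]), which a downstream task collapses with
a softmax-weighted scalar mix scaled by a single gamma.

Pretraining runs full-corpus batches with Adam; the downstream tagger
freezes the BiLM body and trains only the mixing weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .autodiff import (Adam, Linear, Tensor, concat, no_grad, stack,
                       transpose as _t)

BOS = "<bos>"
EOS = "<eos>"
UNK = "<unk>"


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan = sum(shape)
    s = np.sqrt(6.0 / fan)
    return rng.uniform(-s, s, size=shape)


class _LSTMLayer:
    """One projected LSTM direction-layer: hidden -> proj via a linear map."""

    def __init__(self, rng, in_dim: int, hidden_dim: int, proj_dim: int):
        self.hidden_dim = hidden_dim
        self.W = Tensor(_glorot(rng, (4 * hidden_dim, in_dim + hidden_dim)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(4 * hidden_dim), requires_grad=True)
        self.P = Tensor(_glorot(rng, (proj_dim, hidden_dim)), requires_grad=True)
        self.pb = Tensor(np.zeros(proj_dim), requires_grad=True)
        self.gate_lin = Linear(self.W, self.b)
        self.proj_lin = Linear(self.P, self.pb)

    def params(self) -> list[Tensor]:
        return [self.W, self.b, self.P, self.pb]

    def step(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """One batched cell update; returns (projected, h, c)."""
        H = self.hidden_dim
        z = concat([x, h], axis=-1)
        a = self.gate_lin(z)
        f = a[..., :H].sigmoid()
        i = a[..., H:2 * H].sigmoid()
        o = a[..., 2 * H:3 * H].sigmoid()
        g = a[..., 3 * H:].tanh()
        c2 = f * c + i * g
        h2 = o * c2.tanh()
        p = self.proj_lin(h2)
        return p, h2, c2


@dataclass
class ScalarMixParams:
    """Softmax-normalized layer weights and a global scale gamma."""

    s_logits: Tensor
    gamma: Tensor

    @classmethod
    def create(cls, n_layers: int) -> "ScalarMixParams":
        return cls(Tensor(np.zeros(n_layers), requires_grad=True),
                   Tensor(np.ones(()), requires_grad=True))

    def params(self) -> list[Tensor]:
        return [self.s_logits, self.gamma]


def scalar_mix(layer_stack: np.ndarray | Tensor, mix: ScalarMixParams) -> Tensor:
    """Collapse an (L+1, n, d) layer stack to (n, d):
    gamma * sum_j softmax(s)_j * layer_j."""
    st = layer_stack if isinstance(layer_stack, Tensor) else Tensor(layer_stack)
    L1 = st.shape[0]
    if mix.s_logits.shape[0] != L1:
        raise ValueError(
            f"scalar mix has {mix.s_logits.shape[0]} weights, stack has {L1} layers")
    w = mix.s_logits.softmax(axis=0).reshape((L1, 1, 1))
    return mix.gamma * (w * st).sum(axis=0)


class CharBiLM:
    """Two-layer projected BiLSTM language model over characters.

    ``emb_dim`` must equal ``2 * proj_dim`` so that every layer of the
    representation stack has the same width and the scalar mix is a plain
    weighted sum.
    """

    def __init__(self, alphabet: Sequence[str], emb_dim: int = 100,
                 hidden_dim: int = 100, proj_dim: int = 50,
                 n_layers: int = 2, seed: int = 0):
        if emb_dim != 2 * proj_dim:
            raise ValueError("emb_dim must equal 2*proj_dim")
        self.alphabet = sorted(set(alphabet))
        self.emb_dim = emb_dim
        self.hidden_dim = hidden_dim
        self.proj_dim = proj_dim
        self.n_layers = n_layers
        self.seed = seed
        # input vocab: characters, then UNK, BOS, EOS; prediction targets
        # exclude the sentinels (they are never predicted)
        self.vocab = {c: i for i, c in enumerate(self.alphabet)}
        self.unk_id = len(self.vocab)
        self.bos_id = self.unk_id + 1
        self.eos_id = self.unk_id + 2
        self.n_out = self.unk_id + 1  # characters + UNK
        n_in = self.eos_id + 1

        rng = np.random.default_rng(seed)
        self.embedding = Tensor(rng.normal(0, 0.1, size=(n_in, emb_dim)),
                                requires_grad=True)
        self.layers: dict[str, list[_LSTMLayer]] = {}
        for d in ("fwd", "bwd"):
            ls = []
            in_dim = emb_dim
            for _ in range(n_layers):
                ls.append(_LSTMLayer(rng, in_dim, hidden_dim, proj_dim))
                in_dim = proj_dim
            self.layers[d] = ls
        # output softmax shared between directions
        self.W_out = Tensor(_glorot(rng, (self.n_out, proj_dim)),
                            requires_grad=True)
        self.b_out = Tensor(np.zeros(self.n_out), requires_grad=True)

    # -- plumbing -------------------------------------------------------------
    def params(self) -> list[Tensor]:
        ps = [self.embedding, self.W_out, self.b_out]
        for d in ("fwd", "bwd"):
            for layer in self.layers[d]:
                ps.extend(layer.params())
        return ps

    def encode_ids(self, chars: Sequence[str]) -> list[int]:
        return [self.vocab.get(c, self.unk_id) for c in chars]

    # -- core recurrences -----------------------------------------------------
    def _run(self, ids: np.ndarray, direction: str
             ) -> tuple[list[Tensor], Tensor]:
        """Run one direction over an id batch (B, T).

        Returns per-layer projected state sequences (each (B, T, proj)) and
        the embedded inputs (B, T, emb).
        """
        B, T = ids.shape
        emb = self.embedding[ids]
        h = [Tensor(np.zeros((B, self.hidden_dim))) for _ in range(self.n_layers)]
        c = [Tensor(np.zeros((B, self.hidden_dim))) for _ in range(self.n_layers)]
        outs: list[list[Tensor]] = [[] for _ in range(self.n_layers)]
        for t in range(T):
            x = emb[:, t, :]
            for j, layer in enumerate(self.layers[direction]):
                p, h[j], c[j] = layer.step(x, h[j], c[j])
                outs[j].append(p)
                x = p
        seqs = [stack(o, axis=1) for o in outs]
        return seqs, emb

    def representations(self, chars: Sequence[str]) -> np.ndarray:
        """Layer stack for one sentence: (L+1, n, emb_dim) array.

        Layer 0 is the character embedding; layer j>0 concatenates the
        forward and backward projected states of BiLSTM layer j.  Forward
        states at position k depend only on characters 1..k, backward
        states only on k..n.
        """
        if len(chars) == 0:
            raise ValueError("empty sentence")
        ids = np.array(self.encode_ids(chars))
        n = len(ids)
        with no_grad():
            f_seqs, emb = self._run(ids[None, :], "fwd")
            b_seqs, _ = self._run(ids[None, ::-1], "bwd")
        layers = [emb.data[0]]
        for j in range(self.n_layers):
            fw = f_seqs[j].data[0]                # (n, proj)
            bw = b_seqs[j].data[0][::-1]          # realign to sentence order
            layers.append(np.concatenate([fw, bw], axis=1))
        return np.stack(layers)

    # -- language-model objective --------------------------------------------
    def nll(self, sentences: Sequence[Sequence[str]]) -> Tensor:
        """Per-token negative log-likelihood of the joint objective.

        Both directions contribute at every position: the loss is
        (forward NLL + backward NLL) / total token count, so a model
        forced to uniform predictions over an output vocabulary of V
        scores 2*ln(V) per token.
        """
        if not sentences:
            raise ValueError("empty batch")
        id_seqs = [self.encode_ids(s) for s in sentences]
        B = len(id_seqs)
        T = max(len(s) for s in id_seqs)
        n_tok = sum(len(s) for s in id_seqs)
        # forward input: BOS + tokens (state after position k predicts k+1)
        fin = np.full((B, T + 1), self.eos_id)
        bin_ = np.full((B, T + 1), self.bos_id)
        mask = np.zeros((B, T))
        targets = np.zeros((B, T), dtype=int)
        for i, s in enumerate(id_seqs):
            L = len(s)
            fin[i, 0] = self.bos_id
            fin[i, 1:L + 1] = s
            bin_[i, 0] = self.eos_id
            bin_[i, 1:L + 1] = s[::-1]
            mask[i, :L] = 1.0
            targets[i, :L] = s
        # backward targets are per-sentence reversals (alignment differs per
        # sentence length, so they cannot be a single array reversal)
        bwd_targets = np.zeros((B, T), dtype=int)
        bwd_mask = np.zeros((B, T))
        for i, s in enumerate(id_seqs):
            L = len(s)
            bwd_targets[i, :L] = s[::-1]
            bwd_mask[i, :L] = 1.0
        total = Tensor(np.zeros(()))
        for ids, tgt, msk in ((fin, targets, mask),
                              (bin_, bwd_targets, bwd_mask)):
            seqs, _ = self._run(ids, "fwd" if ids is fin else "bwd")
            states = seqs[-1][:, :T, :]          # state after position k
            logits = states @ _t(self.W_out) + self.b_out   # (B, T, V)
            lse = logits.logsumexp(axis=-1)
            bi = np.repeat(np.arange(B), T)
            ti = np.tile(np.arange(T), B)
            gold = logits[(bi, ti, tgt.reshape(-1))].reshape((B, T))
            total = total + ((lse - gold) * Tensor(msk)).sum()
        return total * (1.0 / n_tok)


def train_bilm(corpus: Sequence[Sequence[str]], epochs: int = 200,
               lr: float = 1e-2, seed: int = 0,
               emb_dim: int = 100, hidden_dim: int = 100, proj_dim: int = 50,
               n_layers: int = 2, batch_size: int | None = None,
               log_every: int = 0) -> tuple[CharBiLM, list[float]]:
    """Pretrain a :class:`CharBiLM` on an unlabeled character corpus.

    Returns the model and the per-epoch loss history.  With
    ``batch_size=None`` the whole corpus is one batch.  Fully
    deterministic given the seed.
    """
    if not corpus:
        raise ValueError("empty corpus")
    alphabet = sorted({c for s in corpus for c in s})
    model = CharBiLM(alphabet, emb_dim=emb_dim, hidden_dim=hidden_dim,
                     proj_dim=proj_dim, n_layers=n_layers, seed=seed)
    opt = Adam(model.params(), lr=lr)
    history: list[float] = []
    sents = [list(s) for s in corpus]
    if batch_size is None:
        batch_size = len(sents)
    rng = np.random.default_rng(seed)
    for epoch in range(epochs):
        order = rng.permutation(len(sents))
        tot, ntok = 0.0, 0
        for start in range(0, len(sents), batch_size):
            batch = [sents[i] for i in order[start:start + batch_size]]
            opt.zero_grad()
            loss = model.nll(batch)
            loss.backward()
            opt.step()
            k = sum(len(s) for s in batch)
            tot += loss.item() * k
            ntok += k
        history.append(tot / ntok)
        if log_every and (epoch + 1) % log_every == 0:
            print(f"epoch {epoch + 1}: nll/token = {history[-1]:.4f}")
    return model, history


# -- checkpointing ------------------------------------------------------------

def save_bilm(model: CharBiLM, path: str | Path) -> None:
    meta = dict(alphabet=model.alphabet, emb_dim=model.emb_dim,
                hidden_dim=model.hidden_dim, proj_dim=model.proj_dim,
                n_layers=model.n_layers, seed=model.seed, format=1)
    arrays = {f"p{i}": p.data for i, p in enumerate(model.params())}
    np.savez(path, meta=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_bilm(path: str | Path) -> CharBiLM:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        model = CharBiLM(meta["alphabet"], emb_dim=meta["emb_dim"],
                         hidden_dim=meta["hidden_dim"],
                         proj_dim=meta["proj_dim"], n_layers=meta["n_layers"],
                         seed=meta["seed"])
        for i, p in enumerate(model.params()):
            p.data = z[f"p{i}"].astype(np.float64)
    return model
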