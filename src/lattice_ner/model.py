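"""End-to-end tagger: embeddings + optional contextual mix + bidirectional
lattice encoder + CRF, assembled as one trainable model.

The contextual language model body is frozen here; only its scalar mixing
weights train with the tagger.  Per-sentence layer stacks are therefore
cached, so the (expensive) language-model forward runs once per distinct
sentence per training run.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from . import crf as crf_mod
from .autodiff import Tensor, concat, no_grad, stack
from .bilm import CharBiLM, ScalarMixParams, scalar_mix
from .corpus_io import AnnotatedSentence, repair_bio
from .embeddings import EmbeddingTable
from .lattice import LatticeParams, encode_bidirectional
from .lexicon import Lexicon, build_lexicon


def _label_set(categories: Sequence[str]) -> list[str]:
    labels = ["O"]
    for c in sorted(categories):
        labels += ["B-" + c, "I-" + c]
    return labels


class LatticeNERModel:
    """ELMo-lattice-LSTM-CRF and its ablations.

    ``lexicon=None`` (or an empty lexicon) degrades the encoder to a plain
    character BiLSTM; ``bilm=None`` drops the contextual embedding.  Both
    ablations are exactly the configurations used as baselines.
    """

    def __init__(self, categories: Sequence[str],
                 char_table: EmbeddingTable,
                 word_table: EmbeddingTable | None = None,
                 lexicon: Lexicon | None = None,
                 bilm: CharBiLM | None = None,
                 hidden_dim: int = 200, dropout: float = 0.5,
                 seed: int = 0, extra_chars: Sequence[str] = ()):
        self.categories = sorted(categories)
        self.labels = _label_set(self.categories)
        self.lexicon = lexicon if lexicon is not None else build_lexicon([])
        self.bilm = bilm
        self.hidden_dim = hidden_dim
        self.dropout = dropout
        self.seed = seed

        rng = np.random.default_rng(seed)
        # character vocabulary: static table plus any corpus characters
        chars = sorted(set(char_table.vocab) | set(extra_chars))
        self.char_vocab = {c: i for i, c in enumerate(chars)}
        self.char_dim = char_table.dim
        cvecs = np.stack([char_table.lookup(c) for c in chars])
        self.char_emb = Tensor(cvecs, requires_grad=True)
        self.unk_char = Tensor(char_table.unk_vector.copy(),
                               requires_grad=True)

        # word embeddings: one trainable row per lexicon term
        wt = word_table
        if len(self.lexicon) > 0:
            self.word_dim = wt.dim if wt is not None else self.char_dim
            wrows = [wt.lookup(t) if wt is not None else
                     rng.normal(0, 0.1, self.word_dim)
                     for t in self.lexicon.terms]
            self.word_emb = Tensor(np.stack(wrows), requires_grad=True)
        else:
            self.word_dim = wt.dim if wt is not None else self.char_dim
            self.word_emb = Tensor(np.zeros((0, self.word_dim)))

        input_dim = self.char_dim + (bilm.emb_dim if bilm is not None else 0)
        self.input_dim = input_dim
        self.mix = (ScalarMixParams.create(bilm.n_layers + 1)
                    if bilm is not None else None)
        self.enc_fwd = LatticeParams(input_dim, hidden_dim, self.word_dim,
                                     seed=int(rng.integers(2 ** 31)))
        self.enc_bwd = LatticeParams(input_dim, hidden_dim, self.word_dim,
                                     seed=int(rng.integers(2 ** 31)))
        self.crf = crf_mod.CRFLayer(self.labels, 2 * hidden_dim,
                                    seed=int(rng.integers(2 ** 31)))
        self._stack_cache: dict[str, np.ndarray] = {}

    # -- parameters -----------------------------------------------------------
    def params(self) -> list[Tensor]:
        ps = [self.char_emb, self.unk_char]
        if self.word_emb.shape[0] > 0:
            ps.append(self.word_emb)
        if self.mix is not None:
            ps.extend(self.mix.params())
        ps.extend(self.enc_fwd.params())
        ps.extend(self.enc_bwd.params())
        ps.extend(self.crf.params())
        return ps

    # -- forward --------------------------------------------------------------
    def _char_rows(self, chars: Sequence[str]) -> Tensor:
        known = [self.char_vocab.get(c) for c in chars]
        if all(k is not None for k in known):
            return self.char_emb[np.array(known)]
        rows = [self.char_emb[k] if k is not None else self.unk_char
                for k in known]
        return stack(rows, axis=0)

    def _elmo(self, chars: Sequence[str]) -> Tensor | None:
        if self.bilm is None:
            return None
        key = "".join(chars)
        if key not in self._stack_cache:
            self._stack_cache[key] = self.bilm.representations(chars)
        return scalar_mix(self._stack_cache[key], self.mix)

    def _inputs(self, sent: Sequence[str], training: bool,
                rng: np.random.Generator | None) -> Tensor:
        x = self._char_rows(sent)
        e = self._elmo(sent)
        if e is not None:
            x = concat([x, e], axis=-1)
        if training and self.dropout > 0.0:
            keep = 1.0 - self.dropout
            mask = (rng.random(x.shape) < keep) / keep
            x = x * Tensor(mask)
        return x

    def _encode(self, sent: Sequence[str], training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        x = self._inputs(sent, training, rng)
        matches = self.lexicon.match(sent)
        wvecs = [self.word_emb[m.term_id] for m in matches]
        inputs = [x[t] for t in range(len(sent))]
        hs = encode_bidirectional(inputs, matches, wvecs,
                                  self.enc_fwd, self.enc_bwd)
        return stack(hs, axis=0)

    def loss(self, sentence: AnnotatedSentence,
             rng: np.random.Generator | None = None,
             training: bool = True) -> Tensor:
        """CRF negative log-likelihood of the gold tags for one sentence."""
        hidden = self._encode(sentence.chars, training, rng)
        y = [self.labels.index(t) for t in sentence.tags]
        return self.crf.nll(hidden, y)

    def predict_tags(self, chars: Sequence[str]) -> list[str]:
        """Viterbi-decoded BIO tags (schema-masked, dropout off)."""
        with no_grad():
            hidden = self._encode(list(chars), training=False)
        path = self.crf.decode(hidden)
        return repair_bio([self.labels[i] for i in path])

    def predict(self, sentences: Sequence[AnnotatedSentence]
                ) -> list[list[str]]:
        return [self.predict_tags(s.chars) for s in sentences]

    # -- persistence ----------------------------------------------------------
    def save(self, path: str | Path) -> None:
        meta = dict(categories=self.categories,
                    char_vocab=self.char_vocab,
                    terms=self.lexicon.terms,
                    char_dim=self.char_dim, word_dim=self.word_dim,
                    hidden_dim=self.hidden_dim, dropout=self.dropout,
                    seed=self.seed, has_bilm=self.bilm is not None,
                    format=1)
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params())}
        if self.bilm is not None:
            for i, p in enumerate(self.bilm.params()):
                arrays[f"bilm{i}"] = p.data
            meta["bilm_meta"] = dict(
                alphabet=self.bilm.alphabet, emb_dim=self.bilm.emb_dim,
                hidden_dim=self.bilm.hidden_dim,
                proj_dim=self.bilm.proj_dim, n_layers=self.bilm.n_layers,
                seed=self.bilm.seed)
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(),
                                          dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "LatticeNERModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            bilm = None
            if meta["has_bilm"]:
                bm = meta["bilm_meta"]
                bilm = CharBiLM(bm["alphabet"], emb_dim=bm["emb_dim"],
                                hidden_dim=bm["hidden_dim"],
                                proj_dim=bm["proj_dim"],
                                n_layers=bm["n_layers"], seed=bm["seed"])
                for i, p in enumerate(bilm.params()):
                    p.data = z[f"bilm{i}"].astype(np.float64)
            chars = sorted(meta["char_vocab"], key=meta["char_vocab"].get)
            ctab = EmbeddingTable({c: i for i, c in enumerate(chars)},
                                  np.zeros((len(chars), meta["char_dim"])))
            wtab = EmbeddingTable(
                {t: i for i, t in enumerate(meta["terms"])},
                np.zeros((len(meta["terms"]), meta["word_dim"])))
            model = cls(meta["categories"], ctab, wtab,
                        build_lexicon(meta["terms"]), bilm,
                        hidden_dim=meta["hidden_dim"],
                        dropout=meta["dropout"], seed=meta["seed"])
            for i, p in enumerate(model.params()):
                p.data = z[f"p{i}"].astype(np.float64)
        return model
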