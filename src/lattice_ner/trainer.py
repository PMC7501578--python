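"""NER training loop and replicate protocol.

Training follows the reference recipe for this architecture family:
plain SGD at batch size 1, learning rate lr0 / (1 + decay * epoch),
gradient-norm clipping at 5, inverted dropout on the input embeddings,
strict entity F1 on a dev set after every epoch, best-dev checkpointing.
All randomness (initialization, shuffling, dropout) flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .autodiff import SGD
from .bilm import CharBiLM
from .corpus_io import AnnotatedSentence
from .embeddings import EmbeddingTable
from .evaluator import PRFReport, average_reports, strict_prf
from .lexicon import Lexicon
from .model import LatticeNERModel


@dataclass
class TrainConfig:
    """Hyperparameters; the defaults are the reference settings."""

    char_emb_size: int = 100
    elmo_emb_size: int = 100
    word_emb_size: int = 100
    dropout: float = 0.5
    lstm_hidden: int = 200
    lstm_layers: int = 1
    lr: float = 0.015
    lr_decay: float = 0.05
    epochs: int = 10
    batch_size: int = 1
    seed: int = 0
    elmo_enabled: bool = True
    #: gradient-norm ceiling; typical per-sentence norms for this model are
    #: O(10), so the default only damps rare spikes rather than rescaling
    #: every update
    clip_norm: float = 50.0
    #: stop once dev strict F1 reaches this value (None = run all epochs)
    early_stop_f1: float | None = None

    def __post_init__(self):
        for name in ("char_emb_size", "elmo_emb_size", "word_emb_size",
                     "lstm_hidden", "lstm_layers", "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainHistory:
    losses: list[float] = field(default_factory=list)
    dev_f1: list[float] = field(default_factory=list)
    lrs: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_f1: float = 0.0
    n_updates: int = 0


def lr_at_epoch(lr0: float, decay: float, epoch: int) -> float:
    """Learning rate at a 0-based epoch: lr0 / (1 + decay * epoch)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return lr0 / (1.0 + decay * epoch)


def train(train_corpus: Sequence[AnnotatedSentence],
          dev_corpus: Sequence[AnnotatedSentence],
          lexicon: Lexicon | None,
          char_table: EmbeddingTable,
          word_table: EmbeddingTable | None = None,
          bilm: CharBiLM | None = None,
          config: TrainConfig = None,
          ) -> tuple[LatticeNERModel, TrainHistory]:
    """Train a tagger; returns the best-dev model and the run history."""
    if config is None:
        config = TrainConfig()
    if not train_corpus or not dev_corpus:
        raise ValueError("corpora must be non-empty")
    train_cats = {s.category for sent in train_corpus for s in sent.spans()}
    dev_cats = {s.category for sent in dev_corpus for s in sent.spans()}
    missing = dev_cats - train_cats
    if missing:
        import warnings
        warnings.warn(f"dev categories absent from training data: {missing}")

    if not config.elmo_enabled:
        bilm = None
    corpus_chars = {c for sent in train_corpus for c in sent.chars}
    model = LatticeNERModel(sorted(train_cats | dev_cats) or ["entity"],
                            char_table, word_table, lexicon, bilm,
                            hidden_dim=config.lstm_hidden,
                            dropout=config.dropout, seed=config.seed,
                            extra_chars=sorted(corpus_chars))
    opt = SGD(model.params(), lr=config.lr, clip_norm=config.clip_norm)
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()
    best_state: list[np.ndarray] | None = None

    for epoch in range(config.epochs):
        lr = lr_at_epoch(config.lr, config.lr_decay, epoch)
        opt.lr = lr
        order = rng.permutation(len(train_corpus))
        total = 0.0
        for i in order:
            opt.zero_grad()
            loss = model.loss(train_corpus[i], rng=rng, training=True)
            loss.backward()
            opt.step()
            history.n_updates += 1
            total += loss.item()
        history.losses.append(total / len(train_corpus))
        history.lrs.append(lr)
        report = strict_prf([s.tags for s in dev_corpus],
                            model.predict(dev_corpus))
        history.dev_f1.append(report.f1)
        if best_state is None or report.f1 > history.best_f1:
            history.best_f1 = report.f1
            history.best_epoch = epoch
            best_state = [p.data.copy() for p in model.params()]
        if (config.early_stop_f1 is not None
                and report.f1 >= config.early_stop_f1):
            break
    if best_state is not None:
        for p, d in zip(model.params(), best_state):
            p.data = d
    return model, history


def run_replicates(train_corpus: Sequence[AnnotatedSentence],
                   dev_corpus: Sequence[AnnotatedSentence],
                   test_corpus: Sequence[AnnotatedSentence],
                   lexicon: Lexicon | None,
                   char_table: EmbeddingTable,
                   word_table: EmbeddingTable | None,
                   bilm: CharBiLM | None,
                   config: TrainConfig,
                   seeds: Sequence[int],
                   ) -> tuple[list[PRFReport], tuple[float, float, float]]:
    """Train one model per seed and report each test-set P/R/F1 plus the
    arithmetic mean across runs (the replicate-averaging protocol)."""
    reports: list[PRFReport] = []
    for seed in seeds:
        cfg = TrainConfig(**{**asdict(config), "seed": seed})
        model, _ = train(train_corpus, dev_corpus, lexicon, char_table,
                         word_table, bilm, cfg)
        reports.append(strict_prf([s.tags for s in test_corpus],
                                  model.predict(test_corpus)))
    return reports, average_reports(reports)
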