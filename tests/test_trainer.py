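"""Training-loop behaviour on small fixtures (fast settings throughout)."""

import numpy as np
import pytest

from lattice_ner.model import LatticeNERModel
from lattice_ner.trainer import (TrainConfig, lr_at_epoch, run_replicates,
                                 train)

FAST = dict(char_emb_size=10, word_emb_size=10, lstm_hidden=12, epochs=2,
            elmo_enabled=False)


class TestSchedule:
    def test_epoch_zero_is_base_rate(self):
        assert lr_at_epoch(0.015, 0.05, 0) == 0.015

    def test_epoch_one_decayed(self):
        assert lr_at_epoch(0.015, 0.05, 1) == pytest.approx(0.015 / 1.05)

    def test_zero_decay_constant(self):
        assert all(lr_at_epoch(0.01, 0.0, e) == 0.01 for e in range(5))

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            lr_at_epoch(0.01, 0.05, -1)


class TestTrain:
    def test_one_epoch_one_sentence_one_update(self, small_fixture):
        sent = small_fixture["corpus"][0]
        cfg = TrainConfig(seed=0, epochs=1, **{k: v for k, v in FAST.items()
                                               if k != "epochs"})
        _, hist = train([sent], [sent], small_fixture["lexicon"],
                        small_fixture["char_table"],
                        small_fixture["word_table"], None, cfg)
        assert hist.n_updates == 1
        assert len(hist.losses) == len(hist.dev_f1) == len(hist.lrs) == 1

    def test_same_seed_identical_losses(self, small_fixture):
        corpus = small_fixture["corpus"][:6]
        cfg = TrainConfig(seed=3, **FAST)
        args = (corpus, corpus, small_fixture["lexicon"],
                small_fixture["char_table"], small_fixture["word_table"],
                None, cfg)
        _, h1 = train(*args)
        _, h2 = train(*args)
        assert h1.losses == h2.losses
        assert h1.dev_f1 == h2.dev_f1

    def test_dev_category_missing_from_train_warns(self, small_fixture):
        corpus = small_fixture["corpus"]
        train_set = [s for s in corpus if all(t == "O" or "anatomy" not in t
                                              for t in s.tags)][:4]
        dev_set = [s for s in corpus
                   if any("anatomy" in t for t in s.tags)][:2]
        if not train_set or not dev_set:
            pytest.skip("fixture lacks the category split")
        cfg = TrainConfig(seed=0, **FAST)
        with pytest.warns(UserWarning, match="absent"):
            train(train_set, dev_set, small_fixture["lexicon"],
                  small_fixture["char_table"], small_fixture["word_table"],
                  None, cfg)

    def test_empty_corpus_rejected(self, small_fixture):
        with pytest.raises(ValueError):
            train([], [], None, small_fixture["char_table"], None, None,
                  TrainConfig(**FAST))


class TestPredict:
    def test_eval_deterministic(self, small_fixture):
        corpus = small_fixture["corpus"][:4]
        cfg = TrainConfig(seed=1, **FAST)
        model, _ = train(corpus, corpus, small_fixture["lexicon"],
                         small_fixture["char_table"],
                         small_fixture["word_table"], None, cfg)
        assert model.predict(corpus) == model.predict(corpus)

    def test_empty_sentence_list(self, small_fixture):
        corpus = small_fixture["corpus"][:2]
        cfg = TrainConfig(seed=1, **FAST)
        model, _ = train(corpus, corpus, None,
                         small_fixture["char_table"], None, None, cfg)
        assert model.predict([]) == []

    def test_tags_are_schema_consistent(self, small_fixture):
        from lattice_ner.corpus_io import is_bio_consistent
        corpus = small_fixture["corpus"][:4]
        cfg = TrainConfig(seed=2, **FAST)
        model, _ = train(corpus, corpus, small_fixture["lexicon"],
                         small_fixture["char_table"],
                         small_fixture["word_table"], None, cfg)
        for tags in model.predict(corpus):
            assert is_bio_consistent(tags)


class TestCheckpoint:
    def test_save_load_predicts_identically(self, tmp_path, small_fixture):
        corpus = small_fixture["corpus"][:4]
        cfg = TrainConfig(seed=5, **FAST)
        model, _ = train(corpus, corpus, small_fixture["lexicon"],
                         small_fixture["char_table"],
                         small_fixture["word_table"], None, cfg)
        p = tmp_path / "model.npz"
        model.save(p)
        back = LatticeNERModel.load(p)
        assert back.predict(corpus) == model.predict(corpus)


class TestAblationEquivalences:
    def test_empty_lexicon_equals_none(self, small_fixture):
        """Training with no lexicon and with an empty one are the same
        model family (character BiLSTM-CRF)."""
        from lattice_ner.lexicon import build_lexicon
        corpus = small_fixture["corpus"][:4]
        cfg = TrainConfig(seed=9, **FAST)
        m1, h1 = train(corpus, corpus, None, small_fixture["char_table"],
                       None, None, cfg)
        m2, h2 = train(corpus, corpus, build_lexicon([]),
                       small_fixture["char_table"], None, None, cfg)
        assert h1.losses == h2.losses


class TestReplicates:
    def test_single_run_average_equals_run(self, small_fixture):
        corpus = small_fixture["corpus"][:5]
        cfg = TrainConfig(**FAST)
        reports, avg = run_replicates(corpus, corpus, corpus,
                                      small_fixture["lexicon"],
                                      small_fixture["char_table"],
                                      small_fixture["word_table"], None,
                                      cfg, seeds=[7])
        assert avg == (reports[0].precision, reports[0].recall,
                       reports[0].f1)

    def test_identical_seeds_zero_variance(self, small_fixture):
        corpus = small_fixture["corpus"][:5]
        cfg = TrainConfig(**FAST)
        reports, _ = run_replicates(corpus, corpus, corpus, None,
                                    small_fixture["char_table"], None, None,
                                    cfg, seeds=[4, 4])
        assert reports[0].f1 == reports[1].f1

    def test_average_is_arithmetic_mean(self, small_fixture):
        corpus = small_fixture["corpus"][:5]
        cfg = TrainConfig(**FAST)
        reports, avg = run_replicates(corpus, corpus, corpus,
                                      small_fixture["lexicon"],
                                      small_fixture["char_table"],
                                      small_fixture["word_table"], None,
                                      cfg, seeds=[1, 2, 3])
        assert avg[2] == pytest.approx(np.mean([r.f1 for r in reports]))
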