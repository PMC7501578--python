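"""Train the lattice tagger on a synthetic corpus and score it strictly.

Generates a small seeded corpus with a lexicon, trains the (no-ELMo)
lattice-LSTM-CRF for a few epochs, then reports strict entity-level
precision/recall/F1 per category.
"""

from lattice_ner import TrainConfig, report_table, strict_prf, train
from lattice_ner.synthetic import (DEFAULT_CATEGORIES, FixtureConfig,
                                   generate_corpus,
                                   generate_embedding_tables,
                                   generate_lexicon)

cfg = FixtureConfig(n_sentences=60, categories=DEFAULT_CATEGORIES[:3],
                    entity_density=1.5, sentence_len=(8, 16), seed=11)
lexicon, categories = generate_lexicon(cfg)
corpus = generate_corpus(lexicon, categories, cfg)
char_table, word_table = generate_embedding_tables(lexicon, cfg.alphabet(),
                                                   dim=50, seed=11)

# this desk-scale demo uses a smaller model than the full-scale defaults,
# so it takes a larger learning rate and a few more epochs to converge
config = TrainConfig(epochs=25, seed=1, elmo_enabled=False, lstm_hidden=100,
                     char_emb_size=50, word_emb_size=50, lr=0.05)
model, history = train(corpus, corpus, lexicon, char_table, word_table,
                       None, config)

print("training loss, epochs 1/5/10/25:",
      [round(history.losses[i], 2) for i in (0, 4, 9, 24)])
print("training F1,   epochs 1/5/10/25:",
      [round(history.dev_f1[i], 1) for i in (0, 4, 9, 24)])

report = strict_prf([s.tags for s in corpus], model.predict(corpus))
print("\n" + report_table(report))
# Each row: strict precision/recall/F1 (%) plus gold/predicted/matched
# entity counts; an entity counts only when begin, end and category all
# agree exactly.  The loss should fall monotonically and F1 rise toward
# 100 as the model overfits this small corpus.
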