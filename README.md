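# lattice-ner

A sequence tagger for **clinical named entity recognition in character-based
(Chinese) text**: a lattice LSTM encoder over characters and dictionary
words, optionally fed by contextualized character embeddings from a
character-input bidirectional language model, decoded by a linear-chain CRF,
and evaluated with strict entity-level precision/recall/F1.

It is aimed at people building NER systems for electronic medical records in
languages without whitespace word boundaries, where purely character-based
models lose word-level cues and word-based models inherit segmentation
errors. Everything — including the recurrent networks and their gradients —
runs on NumPy (float64) via a small reverse-mode autodiff tape shipped with
the package, so results are exactly reproducible from a seed on any machine.

## The model

A sentence is a character sequence c_1..c_m. A domain lexicon **D** is
matched against the sentence with a trie; every multi-character subsequence
w_{b,e} ∈ D becomes a *word path* of the lattice.

**Character path.** A standard LSTM over per-character inputs
x_t = [static embedding ; contextual embedding]:

    f_t, o_t, i_t = σ(W [h_{t-1}, x_t] + b),   g_t = tanh(W_c [h_{t-1}, x_t] + b_c)

**Word cells.** Each match (b, e) spawns an output-gate-free memory from the
state at its first character:

    c^w_{b,e} = σ(f^w) ⊙ c_b + σ(i^w) ⊙ tanh(g^w),   gates linear in [x^w_{b,e}, h_b]

**Merge.** At the word's last character, an extra *combine gate*
i^c_{b,e} = σ(W^l [x_e, c^w_{b,e}] + b^l) competes with the character
input gate; the gate logits are softmax-normalized elementwise into weights
α (summing to 1 per hidden unit), and

    c_t = Σ_b α_{b,t} ⊙ c^w_{b,t} + α_t ⊙ g_t,   h_t = o_t ⊙ tanh(c_t)

With an empty lexicon this reduces exactly to a character BiLSTM — that
degenerate case is the character baseline.

**Contextual embeddings.** A two-layer bidirectional language model reads
character embeddings directly (no convolutional character encoder), projects
each direction to 50 dims (each layer's representation is a 100-dim
concatenation), and is pretrained on unlabeled text by the joint
forward+backward likelihood. The tagger consumes a softmax-weighted scalar
mix γ Σ_j s_j h_{k,j} of the L+1 layers; the mix weights train with the
tagger, the LM body stays frozen.

**CRF.** Sentence scores S(X,y) = Σ_i p_{i,y_i} + Σ_i A_{y_{i-1},y_i} with
START/STOP states; exact log-partition by the forward algorithm in log
space; exact Viterbi decoding with an optional BIO-schema transition mask.

**Evaluation.** An entity counts only if begin, end and category all match
exactly; reports are per category plus micro-averaged, and replicate runs
are averaged arithmetically.

## Worked example

```bash
python examples/01_corpus_and_lattice.py
```

```
characters: 胃 体 粘 膜
tags:       B-IMG I-IMG I-IMG I-IMG
entities:   [EntitySpan(begin=0, end=4, category='IMG')]

lattice word paths (half-open [begin, end)):
  (0, 2)  胃体
  (0, 4)  胃体粘膜
  (2, 4)  粘膜
```

The three word paths are the lexicon terms found in 胃体粘膜 (gastric
mucosa); the encoder merges 粘膜 and 胃体粘膜 into the character cell at
the final character, alongside the character recurrence itself.

`examples/03_train_and_evaluate.py` trains a small lattice tagger on a
seeded synthetic corpus and prints the strict per-category table:

```
training loss, epochs 1/5/10/25: [10.54, 4.5, 1.79, 0.36]
training F1,   epochs 1/5/10/25: [0.0, 27.8, 73.8, 98.4]

category	precision	recall	f1	gold	pred	match
anatomy	100.00	100.00	100.00	31	31	31
disease	100.00	100.00	100.00	19	19	19
drug	90.91	90.91	90.91	11	11	10
All	98.36	98.36	98.36	61	61	60
```

Loss falls, strict F1 climbs toward 100 as the model fits the corpus; each
row counts gold/predicted/exactly-matched entities for one category.
`examples/04_lexicon_ablation.py` repeats training with and without the
lexicon on deliberately ambiguous data and prints the mean F1 gap the word
lattice delivers.

## Command line

```bash
lattice-ner simulate   --out-dir data --seed 7          # corpus+lexicon+tables
lattice-ner train-bilm --corpus data/unlabeled.txt --epochs 50 --out bilm.npz
lattice-ner train      --train data/corpus.bio --lexicon data/lexicon.txt \
                       --char-emb data/char_emb.vec --word-emb data/word_emb.vec \
                       --bilm bilm.npz --out model.npz
lattice-ner predict    --model model.npz --in data/corpus.bio --out pred.tsv
lattice-ner evaluate   --pred pred.tsv --per-category
```

Every run writes a JSON manifest (config, seed, input checksums, outputs)
next to its output. Config precedence: CLI flag > YAML config > defaults.

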