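# Methods

This note documents the model, the numerical choices, the synthetic-data
design, and the open design decisions of `lattice-ner`, in the order a
reader implementing or auditing the package would need them.

## Problem setting and assumptions

Clinical named entity recognition in Chinese electronic medical records is
framed as per-character BIO sequence tagging: the tagging unit is the
single Unicode code point (no grapheme clustering, no word segmentation),
sentences are obtained by splitting raw record text at sentence-final
punctuation (。；！？ by default; the set is configurable because no
canonical set exists) with a hard split at 200 characters, and entity
categories form a fixed closed set. Over-long sentences are split at the
length cap, with the cut moved left to the nearest O tag so no entity is
severed. Bare `I-X` tags read from a corpus are repaired to `B-X` rather
than dropped — conservative, entity-mass-preserving, and the same policy
applied to decoder output before evaluation.

Internal indices are 0-based half-open `[begin, end)`. The lattice
literature writes 1-based inclusive subscripts (the word spanning the
first two characters is w_{1,2}); converters apply only when printing
worked examples.

## Lattice encoder

The character path is a standard LSTM; lexicon matches add word paths.
Design decisions that are not forced by the architecture:

- **Gate form.** All gates are σ(W[·]+b) / tanh(W[·]+b) with the bias
  inside the nonlinearity, and the combine gate includes a weight matrix,
  σ(W^l [x_e, c^w_{b,e}] + b^l). Gate-like quantities must be bounded and
  dimensionally consistent; a projection-free combine gate would require
  the character-input and hidden dimensions to coincide.
- **Merge normalization.** At a position receiving m word cells, the m
  combine-gate logits and the character input-gate logit are
  softmax-normalized *elementwise* (per hidden unit) so the merged cell is
  a convex combination of word cells and the character candidate; the
  weights sum to 1 within 1e-6 by construction and this is asserted in
  tests. At merge positions the forget path from c_{t-1} is dropped — the
  competition is among word memories and the current candidate.
- **Word-cell spawn point.** A word (b, e) spawns from (h_b, c_b), the
  state *at* its first character, and merges at its last character e-1.
  Word cells have forget and input gates but no output gate: labels are
  predicted only on characters, so word units never emit hidden states
  (asserted structurally — the word-cell function returns only a memory).
- **Positions without word cells** use the plain LSTM update, which makes
  the empty-lexicon encoder *exactly* a character LSTM; this degeneracy is
  verified elementwise against an independent NumPy LSTM.
- **Directionality.** The encoder runs bidirectionally with separate
  forward/backward parameter sets by default (match coordinates are
  mirrored for the backward pass); a unidirectional call exists. The
  lattice construction itself is direction-symmetric, and every serious
  baseline in this family is bidirectional.
- **Lexicon matching** keeps *all* matches, nested and overlapping;
  selection is the encoder's job. Terms are ≥ 2 characters (a 1-character
  word duplicates the character path). Matches are sorted by (end, begin)
  so the encoder can consume "words ending at t" directly. No character
  normalization (e.g. variant forms of the same clinical morpheme) is
  performed.

## Contextual character language model

A two-layer bidirectional LSTM language model whose input is the character
embedding directly — the convolutional character encoder of the original
contextual-embedding architecture is removed, because the character is
already the smallest unit. Per direction, each layer's hidden state is
projected to 50 dims; a layer representation is the 100-dim concatenation
of the two directions, and layer 0 is the 100-dim character embedding
(the embedding width must equal twice the projection width). The training
objective is the joint forward+backward per-token negative log-likelihood;
reported "per-token NLL" sums both directions, so uniform guessing over an
output vocabulary of V costs 2·ln V.

Unforced choices: the pre-projection hidden size defaults to 100
(unstated in the architecture family; small suits desk scale); the output
softmax is full (character vocabularies are small; exactness over
sampling) and shared between directions (halves parameters, standard
practice); BOS/EOS sentinels supply the edge conditionals and are never
predicted or represented; pretraining uses Adam (lr 0.01) — the SGD
recipe below is specific to tagger training, and nothing ties the LM
pretraining to it. During tagger training the LM body is frozen and only
the scalar-mix weights (softmax-normalized layer weights s and the global
scale γ, initialized uniform and 1) are trained; per-sentence layer
stacks are therefore computed once and cached.

## CRF

Emission scores are unnormalized logits (calling them probabilities would
make the global normalization incoherent); START/STOP are explicit states
and structurally impossible transitions carry an additive −1e4 rather than
−∞, keeping log-sum-exp gradients finite. The log-partition uses the
forward recursion in log space; decoding is exact Viterbi with ties broken
toward the lowest label index (determinism for tests). A BIO transition
mask (no entry into `I-X` except from `B-X`/`I-X`) is applied at decode
time by default and never during training; on schema-consistent data it
cannot make the gold path infeasible.

## Training recipe

Defaults are the reference settings for this architecture family:
embeddings 100-dim (characters, words, contextual), LSTM hidden 200, one
encoder layer, dropout 0.5 (inverted, on the concatenated input embedding
only — not on hidden states), SGD at batch size 1, lr 0.015 with schedule
lr₀/(1 + 0.05·epoch) (the decay constant is named in the family's
recipe; this hyperbolic schedule is the one its reference implementations
use), 10 epochs. Model selection keeps the best-dev-F1 epoch; an optional
early-stop threshold on dev F1 exists for overfit-style runs. All
randomness — initialization, shuffling, dropout masks — flows from a
single integer seed, and two runs with the same seed produce bit-identical
loss trajectories.

Gradient-norm clipping defaults to 50. Measured per-sentence gradient
norms for this model at initialization are roughly 10–40, so a ceiling of
50 damps only rare spikes; a much lower ceiling (e.g. the commonly copied
5.0) silently rescales every update into a ~4× smaller learning rate and
materially slows batch-size-1 SGD.

Word embeddings of lexicon terms absent from the supplied table start from
the table's seeded UNK row; embedding tables are fine-tuned with the
tagger (configurable). Disabling the lexicon yields the character
BiLSTM-CRF baseline; disabling the contextual embedding yields the plain
lattice-LSTM-CRF — both ablations are reachable by configuration flags
alone, with no code changes.

## Evaluation

Strict matching: a predicted entity counts only when sentence, begin, end
and category all agree with a gold entity. Metrics are percentages;
0/0 is defined as 0; duplicate identical gold spans are collapsed;
predictions are BIO-repaired before span extraction. Replicate protocol:
n independently seeded training runs, arithmetic mean of P/R/F1.

## Synthetic data

The generator emulates the *structure* of clinical NER corpora — not
their language: short sentences of single characters from a private-use
Unicode alphabet, a fixed category set (six by default: anatomy, disease,
drug, image, laboratory, operation), entities that are exact terms of a
2–5-character lexicon inserted at a Poisson rate per sentence (default
density 1.5), and — the property the lattice exists to exploit —
*ambiguity*: at ambiguity rate a, a share of lexicon terms is built to
overlap other terms, and the filler text contains decoy fragments (proper
prefixes of terms that are not themselves terms, and contain no complete
term). A character-only model sees entity-like material tagged O; the
lexicon tells the lattice model no complete term is present. At a = 0,
terms are constructed over pairwise-disjoint character sets (no shared
bigrams). Embedding tables are seeded Gaussians with component scale 0.5,
giving 100-dim vector norms near 5 — the magnitude range of real
word2vec-trained tables; unit-norm vectors would understate the input
signal real systems receive.

Default sentence lengths are 10–25 characters: clinical sentences after
punctuation splitting are short, and the quadratic-free desk-scale cost
keeps the full benchmark suite in minutes. For the language-model
memorization benchmark a separate generator produces cyclic-pattern
sentences (a fixed 4-character cycle entered at a random phase, length
40): the corpus is deterministic except for the phase, so the irreducible
per-token NLL is ≈ 2·ln(4)/40 ≈ 0.07 and an adequately trained LM must
approach it — a capacity/optimization sanity check with a computable
floor.

What passing synthetic benchmarks does **not** show: robustness to real
clinical language (mixed alphanumeric laboratory entities, abbreviations,
variant forms), realistic label imbalance, or cross-document effects.
The benchmarks validate the machinery — exact inference, gradient
correctness, the lattice's use of lexicon evidence — not clinical-grade
accuracy.

## Benchmark problem sizes

The shipped benchmarks are sized for a single CPU: the overfit benchmark
trains the full model (contextual embeddings on, reference
hyperparameters, up to 30 epochs with early stop at 100% training F1) on
200 sentences; the lexicon-benefit experiment uses a 100/50 train/test
split at ambiguity 0.5 with 5 replicate seeds per configuration and the
contextual embedding off (the property under test isolates the lexicon);
LM memorization uses 50 sentences and a 16-dim model. These sizes are the
package's benchmark definitions, chosen once.

## Known limitations

- Batch size is fixed at 1 for the tagger (the lattice computation is
  input-dependent); the LM pretrainer batches over sentences.
- No GPU path; NumPy float64 throughout. Fine at benchmark scale, slow for
  corpora of tens of thousands of sentences.
- The BIO decode mask assumes the label set is exactly {O} ∪ {B-,I-}×cats.
- Lexicon matching is exact; orthographic variants of a term are distinct
  terms.
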