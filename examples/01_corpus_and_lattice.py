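"""Build a tiny BIO corpus and inspect its word lattice.

Shows how a sentence's characters, its gold BIO tags and the lexicon
matches that form the word lattice relate to one another.
"""

from lattice_ner import build_lexicon, spans_from_tags
from lattice_ner.corpus_io import AnnotatedSentence

# the classic worked example: "胃体粘膜" (gastric mucosa), an image-entity
sentence = AnnotatedSentence(list("胃体粘膜"),
                             ["B-IMG", "I-IMG", "I-IMG", "I-IMG"])
lexicon = build_lexicon(["胃体", "粘膜", "胃体粘膜"])

print("characters:", " ".join(sentence.chars))
print("tags:      ", " ".join(sentence.tags))
print("entities:  ", spans_from_tags(sentence.tags))

print("\nlattice word paths (half-open [begin, end)):")
for m in lexicon.match(sentence.chars):
    term = lexicon.terms[m.term_id]
    print(f"  ({m.begin}, {m.end})  {term}")
# Three paths: the two 2-character terms and the full 4-character term.
# The encoder merges each one into the character path at its last
# character, so position 3 receives word memories from both 粘膜 and
# 胃体粘膜 in addition to the character recurrence.
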