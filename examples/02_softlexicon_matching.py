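"""The B/M/E/S word-set worked example on the sentence 植物病害.

Shows how each character collects the lexicon words containing it, split by
the character's position inside the word, and how the sets pool into
frequency-weighted vectors.
"""

import numpy as np

from kiwiner.corpus_io import Lexicon, random_embeddings
from kiwiner.lexmatch import match_word_sets, softlexicon_feature

sentence = "植物病害"
lexicon = Lexicon({"植物": 5, "病害": 3, "植物病害": 2, "病": 4})
embeddings = random_embeddings(list(lexicon), dim=8, seed=0)

for i, ch in enumerate(sentence):
    ws = match_word_sets(sentence, lexicon, i)
    fmt = lambda part: "{" + ", ".join(f"{w}:{z}" for w, z in part) + "}"
    print(f"{ch}: B={fmt(ws.b)} M={fmt(ws.m)} E={fmt(ws.e)} S={fmt(ws.s)}  Z={ws.z_total}")

# the character 物 matches exactly two words: 植物病害 (middle) and 植物 (end)
ws = match_word_sets(sentence, lexicon, 1)
print(f"\n物 matches {len(ws.matched_words)} words: {ws.matched_words}")

x_c = np.zeros(8)
fused = softlexicon_feature(x_c, ws, embeddings)
print(f"fused feature length: {len(fused)} (= d_char + 4 * d_word = 8 + 32)")
mass = sum(4 * z / ws.z_total for part in ws.as_tuple() for _, z in part)
print(f"total set-weight mass: {mass:.6f} (identically 4 by the weighting identity)")
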