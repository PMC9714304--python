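"""Detect domain words in a raw corpus and build an NER lexicon.

Generates a synthetic corpus with planted multi-character domain terms,
runs the WF/MI/CE filter cascade, and segments the corpus with the
augmented dictionary to produce the word-frequency lexicon.
"""

from kiwiner.newword import DetectionThresholds, SegmenterDict, build_lexicon, detect_new_words
from kiwiner.synthetic import SynthSpec, generate

world, corpus = generate(SynthSpec(seed=1))
base = SegmenterDict(world.common_words)  # stands in for a segmenter's built-ins

found = detect_new_words(corpus.raw, DetectionThresholds(), base)
planted = [w for w in world.domain_words
           if w in corpus.gold_lexicon and corpus.gold_lexicon.freq(w) >= 10]
recall = 100.0 * sum(w in found for w in planted) / len(planted)

print(f"corpus: {len(corpus.raw)} sentences, {len(world.domain_words)} planted domain words")
print(f"detected {len(found)} new words at thresholds WF>=5, MI>=3.9 bits, CE>=2.7 bits")
print(f"recall of planted words with frequency >= 10: {recall:.1f}%")

some = sorted(found, key=lambda w: -found[w].wf)[:3]
for w in some:
    s = found[w]
    print(f"  example candidate: wf={s.wf}  mi={s.mi:.2f}  el={s.el:.2f}  er={s.er:.2f}")

lexicon = build_lexicon(corpus.raw, base, found)
print(f"lexicon from re-segmented corpus: {len(lexicon)} multi-character words")
# High recall means the cohesion/diversity statistics separate real planted
# words from window noise; the lexicon frequencies z(w) feed the tagger's
# Softlexicon weighting.
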