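# Methods

This note records the modelling conventions, numerical choices and open
design decisions behind `kiwiner`, in the spirit of a model card for the
pipeline. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## New-word detection

Candidates are all windows of length 2–4 lying inside punctuation-free
segments (the punctuation set is configurable; windows never cross it).
Statistics, all in base-2 logarithms:

* **WF** — the window count of the candidate.
* **MI** — for a bigram, `log2(p(w) / (p(w1) p(w2)))`, where `p(s) =
  count(s) / (#windows of length |s|)`; each split part is normalised by
  its *own* length's window total. For 3- and 4-grams the bigram formula
  only defines cohesion for one cut, so we score **every** internal binary
  split and take the **minimum** — a string is only as cohesive as its
  weakest split. This is conservative: it can only reduce MI relative to
  any single-split convention.
* **CE** — entropy of the left (and, separately, right) neighbour
  distribution over all occurrences. An occurrence at a segment boundary
  contributes a distinguished `BOUNDARY` pseudo-neighbour, so clause-initial
  words get a well-defined deterministic context instead of being skipped.
  The threshold applies to `min(El, Er)`: a free-standing word must be
  combinable on both sides, which matches the motivation of branching
  entropy.

The filter cascade (WF, then MI, then CE, then membership in the base
dictionary) is monotone in every threshold. Defaults are WF ≥ 5, MI ≥ 3.9
bits, CE ≥ 2.7 bits. Nested candidates that all pass are all kept; no
de-duplication rule is applied.

The segmenter used for lexicon construction is a built-in deterministic
forward-maximum-matching dictionary segmenter (longest match left to right,
single-character fallback), so the package carries no external segmenter
dependency; anything exposing `segment`/`__contains__` can be plugged in
instead. The statistics and the filter are segmenter-independent. Lexicon
frequencies `z(w)` count how often `w` was produced as a segment; single
characters are never lexicon entries.

## Softlexicon features

The four word sets follow the standard position semantics: `B(ci)` words
starting at `i` with length ≥ 2, `E(ci)` words ending at `i`, `M(ci)` words
strictly containing `i` in their interior, `S(ci)` the single character if
it is itself a lexicon word. An empty set is represented by a `<NONE>`
placeholder with frequency 1 that participates in the normaliser `Z`; this
keeps the pooled vector defined for empty sets, and `<NONE>` has its own
(zero-initialised, trainable) embedding. The per-character weight mass
`Σ_sets Σ_w 4 z(w)/Z` is identically 4, and pooled vectors are invariant to
scaling all frequencies by a constant.

`z(w)` is the static lexicon frequency fixed at lexicon build time; no
per-batch re-counting. Matching is trie-backed and capped at the longest
lexicon word, and is verified against a brute-force all-substrings scanner.

One documented divergence: the published worked example for the character
病 in 植物病害 lists `B={病害}, M={None}` even though 植物病害 is in the
example lexicon and, by the set definitions, holds 病 as an interior
character. The implementation follows the definitions (`M={植物病害}`);
the formulas beat the worked example.

## Criss-cross attention and gates

The block projects a `C×W×H` map to queries/keys (`C' = max(1, C/8)`,
bias-free 1×1 convolutions) and values (`C→C`, bias-free), computes
affinities of each position against the `H+W−1` positions in its row and
column (the position itself counted once), softmaxes them, aggregates the
values and adds the input (residual). Two exact structural properties are
used as test oracles: a zero value projection makes the block the identity,
and at `H = 1` the block equals dense softmax attention along the width.

For the per-set gates, the four pooled set vectors form a `d_w×4×1` map fed
through a criss-cross block; the flattened output passes one shared affine
map to 4 logits and a sigmoid. Gates are independent values in (0,1) — not
a distribution — so forcing all gates to 1 reproduces the static
Softlexicon feature exactly (an identity the tests assert). The flattening
order is a free convention since the affine map is learned.

## PCAT

Two parallel branches over the `[C,W,1]` encoder output: conv1×1 → CC →
conv1×3, and conv1×3 → CC → conv1×3, summed. Published descriptions leave
the convolution details open; here convolutions carry a bias, use no
nonlinearity, and pad symmetrically with zeros so the width is preserved
for every `W ≥ 1`. The two branches do not share criss-cross weights.
Intermediate channel counts stay at `C`.

## Tagger and training

Architecture: fused character features (dropout applied here during
training) → single-layer BiLSTM → PCAT → linear emissions → linear-chain
CRF over the BMES-O tagset with START/STOP transitions. The reference
hyper-parameters are the defaults: 50-dim character and word embeddings,
300 hidden units per direction, dropout 0.5, batch 16, SGD with initial
learning rate 0.0015 and schedule `lr_e = lr0 / (1 + 0.05 e)`. Gradient
clipping at global L2 norm 5 is added for stability (configurable, not part
of the reference recipe). Embeddings are trainable; pretrained tables
initialise them when supplied, otherwise seeded uniform(−0.1, 0.1).

Viterbi decoding masks impossible BMES transitions (entering M/E from
outside the entity's B/M run, opening a sentence with M/E, stopping inside
an entity) with −∞, so decoded sequences are always well-formed; ties break
toward the lowest tag index. The CRF forward recursion uses a
constant-shift log-sum-exp; partition and Viterbi are validated against
exhaustive path enumeration, and the NLL gradient against finite
differences.

The engine is a ~300-line reverse-mode autograd over float64 numpy arrays.
Float64 keeps same-seed runs bitwise identical, which the determinism
contract (identical epoch-1 loss for identical seeds) relies on.

**Desk-scale demonstration config.** The learnability checks train a small
model (16-dim embeddings, 32 hidden units, dropout 0, SGD lr 0.5 with the
same decay schedule) on 200 synthetic sentences for up to 30 epochs. This
is the package's own choice of demonstration scale: the reference recipe
(lr 0.0015, dropout 0.5, 300 hidden units) is tuned for multi-thousand-
sentence corpora and long schedules, while a memorization check wants a
small model driven hard. Dropout is disabled precisely because the point is
to overfit; the learning rate was chosen for a plain-SGD CRF objective at
this model size.

## Synthetic data

The generator builds: an alphabet of private-use pseudo-characters
(default 300); background "common" words of length 1–3 over a 150-character
frequent pool; and 60 multi-character domain words over the full alphabet,
spread over 6 categories with Zipf category proportions. Frequencies use
Zipf–Mandelbrot laws (shifts 10 for characters, 3 for words): with a
truncated inventory, an unshifted Zipf law concentrates an unrealistically
large share of tokens on the top item (real running text gives its most
frequent character a few percent), and the shift restores realistic
marginals. A configurable fraction (default 0.3, exact by construction) of
domain words nests a shorter vocabulary word as a proper substring.
Sentences concatenate sampled words (mean 6 words, Poisson), with a 0.25
chance per slot of drawing an entity word; boundaries are recorded, so gold
spans, gold segmentation and gold lexicon frequencies are exact by
construction.

What the generator does **not** emulate: real orthography, morphology,
grammatical word order, ambiguous segmentations across word boundaries,
annotation noise, and context cues that correlate with entity categories.
Passing tests therefore demonstrate the correctness of the statistics,
matching, algebra and optimisation — not state-of-the-art accuracy on real
agricultural text, which additionally depends on pretrained embeddings and
corpus scale.

## Degenerate inputs and edge conventions

* Ill-formed BMES runs decode to no entity (conservative repair): dropping
  rather than repairing avoids inflating true positives in evaluation.
* Coordinates are 0-based half-open throughout.
* Duplicate lexicon rows merge by summation with a warning (supports
  concatenating lexicon shards).
* Zero-denominator precision/recall report 0 with an `undefined` flag.
* Empty word sets, width-1 sequences, and single-character sentences are
  all exercised in tests.

## Known limitations

* Training is pure-numpy and single-threaded: practical up to thousands of
  short sentences, not millions.
* MI normalisation and the multi-gram split rule are explicit conventions;
  published descriptions of the statistics leave them open, and other
  choices (mean split, joint normalisation) would shift the detector's
  operating point.
* The general `H > 1` criss-cross path is a readable position loop used by
  tests; only the `H = 1` fast path is used by the tagger.
* No recurrent (multi-sweep) criss-cross, no alternative encoders beyond
  the BiLSTM, and no partial-credit evaluation.
* Whether the learned per-set gates beat static frequency weighting is a
  claim about large-corpus behaviour; at the desk scale of this test suite
  the comparison is noise-dominated, so the suite logs the two held-out F1
  scores side by side without asserting a direction.
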