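"""Seeded synthetic corpora emulating an annotated agricultural NER dataset.

The real training data for this kind of model is a hand-annotated corpus of
domain text.  This module fabricates a statistically similar world so every
other module can be exercised end to end without any download:

* a vocabulary of common (background) words and multi-character domain
  entity words of lengths 2-4 spread over several categories;
* uneven, Zipf-like category sizes (real entity inventories are skewed);
* a configurable fraction of entity words that nest a shorter vocabulary
  word as a proper substring (nested entities are endemic in the domain);
* sentences assembled by concatenating sampled words, which gives a
  well-defined gold segmentation, gold entity spans, and a gold lexicon with
  exact frequencies.

Pseudo-characters come from the Unicode private-use area (U+E000 ...), so no
real-language assumption can leak into tests.  Common words draw their
characters from a small, Zipf-biased pool of "frequent" characters while
domain words draw uniformly from the whole alphabet — mirroring real Chinese
text, where technical terms use rarer characters than function words.
Everything is bitwise-determined by the spec seed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .corpus_io import EntitySpan, Lexicon, TaggedSentence, spans_to_tags

_PUA_BASE = 0xE000


@dataclass
class SynthSpec:
    """Parameters of the synthetic world and corpus."""

    alphabet_size: int = 300
    n_common_words: int = 100
    n_domain_words: int = 60
    n_categories: int = 6
    category_proportions: Optional[Sequence[float]] = None  # default: Zipf
    nested_fraction: float = 0.3
    n_sentences: int = 2000
    mean_sentence_words: float = 6.0
    entity_token_rate: float = 0.25  # share of word slots drawing an entity word
    n_common_chars: int = 150       # pool for common-word characters
    seed: int = 0

    def __post_init__(self) -> None:
        if self.category_proportions is None:
            raw = 1.0 / (1.0 + np.arange(self.n_categories))
            self.category_proportions = tuple(raw / raw.sum())
        props = np.asarray(self.category_proportions, dtype=float)
        if len(props) != self.n_categories or not np.isclose(props.sum(), 1.0):
            raise ValueError("category_proportions must have n_categories entries summing to 1")
        if not 0.0 <= self.nested_fraction <= 1.0:
            raise ValueError("nested_fraction must be in [0, 1]")
        if self.n_common_chars > self.alphabet_size:
            raise ValueError("n_common_chars cannot exceed alphabet_size")


@dataclass
class World:
    """Generated vocabulary: background words plus categorised entity words."""

    alphabet: List[str]
    common_words: List[str]
    domain_words: Dict[str, str]          # word -> category
    categories: List[str]
    nested_words: List[str] = field(default_factory=list)

    @property
    def all_words(self) -> List[str]:
        return self.common_words + list(self.domain_words)


def _categories(n: int) -> List[str]:
    base = ["KIWI", "DIS", "PEST", "PART", "MED", "LOC"]
    if n <= len(base):
        return base[:n]
    return base + [f"CAT{i}" for i in range(n - len(base))]


def generate_world(spec: SynthSpec) -> World:
    """Deterministically build the vocabulary for *spec*.

    Exactly ``round(nested_fraction * n_domain_words)`` entity words are
    constructed around a shorter vocabulary word as a proper substring.
    """
    rng = np.random.default_rng(spec.seed)
    alphabet = [chr(_PUA_BASE + i) for i in range(spec.alphabet_size)]
    max_words = spec.alphabet_size**2  # loose feasibility bound on 2-char words
    if spec.n_common_words + spec.n_domain_words > max_words:
        raise ValueError("vocabulary larger than the combinatorial space")

    # Frequent words reuse a pool of frequent characters.  The pool follows a
    # Zipf-Mandelbrot law (shift 10): with a truncated inventory a pure Zipf
    # law would give the top character an unrealistically large marginal
    # (real running text tops out around a few percent per character).
    common_pool = alphabet[: spec.n_common_chars]
    pool_p = 1.0 / (10.0 + np.arange(len(common_pool)))
    pool_p /= pool_p.sum()

    used: set = set()

    def fresh(make) -> str:
        for _ in range(10000):
            w = make()
            if w not in used:
                used.add(w)
                return w
        raise RuntimeError("could not generate a fresh word; alphabet too small")

    common_words: List[str] = []
    for _ in range(spec.n_common_words):
        length = int(rng.choice([1, 2, 2, 3]))
        common_words.append(
            fresh(lambda: "".join(rng.choice(common_pool, size=length, p=pool_p)))
        )

    categories = _categories(spec.n_categories)
    n_nested = round(spec.nested_fraction * spec.n_domain_words)
    domain_words: Dict[str, str] = {}
    nested_words: List[str] = []
    cat_cycle = rng.choice(
        spec.n_categories, size=spec.n_domain_words, p=np.asarray(spec.category_proportions)
    )
    inner_candidates = [w for w in common_words if len(w) <= 2]
    for k in range(spec.n_domain_words):
        if k < n_nested and inner_candidates:
            # nest a shorter existing word as a proper substring
            def make_nested() -> str:
                inner = inner_candidates[int(rng.integers(len(inner_candidates)))]
                extra = int(rng.integers(1, 5 - len(inner))) if len(inner) < 4 else 1
                pad = "".join(
                    alphabet[int(rng.integers(spec.alphabet_size))] for _ in range(extra)
                )
                cut = int(rng.integers(len(pad) + 1))
                return pad[:cut] + inner + pad[cut:]

            w = fresh(make_nested)
            nested_words.append(w)
        else:
            length = int(rng.integers(2, 5))
            w = fresh(
                lambda: "".join(
                    alphabet[int(rng.integers(spec.alphabet_size))] for _ in range(length)
                )
            )
        domain_words[w] = categories[int(cat_cycle[k])]
    return World(alphabet, common_words, domain_words, categories, nested_words)


class SynthCorpus(NamedTuple):
    """Generated corpus with recorded word boundaries."""

    raw: List[str]                      # sentences, for new-word detection
    tagged: List[TaggedSentence]        # gold BMES-O taggings
    gold_lexicon: Lexicon               # true multi-character words + counts
    word_sequences: List[List[str]]     # the sampled words per sentence


def generate_corpora(world: World, spec: SynthSpec) -> SynthCorpus:
    """Sample the corpus: raw sentences, gold taggings, and the gold lexicon.

    Each sentence concatenates sampled words; entity-word occurrences become
    gold spans (rendered to BMES-O tags), and the gold lexicon counts every
    multi-character word occurrence.  The sampled word sequences are returned
    too, so frequencies and segmentations can be checked independently.
    """
    rng = np.random.default_rng(spec.seed + 1)
    common = world.common_words
    # Zipf-Mandelbrot (shift 3) over the truncated background vocabulary,
    # keeping the top word's token share near real-text levels.
    common_p = 1.0 / (3.0 + np.arange(len(common)))
    common_p /= common_p.sum()
    domain = list(world.domain_words)
    cat_of = world.domain_words
    props = np.asarray(spec.category_proportions, dtype=float)
    by_cat: Dict[str, List[str]] = {c: [] for c in world.categories}
    for w, c in cat_of.items():
        by_cat[c].append(w)
    active = [c for c in world.categories if by_cat[c]]
    active_p = np.array([props[world.categories.index(c)] for c in active])
    active_p /= active_p.sum()

    raw: List[str] = []
    tagged: List[TaggedSentence] = []
    word_seqs: List[List[str]] = []
    word_freqs: Counter = Counter()
    for _ in range(spec.n_sentences):
        n_words = max(1, int(rng.poisson(spec.mean_sentence_words)))
        words: List[str] = []
        spans: List[EntitySpan] = []
        pos = 0
        for _ in range(n_words):
            if domain and rng.random() < spec.entity_token_rate:
                cat = active[int(rng.choice(len(active), p=active_p))]
                pool = by_cat[cat]
                # Zipf within category: frequent terms dominate, tail stays rare
                p = 1.0 / (1.0 + np.arange(len(pool)))
                p /= p.sum()
                w = pool[int(rng.choice(len(pool), p=p))]
                spans.append(EntitySpan(pos, pos + len(w), cat))
            else:
                w = common[int(rng.choice(len(common), p=common_p))]
            words.append(w)
            word_freqs[w] += 1
            pos += len(w)
        text = "".join(words)
        raw.append(text)
        word_seqs.append(words)
        tagged.append(TaggedSentence(text, spans_to_tags(spans, len(text))))

    gold_lex = Lexicon()
    for w, c in word_freqs.items():
        if len(w) >= 2:
            gold_lex.add(w, c)
    return SynthCorpus(raw, tagged, gold_lex, word_seqs)


def generate(spec: SynthSpec) -> Tuple[World, SynthCorpus]:
    """Convenience wrapper: world plus corpora in one call."""
    world = generate_world(spec)
    return world, generate_corpora(world, spec)
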