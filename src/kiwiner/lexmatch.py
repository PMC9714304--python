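"""BMES word-set matching and frequency-weighted Softlexicon features.

For character ``c_i`` of a sentence, every lexicon word containing ``c_i``
is routed to one of four sets by the character's position in the word:

* ``B(c_i)`` — words beginning at i (length >= 2),
* ``M(c_i)`` — words strictly containing i in their interior,
* ``E(c_i)`` — words ending at i (length >= 2),
* ``S(c_i)`` — the single character itself, if it is a lexicon word.

An empty set is represented by the placeholder ``(<NONE>, 1)`` so the
frequency-weighted mean below stays defined.  Each set is pooled into one
vector weighted by static lexicon frequency z(w):

    v(S) = (4/Z) * sum_{w in S} z(w) e_w(w),   Z = sum over all four sets.

The baseline character feature concatenates the character embedding with the
four pooled vectors; the attention-weighted variant (neural module) rescales
each pooled vector by a learned per-set gate before concatenation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .corpus_io import NONE_TOKEN, EmbeddingTable, Lexicon

logger = logging.getLogger(__name__)

_warned_missing: set = set()


@dataclass
class WordSets:
    """The four matched word sets for one character: (word, z(w)) pairs."""

    b: List[Tuple[str, int]]
    m: List[Tuple[str, int]]
    e: List[Tuple[str, int]]
    s: List[Tuple[str, int]]

    def as_tuple(self) -> Tuple[List[Tuple[str, int]], ...]:
        return (self.b, self.m, self.e, self.s)

    @property
    def z_total(self) -> int:
        """Z: summed frequency over the union of all four sets (NONE counts 1)."""
        return sum(z for word_set in self.as_tuple() for _, z in word_set)

    @property
    def matched_words(self) -> List[str]:
        """All real (non-placeholder) matched words."""
        return [w for word_set in self.as_tuple() for w, _ in word_set if w != NONE_TOKEN]


_EMPTY = [(NONE_TOKEN, 1)]


def match_word_sets(sentence: str, lexicon: Lexicon, i: int) -> WordSets:
    """Match character *i* of *sentence* against *lexicon* into B/M/E/S sets.

    Uses the lexicon trie: for each feasible start position j <= i a single
    trie walk enumerates all lexicon words covering position i, so the cost
    is O(max word length ** 2) per character, independent of lexicon size.
    Words within a set are ordered by increasing start index, then length.
    """
    n = len(sentence)
    if not 0 <= i < n:
        raise IndexError(f"character index {i} out of range for length {n}")
    b: List[Tuple[str, int]] = []
    m: List[Tuple[str, int]] = []
    e: List[Tuple[str, int]] = []
    s: List[Tuple[str, int]] = []
    lo = max(0, i - lexicon.max_word_len + 1)
    for j in range(lo, i + 1):
        for word, end in lexicon.words_starting_at(sentence, j):
            if end <= i:  # word lies entirely before position i
                continue
            z = lexicon.freq(word)
            length = end - j
            if length == 1:
                s.append((word, z))  # j == i here
            elif j == i:
                b.append((word, z))
            elif end - 1 == i:
                e.append((word, z))
            else:
                m.append((word, z))
    return WordSets(b or list(_EMPTY), m or list(_EMPTY), e or list(_EMPTY), s or list(_EMPTY))


def weighted_set_vector(
    word_set: List[Tuple[str, int]], z_total: int, embeddings: EmbeddingTable
) -> np.ndarray:
    """Frequency-weighted pooled vector (4/Z) * sum z(w) e_w(w) for one set.

    Words missing from the embedding table fall back to the UNK vector (logged
    once per word).
    """
    if z_total <= 0:
        raise ValueError("z_total must be positive")
    v = np.zeros(embeddings.dim)
    for word, z in word_set:
        if word not in embeddings and word not in _warned_missing:
            _warned_missing.add(word)
            logger.warning("word %r missing from embedding table; using UNK", word)
        v += z * embeddings.get(word)
    return (4.0 / z_total) * v


def softlexicon_feature(
    x_c: np.ndarray, word_sets: WordSets, embeddings: EmbeddingTable
) -> np.ndarray:
    """Baseline fused feature: concat(x_c, v_B, v_M, v_E, v_S).

    Output length is d_char + 4 * d_word.  This is the static (frequency
    only) weighting; the learned per-set gates live in the neural module and
    reduce to this exactly when every gate equals 1.
    """
    z = word_sets.z_total
    parts = [np.asarray(x_c, dtype=float)]
    for word_set in word_sets.as_tuple():
        parts.append(weighted_set_vector(word_set, z, embeddings))
    return np.concatenate(parts)


def sentence_word_sets(sentence: str, lexicon: Lexicon) -> List[WordSets]:
    """B/M/E/S sets for every character of a sentence."""
    return [match_word_sets(sentence, lexicon, i) for i in range(len(sentence))]
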