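"""Statistics-based new-word detection and lexicon construction.

Out-of-vocabulary domain terms (disease names, chemicals, cultivar names)
break dictionary segmenters and thereby poison any lexicon built from their
output.  This module discovers such terms directly from a raw corpus:

1. candidate strings are all N-gram windows (N = 2, 3, 4) that lie inside a
   punctuation-free segment;
2. each candidate is scored by word frequency (WF), mutual information
   (MI, internal cohesion in bits) and left/right contextual entropy
   (CE, diversity of adjacent characters in bits);
3. candidates are filtered in turn by thresholds on WF, MI and CE
   (defaults 5 / 3.9 / 2.7), and words already known to the segmenter
   are dropped;
4. the surviving new words are added to a dictionary segmenter, which then
   segments a second corpus to produce the NER lexicon with frequencies.

All logarithms are base 2.  MI for 3- and 4-grams is the minimum over all
internal binary split points — a string is only as cohesive as its weakest
split.  The CE filter applies to min(left, right) entropy, so a word must be
freely combinable on both sides.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .corpus_io import Lexicon

#: Sentinel left/right neighbor for occurrences at a segment boundary.
BOUNDARY = "<BOUNDARY>"

#: Characters that terminate a candidate segment (no window may cross them).
DEFAULT_PUNCTUATION = set(
    "，。！？；：、“”‘’（）《》〈〉【】…—·,.!?;:()[]<>\"' \t　"
)


@dataclass(frozen=True)
class DetectionThresholds:
    """Filter thresholds: word frequency, cohesion (bits), context entropy (bits)."""

    wf_min: int = 5
    mi_min: float = 3.9
    ce_min: float = 2.7

    def __post_init__(self) -> None:
        if self.wf_min < 0 or self.mi_min < 0 or self.ce_min < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class NgramStats:
    """Audit record for one candidate string."""

    string: str
    wf: int
    mi: float
    el: float
    er: float

    @property
    def ce(self) -> float:
        """The filtered context-entropy statistic: min of the two sides."""
        return min(self.el, self.er)


@dataclass
class NgramCounts:
    """Window counts per length plus window-position totals per length."""

    counts: Dict[int, Counter] = field(default_factory=dict)
    totals: Dict[int, int] = field(default_factory=dict)

    def prob(self, s: str) -> float:
        n = len(s)
        total = self.totals.get(n, 0)
        if total == 0:
            raise ValueError(f"no windows of length {n} were counted")
        c = self.counts[n].get(s, 0)
        if c == 0:
            raise ValueError(f"string {s!r} never observed")
        return c / total


def split_segments(sentence: str, punctuation: Optional[Set[str]] = None) -> List[str]:
    """Split a sentence into maximal punctuation-free segments."""
    punct = DEFAULT_PUNCTUATION if punctuation is None else punctuation
    segments: List[str] = []
    buf: List[str] = []
    for ch in sentence:
        if ch in punct:
            if buf:
                segments.append("".join(buf))
                buf = []
        else:
            buf.append(ch)
    if buf:
        segments.append("".join(buf))
    return segments


def extract_ngram_counts(
    corpus: Iterable[str],
    n_values: Sequence[int] = (2, 3, 4),
    punctuation: Optional[Set[str]] = None,
) -> NgramCounts:
    """Count every N-gram window inside punctuation-free segments.

    Unigram counts are always collected as well, because MI split parts of
    length 1 need their own probabilities.
    """
    if not set(n_values) <= {2, 3, 4}:
        raise ValueError("candidate lengths must be drawn from {2, 3, 4}")
    lengths = sorted(set(n_values) | {1})
    out = NgramCounts({n: Counter() for n in lengths}, {n: 0 for n in lengths})
    for sentence in corpus:
        for seg in split_segments(sentence, punctuation):
            for n in lengths:
                m = len(seg) - n + 1
                if m <= 0:
                    continue
                ctr = out.counts[n]
                for i in range(m):
                    ctr[seg[i : i + n]] += 1
                out.totals[n] += m
    return out


def mutual_information(w: str, counts: NgramCounts) -> float:
    """Cohesion of *w* in bits.

    For a bigram this is ``log2(p(w) / (p(w1) p(w2)))`` with each probability
    normalised by its own length's window total.  Longer candidates take the
    minimum over all internal binary splits.
    """
    if len(w) < 2:
        raise ValueError("MI requires at least two characters")
    p_w = counts.prob(w)
    best = math.inf
    for k in range(1, len(w)):
        left, right = w[:k], w[k:]
        mi = math.log2(p_w / (counts.prob(left) * counts.prob(right)))
        best = min(best, mi)
    return best


def _entropy(counter: Counter) -> float:
    total = sum(counter.values())
    if total == 0:
        return 0.0
    h = 0.0
    for c in counter.values():
        p = c / total
        h -= p * math.log2(p)
    return h


class NeighborIndex:
    """Left/right neighbor distributions for every candidate window.

    Built in a single pass over the corpus so that contextual entropy for all
    candidates costs O(corpus size), not O(candidates x corpus size).
    """

    def __init__(
        self,
        corpus: Iterable[str],
        n_values: Sequence[int] = (2, 3, 4),
        punctuation: Optional[Set[str]] = None,
    ):
        self.left: Dict[str, Counter] = defaultdict(Counter)
        self.right: Dict[str, Counter] = defaultdict(Counter)
        lengths = sorted(set(n_values))
        for sentence in corpus:
            for seg in split_segments(sentence, punctuation):
                for n in lengths:
                    for i in range(len(seg) - n + 1):
                        w = seg[i : i + n]
                        self.left[w][seg[i - 1] if i > 0 else BOUNDARY] += 1
                        self.right[w][seg[i + n] if i + n < len(seg) else BOUNDARY] += 1

    def entropies(self, w: str) -> Tuple[float, float]:
        return _entropy(self.left[w]), _entropy(self.right[w])


def contextual_entropy(
    w: str, corpus: Iterable[str], punctuation: Optional[Set[str]] = None
) -> Tuple[float, float]:
    """Left and right neighbor entropies of *w* in bits.

    Occurrences at a segment boundary contribute a distinguished BOUNDARY
    pseudo-neighbor, so a word that always starts a clause still shows a
    deterministic (zero-entropy) left context rather than an undefined one.
    """
    left: Counter = Counter()
    right: Counter = Counter()
    n = len(w)
    found = False
    for sentence in corpus:
        for seg in split_segments(sentence, punctuation):
            start = 0
            while True:
                i = seg.find(w, start)
                if i < 0:
                    break
                found = True
                left[seg[i - 1] if i > 0 else BOUNDARY] += 1
                right[seg[i + n] if i + n < len(seg) else BOUNDARY] += 1
                start = i + 1
    if not found:
        raise ValueError(f"string {w!r} does not occur in the corpus")
    return _entropy(left), _entropy(right)


class SegmenterDict:
    """Deterministic forward-maximum-matching dictionary segmenter.

    Scans left to right, always consuming the longest dictionary word that
    starts at the current position, falling back to a single character.  The
    concatenation of the produced segments always reproduces the input.  An
    external segmenter can be plugged in wherever a ``SegmenterDict`` is
    accepted, as long as it offers ``segment`` and ``__contains__``.
    """

    def __init__(self, words: Iterable[str] = ()):
        self._trie: dict = {}
        self._words: Set[str] = set()
        self._max_len = 1
        for w in words:
            self.add_word(w)

    def add_word(self, word: str) -> None:
        if not word:
            raise ValueError("empty word")
        if word in self._words:
            return
        self._words.add(word)
        node = self._trie
        for ch in word:
            node = node.setdefault(ch, {})
        node[""] = True
        self._max_len = max(self._max_len, len(word))

    def __contains__(self, word: str) -> bool:
        return word in self._words

    def __len__(self) -> int:
        return len(self._words)

    def segment(self, text: str) -> List[str]:
        out: List[str] = []
        i = 0
        n = len(text)
        while i < n:
            node = self._trie
            best = i + 1  # single-character fallback
            for j in range(i, min(n, i + self._max_len)):
                node = node.get(text[j])
                if node is None:
                    break
                if "" in node:
                    best = j + 1
            out.append(text[i:best])
            i = best
        return out


def detect_new_words(
    corpus: Sequence[str],
    thresholds: DetectionThresholds = DetectionThresholds(),
    base_dict: Optional[SegmenterDict] = None,
    n_values: Sequence[int] = (2, 3, 4),
    punctuation: Optional[Set[str]] = None,
) -> Dict[str, NgramStats]:
    """Run the WF → MI → CE filter cascade over all candidate N-grams.

    Returns the surviving candidates with their statistics attached for
    audit.  Candidates already present in *base_dict* are excluded (they are
    not *new*).  The cascade is monotone: raising any threshold can only
    shrink the result.
    """
    if not corpus:
        raise ValueError("corpus is empty")
    counts = extract_ngram_counts(corpus, n_values, punctuation)
    survivors: List[str] = []
    for n in sorted(set(n_values)):
        for w, wf in counts.counts[n].items():
            if wf < thresholds.wf_min:
                continue
            if base_dict is not None and w in base_dict:
                continue
            survivors.append(w)
    neighbors = NeighborIndex(corpus, sorted(set(n_values)), punctuation)
    out: Dict[str, NgramStats] = {}
    for w in survivors:
        mi = mutual_information(w, counts)
        if mi < thresholds.mi_min:
            continue
        el, er = neighbors.entropies(w)
        if min(el, er) < thresholds.ce_min:
            continue
        out[w] = NgramStats(w, counts.counts[len(w)][w], mi, el, er)
    return out


def build_lexicon(
    corpus_b: Iterable[str],
    segmenter: SegmenterDict,
    new_words: Iterable[str] = (),
) -> Lexicon:
    """Segment *corpus_b* and count multi-character segments into a lexicon.

    *new_words* are added to the segmenter first (idempotent).  ``z(w)`` is
    the number of times *w* was produced as a segment; single characters are
    not lexicon entries.
    """
    for w in new_words:
        segmenter.add_word(w)
    freqs: Counter = Counter()
    for sentence in corpus_b:
        for seg in segmenter.segment(sentence):
            if len(seg) >= 2:
                freqs[seg] += 1
    lex = Lexicon()
    for word, freq in freqs.items():
        lex.add(word, freq)
    return lex
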