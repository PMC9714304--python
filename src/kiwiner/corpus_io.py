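"""Corpus, lexicon and embedding I/O plus BMES-O tag/span conversion.

Sentences are plain Python strings of Unicode characters.  Supervised data
uses the BMES-O character tagging scheme: each character of a multi-character
entity is tagged ``B-<cat>`` (begin), ``M-<cat>`` (middle) or ``E-<cat>``
(end); a single-character entity is ``S-<cat>``; everything else is ``O``.

On-disk formats are deliberately simple and line-oriented:

* tagged corpus — CoNLL-style two-column UTF-8 text, one ``char<TAB>tag``
  per line, blank line between sentences;
* lexicon — TSV ``word<TAB>frequency``;
* embeddings — word2vec text format (optional ``count dim`` header).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

#: Reserved embedding tokens: unknown word, empty-word-set placeholder, padding.
UNK = "<UNK>"
NONE_TOKEN = "<NONE>"
PAD = "<PAD>"

_POSITIONS = ("B", "M", "E", "S")


class CorpusFormatError(ValueError):
    """Raised when an on-disk corpus/lexicon/embedding file is malformed."""


class EntitySpan(NamedTuple):
    """Half-open character span ``[start, end)`` with an entity category."""

    start: int
    end: int
    category: str


@dataclass
class TaggedSentence:
    """A sentence with one BMES-O tag per character."""

    text: str
    tags: List[str]

    def __post_init__(self) -> None:
        if len(self.tags) != len(self.text):
            raise ValueError(
                f"tag/char length mismatch: {len(self.tags)} tags for "
                f"{len(self.text)} characters"
            )
        for t in self.tags:
            if t != "O":
                pos, _, cat = t.partition("-")
                if pos not in _POSITIONS or not cat:
                    raise ValueError(f"malformed tag {t!r}")

    def __len__(self) -> int:
        return len(self.text)

    @property
    def spans(self) -> List[EntitySpan]:
        return tags_to_spans(self.tags)

    @property
    def categories(self) -> List[str]:
        return sorted({s.category for s in self.spans})


# ---------------------------------------------------------------------------
# tag <-> span conversion
# ---------------------------------------------------------------------------

def tags_to_spans(tags: Sequence[str]) -> List[EntitySpan]:
    """Decode a BMES-O tag sequence into entity spans.

    Only maximal well-formed runs produce spans: ``S-X`` yields a length-1
    span and ``B-X (M-X)* E-X`` a multi-character span.  Ill-formed portions
    (an ``M`` without a ``B``, a category switch mid-entity, an unterminated
    ``B`` run) yield nothing — conservative repair, chosen so that decoding
    never invents entities the tagger did not fully commit to.
    """
    spans: List[EntitySpan] = []
    n = len(tags)
    i = 0
    while i < n:
        tag = tags[i]
        pos, _, cat = tag.partition("-")
        if pos == "S" and cat:
            spans.append(EntitySpan(i, i + 1, cat))
            i += 1
        elif pos == "B" and cat:
            j = i + 1
            while j < n and tags[j] == f"M-{cat}":
                j += 1
            if j < n and tags[j] == f"E-{cat}":
                spans.append(EntitySpan(i, j + 1, cat))
                i = j + 1
            else:
                i += 1  # unterminated run: drop, rescan from next char
        else:
            i += 1
    return spans


def spans_to_tags(spans: Iterable[EntitySpan], n: int) -> List[str]:
    """Render non-overlapping entity spans as a BMES-O tag sequence of length *n*."""
    tags = ["O"] * n
    for span in sorted(spans, key=lambda s: s.start):
        start, end, cat = span
        if not (0 <= start < end <= n):
            raise ValueError(f"span {span} out of range for length {n}")
        if any(tags[k] != "O" for k in range(start, end)):
            raise ValueError(f"span {span} overlaps a previous span")
        if end - start == 1:
            tags[start] = f"S-{cat}"
        else:
            tags[start] = f"B-{cat}"
            for k in range(start + 1, end - 1):
                tags[k] = f"M-{cat}"
            tags[end - 1] = f"E-{cat}"
    return tags


# ---------------------------------------------------------------------------
# tagged corpus I/O
# ---------------------------------------------------------------------------

def read_tagged_corpus(path, encoding: str = "utf-8") -> List[TaggedSentence]:
    """Read a CoNLL-style two-column ``char<TAB>tag`` file.

    Blank lines separate sentences.  Raises :class:`CorpusFormatError` naming
    the offending line on a wrong column count or an unknown position code.
    """
    sentences: List[TaggedSentence] = []
    chars: List[str] = []
    tags: List[str] = []

    def flush() -> None:
        if chars:
            sentences.append(TaggedSentence("".join(chars), list(tags)))
            chars.clear()
            tags.clear()

    with open(path, encoding=encoding) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                flush()
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(cols)}"
                )
            char, tag = cols
            if len(char) != 1:
                raise CorpusFormatError(
                    f"{path}:{lineno}: first column must be a single character, got {char!r}"
                )
            if tag != "O":
                pos, _, cat = tag.partition("-")
                if pos not in _POSITIONS or not cat:
                    raise CorpusFormatError(
                        f"{path}:{lineno}: unknown tag {tag!r} "
                        f"(positions must be one of B/M/E/S)"
                    )
            chars.append(char)
            tags.append(tag)
    flush()
    return sentences


def write_tagged_corpus(sentences: Iterable[TaggedSentence], path, encoding: str = "utf-8") -> None:
    with open(path, "w", encoding=encoding) as fh:
        for sent in sentences:
            for char, tag in zip(sent.text, sent.tags):
                fh.write(f"{char}\t{tag}\n")
            fh.write("\n")


def corpus_categories(sentences: Iterable[TaggedSentence]) -> List[str]:
    """Sorted set of entity categories appearing in a corpus."""
    cats = set()
    for sent in sentences:
        for tag in sent.tags:
            if tag != "O":
                cats.add(tag.partition("-")[2])
    return sorted(cats)


# ---------------------------------------------------------------------------
# lexicon
# ---------------------------------------------------------------------------

class Lexicon:
    """Word → frequency map ``z(w)`` with a trie for prefix matching.

    The trie allows all lexicon words starting at a given sentence position to
    be enumerated in O(longest-word) time, which is what the B/M/E/S word-set
    matcher needs.
    """

    def __init__(self, entries: Optional[Dict[str, int]] = None):
        self._entries: Dict[str, int] = {}
        self._trie: dict = {}
        self._max_len = 0
        if entries:
            for word, freq in entries.items():
                self.add(word, freq)

    def add(self, word: str, freq: int = 1) -> None:
        if not word:
            raise ValueError("empty word")
        if not isinstance(freq, (int, np.integer)) or freq < 1:
            raise ValueError(f"frequency for {word!r} must be a positive integer, got {freq!r}")
        if word in self._entries:
            self._entries[word] += int(freq)
            return
        self._entries[word] = int(freq)
        node = self._trie
        for ch in word:
            node = node.setdefault(ch, {})
        node[""] = word  # leaf marker
        self._max_len = max(self._max_len, len(word))

    def __contains__(self, word: str) -> bool:
        return word in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def freq(self, word: str) -> int:
        return self._entries[word]

    def items(self):
        return self._entries.items()

    @property
    def max_word_len(self) -> int:
        return self._max_len

    def words_starting_at(self, text: str, start: int) -> Iterator[Tuple[str, int]]:
        """Yield ``(word, end)`` for every lexicon word ``text[start:end]``."""
        node = self._trie
        for end in range(start, min(len(text), start + self._max_len)):
            node = node.get(text[end])
            if node is None:
                return
            if "" in node:
                yield node[""], end + 1

    def __eq__(self, other) -> bool:
        return isinstance(other, Lexicon) and self._entries == other._entries


def read_lexicon(path, encoding: str = "utf-8") -> Lexicon:
    """Read a ``word<TAB>frequency`` TSV.  Duplicate words merge by summing."""
    lex = Lexicon()
    seen = set()
    with open(path, encoding=encoding) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 'word<TAB>freq', got {line!r}"
                )
            word, freq_s = cols
            try:
                freq = int(freq_s)
            except ValueError:
                raise CorpusFormatError(
                    f"{path}:{lineno}: frequency must be an integer, got {freq_s!r}"
                ) from None
            if freq < 1:
                raise CorpusFormatError(
                    f"{path}:{lineno}: frequency must be positive, got {freq}"
                )
            if word in seen:
                warnings.warn(
                    f"{path}:{lineno}: duplicate lexicon word {word!r}; frequencies summed",
                    stacklevel=2,
                )
            seen.add(word)
            lex.add(word, freq)
    return lex


def write_lexicon(lexicon: Lexicon, path, encoding: str = "utf-8") -> None:
    with open(path, "w", encoding=encoding) as fh:
        for word in sorted(lexicon):
            fh.write(f"{word}\t{lexicon.freq(word)}\n")


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingTable:
    """Token → dense vector lookup with reserved UNK/NONE/PAD tokens."""

    dim: int
    vectors: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for token, vec in self.vectors.items():
            if vec.shape != (self.dim,):
                raise ValueError(f"vector for {token!r} has shape {vec.shape}, want ({self.dim},)")

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors[token]

    def get(self, token: str) -> np.ndarray:
        """Vector for *token*, falling back to UNK."""
        return self.vectors.get(token, self.vectors[UNK])

    def ensure_reserved(self, rng: Optional[np.random.Generator] = None) -> "EmbeddingTable":
        """Add UNK/NONE/PAD if absent (NONE and PAD zero, UNK small random)."""
        rng = rng if rng is not None else np.random.default_rng(0)
        if UNK not in self.vectors:
            self.vectors[UNK] = rng.uniform(-0.1, 0.1, self.dim)
        if NONE_TOKEN not in self.vectors:
            self.vectors[NONE_TOKEN] = np.zeros(self.dim)
        if PAD not in self.vectors:
            self.vectors[PAD] = np.zeros(self.dim)
        return self


def random_embeddings(tokens: Iterable[str], dim: int, seed: int = 0) -> EmbeddingTable:
    """Seeded uniform(-0.1, 0.1) embeddings for *tokens* plus reserved tokens."""
    rng = np.random.default_rng(seed)
    table = EmbeddingTable(dim, {t: rng.uniform(-0.1, 0.1, dim) for t in tokens})
    return table.ensure_reserved(rng)


def read_embeddings(path, dim: Optional[int] = None, encoding: str = "utf-8",
                    seed: int = 0) -> EmbeddingTable:
    """Read word2vec-style text embeddings.

    An optional first line ``count dim`` is tolerated and ignored beyond a
    consistency check; every other line is ``token v1 ... v_dim``.  Reserved
    tokens are added with seeded random (UNK) / zero (NONE, PAD) vectors when
    the file does not provide them.
    """
    vectors: Dict[str, np.ndarray] = {}
    with open(path, encoding=encoding) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    start = 0
    if lines:
        head = lines[0].split()
        if len(head) == 2 and all(p.isdigit() for p in head):
            if dim is None:
                dim = int(head[1])
            elif int(head[1]) != dim:
                raise CorpusFormatError(
                    f"{path}: header declares dim {head[1]}, caller requested {dim}"
                )
            start = 1
    for line in lines[start:]:
        parts = line.split()
        token, values = parts[0], parts[1:]
        if dim is None:
            dim = len(values)
        if len(values) != dim:
            raise CorpusFormatError(
                f"{path}: token {token!r} has {len(values)} values, expected {dim}"
            )
        vectors[token] = np.array([float(v) for v in values])
    if dim is None:
        raise CorpusFormatError(f"{path}: empty embedding file and no dim given")
    table = EmbeddingTable(dim, vectors)
    return table.ensure_reserved(np.random.default_rng(seed))


def write_sentences(sentences: Iterable[str], path, encoding: str = "utf-8") -> None:
    """Write a raw corpus, one sentence per line."""
    with open(path, "w", encoding=encoding) as fh:
        for s in sentences:
            fh.write(s + "\n")


def read_sentences(path, encoding: str = "utf-8") -> List[str]:
    """Read a raw corpus, one sentence per line; blank lines are skipped."""
    with open(path, encoding=encoding) as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip()]
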