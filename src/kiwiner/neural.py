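"""Criss-cross attention, attention-gated Softlexicon, PCAT, and the
BiLSTM-CRF tagger.

The tagger stacks, per Fig.-style architecture common to lexicon-enhanced
Chinese NER models:

1. character embeddings fused with the four B/M/E/S Softlexicon set vectors,
   where a criss-cross-attention block followed by a sigmoid gate learns one
   importance weight per set (the attention-weighted Softlexicon);
2. a single-layer BiLSTM encoder;
3. PCAT — two parallel conv / criss-cross-attention / conv branches (entry
   filters 1x1 and 1x3) summed, which re-weights encoder features by
   long-range correlation;
4. a linear emission layer and a linear-chain CRF trained by negative
   log-likelihood and decoded by Viterbi with BMES-impossible transitions
   masked to -inf, so decoded tag sequences are always well-formed.

Criss-cross attention treats its input as a ``C x W x H`` feature map and
lets each position attend to the ``H + W - 1`` positions in its own row and
column, with a residual add.  Sentences use ``H = 1``, where the criss-cross
neighbourhood is the whole sequence and the block degenerates to dense
softmax attention along the sentence — that degeneracy is the module's
sequence semantics and is what the oracle tests check.

Everything runs on the numpy autograd in :mod:`kiwiner.autograd`; training is
plain SGD with the learning-rate schedule ``lr_e = lr0 / (1 + decay * e)``
and global-norm gradient clipping.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor
from .corpus_io import (
    NONE_TOKEN,
    PAD,
    UNK,
    EmbeddingTable,
    Lexicon,
    TaggedSentence,
)
from .lexmatch import WordSets, sentence_word_sets, weighted_set_vector

logger = logging.getLogger(__name__)

_POSITIONS = ("B", "M", "E", "S")


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture sizes.  Defaults follow the reference hyper-parameters
    (50-dim character and word embeddings, 300 LSTM hidden units per
    direction, dropout 0.5)."""

    d_char: int = 50
    d_word: int = 50
    lstm_hidden: int = 300
    dropout: float = 0.5
    use_attsoft: bool = True   # learned per-set gates vs static Softlexicon
    use_pcat: bool = True

    def __post_init__(self) -> None:
        if min(self.d_char, self.d_word, self.lstm_hidden) < 1:
            raise ValueError("all dimensions must be positive")


@dataclass
class TrainConfig:
    """Optimisation settings (SGD defaults: batch 16, lr 0.0015, decay 0.05)."""

    batch_size: int = 16
    lr: float = 0.0015
    lr_decay: float = 0.05
    epochs: int = 30
    seed: int = 0
    grad_clip: float = 5.0

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.batch_size < 1:
            raise ValueError("lr must be positive and batch_size >= 1")


# ---------------------------------------------------------------------------
# criss-cross attention
# ---------------------------------------------------------------------------

class CCNetParams:
    """Query/key projections C -> C' (C' < C) and value projection C -> C.

    The three projections are the 1x1 convolutions of the criss-cross block;
    they are bias-free, so a zero value projection makes the block an exact
    identity (residual guarantee).
    """

    def __init__(self, channels: int, reduced: Optional[int] = None,
                 rng: Optional[np.random.Generator] = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        reduced = reduced if reduced is not None else max(1, channels // 8)
        if reduced >= channels and channels > 1:
            raise ValueError("reduced dimension C' must be < C")
        s = 1.0 / np.sqrt(channels)
        self.wq = Parameter(rng.uniform(-s, s, (channels, reduced)))
        self.wk = Parameter(rng.uniform(-s, s, (channels, reduced)))
        self.wv = Parameter(rng.uniform(-s, s, (channels, channels)))
        self.channels = channels
        self.reduced = reduced

    def parameters(self) -> List[Parameter]:
        return [self.wq, self.wk, self.wv]


def _ccnet_dense(F: Tensor, params: CCNetParams) -> Tensor:
    """Dense attention along the first axis of ``F`` ([W, C]) + residual.

    This is criss-cross attention for an H = 1 feature map, vectorised.
    """
    Q = F @ params.wq
    K = F @ params.wk
    V = F @ params.wv
    A = ag.softmax(Q @ K.T, axis=1)
    return A @ V + F


def criss_cross_attention(m: Tensor, params: CCNetParams) -> Tensor:
    """Criss-cross attention over a ``[C, W, H]`` feature map with residual.

    Each position u attends to the H + W - 1 positions sharing its row or
    column (u itself counted once): affinities are ``Q_u . K_i``, softmaxed,
    and used to aggregate the value vectors, which are then added to the
    input.  Output shape equals input shape.
    """
    if not isinstance(m, Tensor):
        m = Tensor(m)
    if m.ndim != 3:
        raise ValueError(f"expected a [C, W, H] feature map, got shape {m.shape}")
    C, W, H = m.shape
    if C != params.channels:
        raise ValueError(f"feature map has {C} channels, params expect {params.channels}")
    F = m.reshape(C, W * H).T  # position-major [W*H, C]; position (w,h) at w*H+h
    if H == 1:
        out = _ccnet_dense(F, params)
        return out.T.reshape(C, W, H)
    Q = F @ params.wq
    K = F @ params.wk
    V = F @ params.wv
    out_rows: List[Tensor] = []
    for w in range(W):
        for h in range(H):
            u = w * H + h
            idx = [wp * H + h for wp in range(W)]
            idx += [w * H + hp for hp in range(H) if hp != h]
            q_u = Q[u : u + 1]                      # [1, C']
            k_sel = ag.rows(K, idx)                  # [H+W-1, C']
            v_sel = ag.rows(V, idx)                  # [H+W-1, C]
            a = ag.softmax(q_u @ k_sel.T, axis=1)    # [1, H+W-1]
            out_rows.append(a @ v_sel + F[u : u + 1])
    out = ag.concat(out_rows, axis=0)
    return out.T.reshape(C, W, H)


# ---------------------------------------------------------------------------
# attention-gated Softlexicon
# ---------------------------------------------------------------------------

class AttSoftParams:
    """CCNet over the 4-set map plus the affine map q: 4*d_w -> 4 logits."""

    def __init__(self, d_word: int, rng: Optional[np.random.Generator] = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.ccnet = CCNetParams(d_word, rng=rng)
        s = 1.0 / np.sqrt(4 * d_word)
        self.q_w = Parameter(rng.uniform(-s, s, (4 * d_word, 4)))
        self.q_b = Parameter(np.zeros(4))
        self.d_word = d_word

    def parameters(self) -> List[Parameter]:
        return self.ccnet.parameters() + [self.q_w, self.q_b]


def attsoft_weights(v_sets: Tensor, params: AttSoftParams) -> Tensor:
    """Learned per-set gates a in (0, 1)^4 from the stacked set vectors.

    *v_sets* is the ``[d_w, 4, 1]`` feature map whose four width positions
    hold the pooled B/M/E/S vectors.  The map passes through criss-cross
    attention, is flattened, mapped to 4 logits by q, and squashed by a
    sigmoid — so the four weights are independent gates, not a distribution.
    """
    if not isinstance(v_sets, Tensor):
        v_sets = Tensor(v_sets)
    if v_sets.shape != (params.d_word, 4, 1):
        raise ValueError(f"expected shape ({params.d_word}, 4, 1), got {v_sets.shape}")
    cc = criss_cross_attention(v_sets, params.ccnet)
    flat = cc.reshape(1, 4 * params.d_word)
    return ((flat @ params.q_w) + params.q_b).sigmoid().reshape(4)


def attsoft_feature(
    x_c: np.ndarray,
    word_sets: WordSets,
    embeddings: EmbeddingTable,
    params: AttSoftParams,
    gates: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Fused character feature with attention-gated set vectors.

    ``concat(x_c, a1 v_B, a2 v_M, a3 v_E, a4 v_S)``; with *gates* forced to
    all ones this reproduces the static Softlexicon feature exactly.
    """
    z = word_sets.z_total
    vs = [weighted_set_vector(ws, z, embeddings) for ws in word_sets.as_tuple()]
    if gates is None:
        m = np.stack(vs, axis=1).reshape(embeddings.dim, 4, 1)
        gates = attsoft_weights(Tensor(m), params).data.ravel()
    return np.concatenate([np.asarray(x_c, dtype=float)] + [gates[k] * vs[k] for k in range(4)])


# ---------------------------------------------------------------------------
# PCAT
# ---------------------------------------------------------------------------

class _Conv1x1:
    def __init__(self, channels: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(channels)
        self.w = Parameter(rng.uniform(-s, s, (channels, channels)))
        self.b = Parameter(np.zeros(channels))

    def __call__(self, X: Tensor) -> Tensor:  # X: [W, C]
        return X @ self.w + self.b

    def parameters(self) -> List[Parameter]:
        return [self.w, self.b]


class _Conv1x3:
    """Width-3 convolution along the sequence, symmetric zero padding."""

    def __init__(self, channels: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(3 * channels)
        self.wl = Parameter(rng.uniform(-s, s, (channels, channels)))
        self.wc = Parameter(rng.uniform(-s, s, (channels, channels)))
        self.wr = Parameter(rng.uniform(-s, s, (channels, channels)))
        self.b = Parameter(np.zeros(channels))

    def __call__(self, X: Tensor) -> Tensor:  # X: [W, C]
        W = X.shape[0]
        zero = Tensor(np.zeros((1, X.shape[1])))
        Xp = ag.concat([zero, X, zero], axis=0)
        return (
            Xp[0:W] @ self.wl + Xp[1 : W + 1] @ self.wc + Xp[2 : W + 2] @ self.wr + self.b
        )

    def parameters(self) -> List[Parameter]:
        return [self.wl, self.wc, self.wr, self.b]


class PcatParams:
    """Two parallel branches: conv1x1/CCNet/conv1x3 and conv1x3/CCNet/conv1x3.

    CCNet weights are NOT shared between branches; convolutions carry a bias
    and no nonlinearity, with symmetric zero padding preserving the width.
    """

    def __init__(self, channels: int, rng: Optional[np.random.Generator] = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.conv1_in = _Conv1x1(channels, rng)
        self.cc1 = CCNetParams(channels, rng=rng)
        self.conv1_out = _Conv1x3(channels, rng)
        self.conv2_in = _Conv1x3(channels, rng)
        self.cc2 = CCNetParams(channels, rng=rng)
        self.conv2_out = _Conv1x3(channels, rng)
        self.channels = channels

    def parameters(self) -> List[Parameter]:
        ps: List[Parameter] = []
        for comp in (self.conv1_in, self.cc1, self.conv1_out,
                     self.conv2_in, self.cc2, self.conv2_out):
            ps.extend(comp.parameters())
        return ps


def pcat_forward(x: Tensor, params: PcatParams) -> Tensor:
    """PCAT over a ``[C, W]`` sequence feature map; output shape equals input.

    The map is unsqueezed to ``[C, W, 1]`` conceptually; since criss-cross
    attention at H = 1 is dense attention along W, both branches run directly
    on the ``[W, C]`` view.
    """
    if not isinstance(x, Tensor):
        x = Tensor(x)
    if x.ndim != 2:
        raise ValueError(f"expected a [C, W] map, got shape {x.shape}")
    if x.shape[1] < 1:
        raise ValueError("width must be >= 1")
    X = x.T  # [W, C]
    b1 = params.conv1_out(_ccnet_dense(params.conv1_in(X), params.cc1))
    b2 = params.conv2_out(_ccnet_dense(params.conv2_in(X), params.cc2))
    return (b1 + b2).T


# ---------------------------------------------------------------------------
# BiLSTM
# ---------------------------------------------------------------------------

class _LstmDirection:
    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(hidden)
        self.wx = Parameter(rng.uniform(-s, s, (d_in, 4 * hidden)))
        self.wh = Parameter(rng.uniform(-s, s, (hidden, 4 * hidden)))
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.b = Parameter(b)
        self.hidden = hidden

    def parameters(self) -> List[Parameter]:
        return [self.wx, self.wh, self.b]

    def run(self, X: Tensor, reverse: bool = False) -> List[Tensor]:
        W = X.shape[0]
        Hn = self.hidden
        h = Tensor(np.zeros((1, Hn)))
        c = Tensor(np.zeros((1, Hn)))
        order = range(W - 1, -1, -1) if reverse else range(W)
        outs: List[Optional[Tensor]] = [None] * W
        for t in order:
            g = X[t : t + 1] @ self.wx + h @ self.wh + self.b
            i = g[:, 0:Hn].sigmoid()
            f = g[:, Hn : 2 * Hn].sigmoid()
            gt = g[:, 2 * Hn : 3 * Hn].tanh()
            o = g[:, 3 * Hn : 4 * Hn].sigmoid()
            c = f * c + i * gt
            h = o * c.tanh()
            outs[t] = h
        return outs  # type: ignore[return-value]


class BiLstmParams:
    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.fwd = _LstmDirection(d_in, hidden, rng)
        self.bwd = _LstmDirection(d_in, hidden, rng)
        self.hidden = hidden

    def parameters(self) -> List[Parameter]:
        return self.fwd.parameters() + self.bwd.parameters()

    def __call__(self, X: Tensor) -> Tensor:  # [W, d_in] -> [W, 2*hidden]
        hf = self.fwd.run(X, reverse=False)
        hb = self.bwd.run(X, reverse=True)
        return ag.concat([ag.concat([f, b], axis=1) for f, b in zip(hf, hb)], axis=0)


# ---------------------------------------------------------------------------
# linear-chain CRF
# ---------------------------------------------------------------------------

class CrfParams:
    """Transition scores over tagset + START/STOP (square matrix of size T+2)."""

    def __init__(self, n_tags: int, rng: Optional[np.random.Generator] = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.n_tags = n_tags
        self.start = n_tags
        self.stop = n_tags + 1
        self.trans = Parameter(rng.uniform(-0.1, 0.1, (n_tags + 2, n_tags + 2)))

    def parameters(self) -> List[Parameter]:
        return [self.trans]


def crf_log_partition(emissions: Tensor, crf: CrfParams) -> Tensor:
    """log sum over all tag paths of exp(path score), including START/STOP
    transitions, by the forward algorithm in log space."""
    if not isinstance(emissions, Tensor):
        emissions = Tensor(emissions)
    W, T = emissions.shape
    if W < 1:
        raise ValueError("need at least one position")
    trans = crf.trans
    alpha = trans[crf.start : crf.start + 1, 0:T] + emissions[0:1]  # [1, T]
    for t in range(1, W):
        scores = alpha.T + trans[0:T, 0:T] + emissions[t : t + 1]   # [T, T]
        alpha = ag.logsumexp(scores, axis=0).reshape(1, T)
    final = alpha + trans[0:T, crf.stop : crf.stop + 1].T
    return ag.logsumexp(final, axis=1).reshape(())


def crf_path_score(emissions: Tensor, tag_ids: Sequence[int], crf: CrfParams) -> Tensor:
    """Score of one tag path: emissions plus transitions incl. START/STOP."""
    if not isinstance(emissions, Tensor):
        emissions = Tensor(emissions)
    trans = crf.trans
    score = trans[crf.start, tag_ids[0]] + emissions[0, tag_ids[0]]
    for t in range(1, len(tag_ids)):
        score = score + trans[tag_ids[t - 1], tag_ids[t]] + emissions[t, tag_ids[t]]
    return score + trans[tag_ids[-1], crf.stop]


def crf_nll(emissions: Tensor, tag_ids: Sequence[int], crf: CrfParams) -> Tensor:
    """Negative log-likelihood of the gold path."""
    return crf_log_partition(emissions, crf) - crf_path_score(emissions, tag_ids, crf)


def viterbi_decode(
    emissions: np.ndarray, crf: CrfParams, mask: Optional[np.ndarray] = None
) -> List[int]:
    """Best tag path by Viterbi; ties break toward the lowest tag index.

    *mask* is an optional boolean ``[T+2, T+2]`` allowed-transition matrix;
    disallowed transitions score -inf, which guarantees well-formed BMES-O
    output when the mask encodes the scheme's constraints.
    """
    emissions = np.asarray(emissions, dtype=float)
    W, T = emissions.shape
    trans = crf.trans.data.copy()
    if mask is not None:
        trans = np.where(mask, trans, -1e9)
    delta = trans[crf.start, :T] + emissions[0]
    back: List[np.ndarray] = []
    for t in range(1, W):
        scores = delta[:, None] + trans[:T, :T] + emissions[t][None, :]
        back.append(np.argmax(scores, axis=0))  # argmax -> first (lowest) index
        delta = np.max(scores, axis=0)
    delta = delta + trans[:T, crf.stop]
    path = [int(np.argmax(delta))]
    for bp in reversed(back):
        path.append(int(bp[path[-1]]))
    path.reverse()
    return path


def bmes_transition_mask(tags: Sequence[str], n_extra: int = 2) -> np.ndarray:
    """Allowed-transition matrix for a BMES-O tagset (plus START/STOP rows).

    Forbidden: entering M-X/E-X from anything other than B-X/M-X; leaving
    B-X/M-X to anything other than M-X/E-X (including STOP); starting a
    sentence with M/E.
    """
    T = len(tags)
    start, stop = T, T + 1
    allowed = np.zeros((T + 2, T + 2), dtype=bool)

    def opens(tag: str) -> bool:  # tags a position may start an entity/O at
        return tag == "O" or tag[0] in ("B", "S")

    for i, src in enumerate(tags):
        src_pos, _, src_cat = src.partition("-")
        for j, dst in enumerate(tags):
            dst_pos, _, dst_cat = dst.partition("-")
            if src_pos in ("B", "M"):
                ok = dst_pos in ("M", "E") and dst_cat == src_cat
            else:  # O, E, S: entity closed, may open a new one
                ok = opens(dst)
            allowed[i, j] = ok
        allowed[i, stop] = src_pos not in ("B", "M")
    for j, dst in enumerate(tags):
        allowed[start, j] = opens(dst)
    return allowed


# ---------------------------------------------------------------------------
# the tagger
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


class KiwinerTagger:
    """Lexicon-enhanced BiLSTM-CRF character tagger.

    Both embedding tables are trainable; when pretrained tables are given
    their vectors initialise the matrices, otherwise seeded uniform
    (-0.1, 0.1) initialisation is used.
    """

    def __init__(
        self,
        categories: Sequence[str],
        chars: Iterable[str],
        lexicon: Lexicon,
        cfg: ModelConfig = ModelConfig(),
        char_embeddings: Optional[EmbeddingTable] = None,
        word_embeddings: Optional[EmbeddingTable] = None,
        seed: int = 0,
    ):
        self.cfg = cfg
        self.categories = sorted(categories)
        self.tags = ["O"] + [f"{p}-{c}" for c in self.categories for p in _POSITIONS]
        self.tag_index = {t: i for i, t in enumerate(self.tags)}
        self.lexicon = lexicon
        rng = np.random.default_rng(seed)

        self.char_vocab: Dict[str, int] = {PAD: 0, UNK: 1}
        for ch in sorted(set(chars)):
            self.char_vocab.setdefault(ch, len(self.char_vocab))
        self.word_vocab: Dict[str, int] = {PAD: 0, UNK: 1, NONE_TOKEN: 2}
        for w in sorted(lexicon):
            self.word_vocab.setdefault(w, len(self.word_vocab))

        def init_table(vocab: Dict[str, int], dim: int,
                       table: Optional[EmbeddingTable]) -> Parameter:
            mat = rng.uniform(-0.1, 0.1, (len(vocab), dim))
            if table is not None:
                if table.dim != dim:
                    raise ValueError(f"embedding dim {table.dim} != configured {dim}")
                for tok, i in vocab.items():
                    if tok in table:
                        mat[i] = table[tok]
            return Parameter(mat)

        self.e_char = init_table(self.char_vocab, cfg.d_char, char_embeddings)
        self.e_word = init_table(self.word_vocab, cfg.d_word, word_embeddings)
        if NONE_TOKEN in self.word_vocab and word_embeddings is None:
            self.e_word.data[self.word_vocab[NONE_TOKEN]] = 0.0

        self.attsoft = AttSoftParams(cfg.d_word, rng) if cfg.use_attsoft else None
        d_in = cfg.d_char + 4 * cfg.d_word
        self.bilstm = BiLstmParams(d_in, cfg.lstm_hidden, rng)
        enc = 2 * cfg.lstm_hidden
        self.pcat = PcatParams(enc, rng) if cfg.use_pcat else None
        s = 1.0 / np.sqrt(enc)
        self.em_w = Parameter(rng.uniform(-s, s, (enc, len(self.tags))))
        self.em_b = Parameter(np.zeros(len(self.tags)))
        self.crf = CrfParams(len(self.tags), rng)
        self.transition_mask = bmes_transition_mask(self.tags)

    # -- parameters --------------------------------------------------------

    def named_parameters(self) -> Dict[str, Parameter]:
        out: Dict[str, Parameter] = {"e_char": self.e_char, "e_word": self.e_word,
                                     "em_w": self.em_w, "em_b": self.em_b,
                                     "crf.trans": self.crf.trans}
        for i, p in enumerate(self.bilstm.parameters()):
            out[f"bilstm.{i}"] = p
        if self.attsoft is not None:
            for i, p in enumerate(self.attsoft.parameters()):
                out[f"attsoft.{i}"] = p
        if self.pcat is not None:
            for i, p in enumerate(self.pcat.parameters()):
                out[f"pcat.{i}"] = p
        return out

    def parameters(self) -> List[Parameter]:
        return list(self.named_parameters().values())

    # -- feature construction ----------------------------------------------

    def _set_arrays(self, word_sets: WordSets) -> List[Tuple[np.ndarray, np.ndarray]]:
        """Per set: (word ids, weights 4*z/Z) ready for embedding pooling."""
        z_total = word_sets.z_total
        out = []
        for ws in word_sets.as_tuple():
            idx = np.array(
                [self.word_vocab.get(w, self.word_vocab[UNK]) for w, _ in ws],
                dtype=np.intp,
            )
            wts = np.array([4.0 * z / z_total for _, z in ws])
            out.append((idx, wts))
        return out

    def _fused_features(self, sentence: str, train: bool,
                        rng: Optional[np.random.Generator]) -> Tensor:
        char_ids = [self.char_vocab.get(ch, self.char_vocab[UNK]) for ch in sentence]
        xc = ag.rows(self.e_char, char_ids)  # [W, d_c]
        all_sets = sentence_word_sets(sentence, self.lexicon)
        fused_rows: List[Tensor] = []
        for i, word_sets in enumerate(all_sets):
            vs: List[Tensor] = []
            for idx, wts in self._set_arrays(word_sets):
                vs.append(Tensor(wts[None, :]) @ ag.rows(self.e_word, idx))  # [1, d_w]
            if self.attsoft is not None:
                m = ag.concat([v.T for v in vs], axis=1).reshape(self.cfg.d_word, 4, 1)
                a = attsoft_weights(m, self.attsoft)
                vs = [a[k : k + 1].reshape(1, 1) * v for k, v in enumerate(vs)]
            fused_rows.append(ag.concat([xc[i : i + 1]] + vs, axis=1))
        X = ag.concat(fused_rows, axis=0)
        if train and self.cfg.dropout > 0:
            assert rng is not None
            keep = 1.0 - self.cfg.dropout
            mask = (rng.random(X.shape) < keep) / keep
            X = X * Tensor(mask)
        return X

    def emissions(self, sentence: str, train: bool = False,
                  rng: Optional[np.random.Generator] = None) -> Tensor:
        X = self._fused_features(sentence, train, rng)
        H = self.bilstm(X)  # [W, 2*hidden]
        if self.pcat is not None:
            H = pcat_forward(H.T, self.pcat).T
        return H @ self.em_w + self.em_b

    def sentence_nll(self, sent: TaggedSentence, train: bool = False,
                     rng: Optional[np.random.Generator] = None) -> Tensor:
        tag_ids = [self.tag_index[t] for t in sent.tags]
        return crf_nll(self.emissions(sent.text, train, rng), tag_ids, self.crf)

    def decode(self, sentence: str) -> List[str]:
        em = self.emissions(sentence).data
        path = viterbi_decode(em, self.crf, self.transition_mask)
        return [self.tags[i] for i in path]

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: npz of parameters + JSON-encoded metadata."""
        meta = {
            "version": CHECKPOINT_VERSION,
            "cfg": asdict(self.cfg),
            "categories": self.categories,
            "char_vocab": self.char_vocab,
            "word_vocab": self.word_vocab,
            "lexicon": dict(self.lexicon.items()),
        }
        arrays = {name: p.data for name, p in self.named_parameters().items()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "KiwinerTagger":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))
            if meta["version"] != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {meta['version']}")
            lexicon = Lexicon({w: int(z) for w, z in meta["lexicon"].items()})
            model = cls(
                meta["categories"],
                [c for c in meta["char_vocab"] if c not in (PAD, UNK)],
                lexicon,
                ModelConfig(**meta["cfg"]),
            )
            if model.char_vocab != meta["char_vocab"] or model.word_vocab != meta["word_vocab"]:
                raise ValueError("checkpoint vocab mismatch")
            for name, p in model.named_parameters().items():
                p.data = data[name].copy()
        return model


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------

def _global_grad_norm(params: List[Parameter]) -> float:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad**2).sum())
    return float(np.sqrt(total))


def train(
    model: KiwinerTagger,
    corpus: Sequence[TaggedSentence],
    cfg: TrainConfig = TrainConfig(),
    dev: Optional[Sequence[TaggedSentence]] = None,
) -> List[dict]:
    """Train by SGD on the CRF negative log-likelihood.

    Epoch *e* (0-based) uses ``lr_e = lr / (1 + lr_decay * e)``; gradients
    are averaged within each batch and clipped to global L2 norm
    ``grad_clip``.  Fully reproducible given ``cfg.seed``.  Returns per-epoch
    history: mean training NLL and, when *dev* is given, entity F1 on it.
    """
    from .evalmetrics import entity_prf  # local import to avoid a cycle

    if not corpus:
        raise ValueError("training corpus is empty")
    rng = np.random.default_rng(cfg.seed)
    params = model.parameters()
    history: List[dict] = []
    n = len(corpus)
    for epoch in range(cfg.epochs):
        lr = cfg.lr / (1.0 + cfg.lr_decay * epoch)
        order = rng.permutation(n)
        total_loss = 0.0
        for lo in range(0, n, cfg.batch_size):
            batch = [corpus[i] for i in order[lo : lo + cfg.batch_size]]
            if not batch:
                warnings.warn("skipping empty batch")
                continue
            for p in params:
                p.zero_grad()
            losses = [model.sentence_nll(s, train=True, rng=rng) for s in batch]
            loss = ag.concat([l.reshape(1) for l in losses], axis=0).sum() / len(batch)
            loss.backward()
            total_loss += loss.item() * len(batch)
            norm = _global_grad_norm(params)
            scale = lr * (cfg.grad_clip / norm if norm > cfg.grad_clip else 1.0)
            for p in params:
                if p.grad is not None:
                    p.data -= scale * p.grad
        record = {"epoch": epoch, "lr": lr, "loss": total_loss / n}
        if dev is not None:
            record["dev_f1"] = entity_prf(list(dev), predict(model, [s.text for s in dev])).f1
        history.append(record)
        logger.info("epoch %d: loss=%.4f lr=%.5f", epoch, record["loss"], lr)
    return history


def predict(model: KiwinerTagger, sentences: Sequence[str]) -> List[TaggedSentence]:
    """Viterbi-decode each sentence into a well-formed BMES-O tagging."""
    return [TaggedSentence(s, model.decode(s)) for s in sentences]
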