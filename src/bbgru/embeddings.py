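"""Token encodings: word / POS lookup tables, tanh-initialized distance
embeddings, and the domain-oriented skip-gram embedding trainer.

Each input token i is represented by the concatenation

    [ word_emb(w_i) ; pos_emb(pos_i) ; d1(e1_pos - i) ; d2(e2_pos - i) ]

where the two distance vectors are looked up by the signed token distance
to the bacterium and location placeholders.  A distance table row for
distance l is initialized with every component equal to tanh(l / s), s
being the largest absolute distance seen in the training corpus; the rows
are trainable afterwards and unseen larger distances are clipped to +-s.

The embedding trainer is skip-gram with negative sampling in which the
context of a focus token includes, for every neighbour inside the window,
five distinct context units: its surface form, stem, chunk tag, entity tag
and POS tag.  Word vectors are read off the surface units and POS vectors
off the POS units.  This is a reconstruction of "training by surrounding
words and their parser-derived biomedical information" as a concrete,
documented objective; it is not a reimplementation of any particular
released trainer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .parse import LinearizedInput, ParseGraph

logger = logging.getLogger(__name__)

OOV = "<oov>"
PAD = "<pad>"


@dataclass
class EmbeddingTable:
    """token -> row lookup with dedicated OOV and padding rows."""

    vocab: dict[str, int]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2 or self.vectors.shape[1] < 1:
            raise ValueError("vectors must be a |V| x k matrix with k >= 1")
        if max(self.vocab.values(), default=-1) >= self.vectors.shape[0]:
            raise ValueError("vocabulary index addresses a missing row")

    @property
    def k(self) -> int:
        return self.vectors.shape[1]

    def index(self, token: str) -> int:
        return self.vocab.get(token, self.vocab[OOV])

    def lookup(self, token: str) -> np.ndarray:
        return self.vectors[self.index(token)]

    @classmethod
    def create(cls, tokens: Iterable[str], k: int, rng: np.random.Generator,
               scale: float = 0.1) -> "EmbeddingTable":
        words = [PAD, OOV] + sorted(set(tokens) - {PAD, OOV})
        vectors = rng.uniform(-scale, scale, size=(len(words), k))
        vectors[0] = 0.0  # padding row stays zero
        return cls(vocab={w: i for i, w in enumerate(words)}, vectors=vectors)

    def save_word2vec(self, path) -> None:
        """word2vec text format: header '|V| k', then token + k floats."""
        order = sorted(self.vocab, key=self.vocab.get)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(order)} {self.k}\n")
            for w in order:
                vec = " ".join(f"{v:.6f}" for v in self.vectors[self.vocab[w]])
                fh.write(f"{w} {vec}\n")

    @classmethod
    def load_word2vec(cls, path) -> "EmbeddingTable":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        n, k = map(int, lines[0].split())
        vocab: dict[str, int] = {}
        vectors = np.zeros((n, k))
        for i, line in enumerate(lines[1 : n + 1]):
            parts = line.rstrip().split(" ")
            vocab[parts[0]] = i
            vectors[i] = [float(x) for x in parts[1 : k + 1]]
        if OOV not in vocab:  # tables from other tools may lack special rows
            vocab[OOV] = len(vocab)
            vectors = np.vstack([vectors, vectors.mean(axis=0, keepdims=True)])
        return cls(vocab=vocab, vectors=vectors)


# ---------------------------------------------------------------------------
# distance features
# ---------------------------------------------------------------------------

def relative_distances(inp: LinearizedInput, i: int, s: int | None = None) -> tuple[int, int]:
    """Signed distances of token i to the two placeholders.

    The convention is entity index minus token index: in the running
    example sequence (contains, entity_1, at, environment, with, entity_2)
    the token "at" has distances (-1, 3).  With *s* given, values are
    clipped to [-s, s].
    """
    l1 = inp.e1_pos - i
    l2 = inp.e2_pos - i
    if s is not None:
        l1 = max(-s, min(s, l1))
        l2 = max(-s, min(s, l2))
    return l1, l2


def init_distance_vector(l: int, s: int, k: int) -> np.ndarray:
    """A k-vector with every component tanh(l/s); the rows stay trainable."""
    if s < 1:
        raise ValueError("distance normalizer s must be >= 1")
    if k < 1:
        raise ValueError("distance embedding width must be >= 1")
    return np.full(k, np.tanh(l / s))


def build_distance_table(s: int, k: int) -> np.ndarray:
    """Rows for distances -s..s (row index l + s)."""
    return np.stack([init_distance_vector(l, s, k) for l in range(-s, s + 1)])


def max_abs_distance(inputs: Iterable[LinearizedInput]) -> int:
    """The normalizer s: largest |relative distance| over a training corpus."""
    s = 1
    for inp in inputs:
        for i in range(len(inp)):
            l1, l2 = relative_distances(inp, i)
            s = max(s, abs(l1), abs(l2))
    return s


def encode_indices(
    inp: LinearizedInput, word_tab: EmbeddingTable, pos_tab: EmbeddingTable, s: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-token row indices into the four lookup tables."""
    n = len(inp)
    wi = np.array([word_tab.index(t) for t in inp.tokens])
    pi = np.array([pos_tab.index(t) for t in inp.pos])
    d1 = np.empty(n, dtype=int)
    d2 = np.empty(n, dtype=int)
    for i in range(n):
        l1, l2 = relative_distances(inp, i, s=s)
        d1[i], d2[i] = l1 + s, l2 + s
    return wi, pi, d1, d2


def encode_sequence(
    inp: LinearizedInput,
    word_tab: EmbeddingTable,
    pos_tab: EmbeddingTable,
    dist1: np.ndarray,
    dist2: np.ndarray,
    s: int,
) -> np.ndarray:
    """n x d_w matrix, row i = [word_emb; pos_emb; d1; d2] for token i."""
    if len(inp) == 0:
        raise ValueError("cannot encode an empty input")
    wi, pi, d1, d2 = encode_indices(inp, word_tab, pos_tab, s)
    return np.hstack([word_tab.vectors[wi], pos_tab.vectors[pi], dist1[d1], dist2[d2]])


# ---------------------------------------------------------------------------
# domain-oriented skip-gram trainer
# ---------------------------------------------------------------------------

@dataclass
class EmbedConfig:
    k: int = 50
    window: int = 5
    lr: float = 0.025
    epochs: int = 3
    negatives: int = 5
    min_count: int = 1
    seed: int = 0


def _context_units(g: ParseGraph, j: int) -> list[str]:
    return [
        g.surface[j],
        f"stem:{g.stem[j]}",
        f"chunk:{g.chunk[j]}",
        f"ent:{g.entity[j]}",
        f"pos:{g.pos[j]}",
    ]


def train_domain_embeddings(
    graphs: Iterable[ParseGraph], config: EmbedConfig | None = None
) -> tuple[EmbeddingTable, EmbeddingTable]:
    """Skip-gram with negative sampling over parser-augmented contexts.

    Focus units are each token's surface and POS tag; context units are
    the surface/stem/chunk/entity/POS of every neighbour within the
    window.  Returns the surface-unit table and the POS-unit table.
    """
    cfg = config or EmbedConfig()
    if cfg.window < 1:
        raise ValueError("window must be >= 1")
    graphs = list(graphs)
    if not graphs:
        raise ValueError("empty training corpus")
    rng = np.random.default_rng(cfg.seed)

    counts: dict[str, int] = {}
    for g in graphs:
        for t in g.surface:
            counts[t] = counts.get(t, 0) + 1
    if not counts:
        raise ValueError("empty vocabulary")

    def surf(t: str) -> str:
        return t if counts[t] >= cfg.min_count else OOV

    focus_vocab: dict[str, int] = {PAD: 0, OOV: 1}
    ctx_vocab: dict[str, int] = {}
    ctx_counts: list[int] = []

    def fid(u: str) -> int:
        if u not in focus_vocab:
            focus_vocab[u] = len(focus_vocab)
        return focus_vocab[u]

    def cid(u: str) -> int:
        if u not in ctx_vocab:
            ctx_vocab[u] = len(ctx_vocab)
            ctx_counts.append(0)
        i = ctx_vocab[u]
        ctx_counts[i] += 1
        return i

    pairs: list[tuple[int, int]] = []
    for g in graphs:
        n = len(g)
        for t in range(n):
            focus = [fid(surf(g.surface[t])), fid(f"pos:{g.pos[t]}")]
            lo, hi = max(0, t - cfg.window), min(n, t + cfg.window + 1)
            for j in range(lo, hi):
                if j == t:
                    continue
                units = _context_units(g, j)
                units[0] = surf(units[0])
                for u in units:
                    c = cid(u)
                    for f in focus:
                        pairs.append((f, c))

    nf, nc = len(focus_vocab), len(ctx_vocab)
    W_in = rng.uniform(-0.5 / cfg.k, 0.5 / cfg.k, size=(nf, cfg.k))
    W_out = np.zeros((nc, cfg.k))

    if cfg.epochs > 0 and pairs:
        freq = np.array(ctx_counts, dtype=float) ** 0.75
        neg_p = freq / freq.sum()
        pair_arr = np.array(pairs)
        total = cfg.epochs * len(pair_arr)
        step = 0
        for _ in range(cfg.epochs):
            order = rng.permutation(len(pair_arr))
            negs = rng.choice(nc, size=(len(pair_arr), cfg.negatives), p=neg_p)
            for row, idx in enumerate(order):
                f, c = pair_arr[idx]
                lr = cfg.lr * max(1e-4, 1.0 - step / total)
                step += 1
                targets = np.concatenate([[c], negs[row]])
                labels = np.zeros(len(targets))
                labels[0] = 1.0
                v = W_in[f]
                u = W_out[targets]
                scores = 1.0 / (1.0 + np.exp(-u @ v))
                grad = (scores - labels)[:, None]  # d loss / d (u.v)
                W_in[f] = v - lr * (grad * u).sum(axis=0)
                W_out[targets] = u - lr * grad * v

    word_words = [w for w in focus_vocab if not w.startswith("pos:")]
    word_tab = EmbeddingTable(
        vocab={w: i for i, w in enumerate(word_words)},
        vectors=np.vstack([W_in[focus_vocab[w]] for w in word_words]),
    )
    word_tab.vectors[word_tab.vocab[PAD]] = 0.0

    pos_words = sorted({u[len("pos:"):] for u in focus_vocab if u.startswith("pos:")})
    pos_rows = [W_in[focus_vocab[f"pos:{p}"]] for p in pos_words]
    pos_vocab = {PAD: 0, OOV: 1}
    for p in pos_words:
        pos_vocab[p] = len(pos_vocab)
    pad_oov = np.zeros((2, cfg.k))
    pad_oov[1] = rng.uniform(-0.5 / cfg.k, 0.5 / cfg.k, size=cfg.k)
    pos_tab = EmbeddingTable(vocab=pos_vocab,
                             vectors=np.vstack([pad_oov] + [r[None, :] for r in pos_rows]))
    return word_tab, pos_tab
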