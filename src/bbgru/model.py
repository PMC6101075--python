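"""The attention-based bidirectional GRU classifier.

Architecture, for one candidate with encoded input rows x_1..x_n
(d_w = k_word + k_pos + k_dist components each):

  GRU cell (no bias terms, matching the gate equations used here):
      r = sigma(W_r x + U_r h_prev)
      h~ = tanh(W x + U (r * h_prev))
      z = sigma(W_z x + U_z h_prev)
      h = z * h_prev + (1 - z) * h~          # z retains the previous state
  Bidirectional merge:  D[:, t] = (h_fwd_t + h_bwd_t) / 2
  Attention pooling:    H = tanh(D); m^ = p^T H; alpha = softmax(m^)
                        r = D alpha; o = tanh(r)
  Output:               softmax(W_o o + b_o) over {none, Lives_In}

Dropout (inverted, rate 0.5 by default) is applied to the pooled vector o
during training only.  All gradients are derived analytically and verified
against numerical differentiation in the test suite; training is mini-batch
Adam at the default learning rate 1e-3 with batch size 5.

Mini-batches are processed one instance at a time with gradient averaging,
which is exactly equivalent to padded-and-masked batching for a mean loss
and avoids padding bookkeeping at the short sequence lengths the
dependency-path inputs produce.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .candidates import CandidateInstance
from .embeddings import (
    EmbeddingTable,
    build_distance_table,
    encode_indices,
    max_abs_distance,
)
from .parse import LinearizedInput

logger = logging.getLogger(__name__)

LABELS = ("none", "Lives_In")
CHECKPOINT_VERSION = 1


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max())
    return e / e.sum()


@dataclass
class GRUParams:
    """The six learned matrices of one GRU direction (no biases)."""

    W_r: np.ndarray
    U_r: np.ndarray
    W_z: np.ndarray
    U_z: np.ndarray
    W: np.ndarray
    U: np.ndarray

    @property
    def hidden(self) -> int:
        return self.W.shape[0]

    @classmethod
    def create(cls, d_in: int, h: int, rng: np.random.Generator) -> "GRUParams":
        def m(rows, cols):
            return rng.uniform(-1.0, 1.0, size=(rows, cols)) / np.sqrt(cols)

        return cls(W_r=m(h, d_in), U_r=m(h, h), W_z=m(h, d_in), U_z=m(h, h),
                   W=m(h, d_in), U=m(h, h))


@dataclass
class GRUStep:
    r: np.ndarray
    z: np.ndarray
    h_tilde: np.ndarray
    h: np.ndarray


@dataclass
class AttentionOutput:
    H: np.ndarray
    m_hat: np.ndarray
    alpha: np.ndarray
    r: np.ndarray
    o: np.ndarray


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    dropout: float = 0.5
    batch_size: int = 5
    epochs: int = 4
    layers: int = 1
    k_word: int = 50
    k_pos: int = 50
    k_dist: int = 50  # total over both targets; each gets k_dist // 2
    hidden: int | None = None  # None -> d_w
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.layers != 1:
            raise ValueError("only single-layer GRUs are supported")
        if self.k_dist % 2:
            raise ValueError("k_dist is split over two targets and must be even")

    @property
    def d_w(self) -> int:
        return self.k_word + self.k_pos + self.k_dist


@dataclass
class ModelState:
    word_tab: EmbeddingTable
    pos_tab: EmbeddingTable
    dist1: np.ndarray
    dist2: np.ndarray
    s: int
    fwd: GRUParams
    bwd: GRUParams
    p: np.ndarray
    W_o: np.ndarray
    b_o: np.ndarray
    config: TrainConfig
    train_log: list[float] = field(default_factory=list)

    def params(self) -> dict[str, np.ndarray]:
        out = {"word": self.word_tab.vectors, "pos": self.pos_tab.vectors,
               "dist1": self.dist1, "dist2": self.dist2,
               "p": self.p, "W_o": self.W_o, "b_o": self.b_o}
        for tag, g in (("fwd", self.fwd), ("bwd", self.bwd)):
            for name in ("W_r", "U_r", "W_z", "U_z", "W", "U"):
                out[f"{tag}.{name}"] = getattr(g, name)
        return out


def init_state(
    cfg: TrainConfig,
    word_tab: EmbeddingTable,
    pos_tab: EmbeddingTable,
    s: int,
    rng: np.random.Generator,
) -> ModelState:
    h = cfg.hidden or cfg.d_w
    half = cfg.k_dist // 2
    return ModelState(
        word_tab=word_tab, pos_tab=pos_tab,
        dist1=build_distance_table(s, half), dist2=build_distance_table(s, half),
        s=s,
        fwd=GRUParams.create(cfg.d_w, h, rng), bwd=GRUParams.create(cfg.d_w, h, rng),
        p=rng.uniform(-1.0, 1.0, size=h) / np.sqrt(h),
        W_o=rng.uniform(-1.0, 1.0, size=(2, h)) / np.sqrt(h),
        b_o=np.zeros(2),
        config=cfg,
    )


# ---------------------------------------------------------------------------
# forward building blocks
# ---------------------------------------------------------------------------

def gru_step(x: np.ndarray, h_prev: np.ndarray, params: GRUParams) -> GRUStep:
    """One gated update: reset, candidate memory, update gate, new state."""
    if x.shape[0] != params.W.shape[1] or h_prev.shape[0] != params.U.shape[1]:
        raise ValueError("input/state width does not match the gate matrices")
    r = sigmoid(params.W_r @ x + params.U_r @ h_prev)
    h_tilde = np.tanh(params.W @ x + params.U @ (r * h_prev))
    z = sigmoid(params.W_z @ x + params.U_z @ h_prev)
    h = z * h_prev + (1.0 - z) * h_tilde
    return GRUStep(r=r, z=z, h_tilde=h_tilde, h=h)


def _gru_run(X: np.ndarray, params: GRUParams) -> list[GRUStep]:
    h = np.zeros(params.hidden)
    steps = []
    for t in range(X.shape[0]):
        st = gru_step(X[t], h, params)
        steps.append(st)
        h = st.h
    return steps


def bgru_forward(X: np.ndarray, fwd: GRUParams, bwd: GRUParams) -> np.ndarray:
    """Per-position mean of forward and backward states: D is h x n."""
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("input must be a non-empty n x d_w matrix")
    f = _gru_run(X, fwd)
    b = _gru_run(X[::-1], bwd)
    n = X.shape[0]
    D = np.empty((fwd.hidden, n))
    for t in range(n):
        D[:, t] = (f[t].h + b[n - 1 - t].h) / 2.0
    return D


def attention_pool(D: np.ndarray, p: np.ndarray) -> AttentionOutput:
    """Softmax-weighted pooling of the hidden states (max-stabilized)."""
    H = np.tanh(D)
    m_hat = p @ H
    alpha = softmax(m_hat)
    r = D @ alpha
    return AttentionOutput(H=H, m_hat=m_hat, alpha=alpha, r=r, o=np.tanh(r))


# ---------------------------------------------------------------------------
# full forward/backward for training
# ---------------------------------------------------------------------------

def _encode(state: ModelState, inp: LinearizedInput):
    wi, pi, d1, d2 = encode_indices(inp, state.word_tab, state.pos_tab, state.s)
    X = np.hstack([state.word_tab.vectors[wi], state.pos_tab.vectors[pi],
                   state.dist1[d1], state.dist2[d2]])
    return X, (wi, pi, d1, d2)


def _forward(state: ModelState, inp: LinearizedInput, drop_mask: np.ndarray | None):
    X, idx = _encode(state, inp)
    fsteps = _gru_run(X, state.fwd)
    bsteps = _gru_run(X[::-1], state.bwd)
    n = X.shape[0]
    D = np.empty((state.fwd.hidden, n))
    for t in range(n):
        D[:, t] = (fsteps[t].h + bsteps[n - 1 - t].h) / 2.0
    att = attention_pool(D, state.p)
    o = att.o if drop_mask is None else att.o * drop_mask
    logits = state.W_o @ o + state.b_o
    probs = softmax(logits)
    cache = {"X": X, "idx": idx, "fsteps": fsteps, "bsteps": bsteps, "D": D,
             "att": att, "o_used": o, "drop_mask": drop_mask, "probs": probs}
    return probs, cache


def _gru_backward(steps: list[GRUStep], X: np.ndarray, dH_seq: np.ndarray,
                  params: GRUParams) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """BPTT through one direction.

    dH_seq[t] is the loss gradient flowing into state h_t from outside the
    recurrence; returns gate-matrix gradients and the gradient w.r.t. X.
    """
    n = X.shape[0]
    g = {k: np.zeros_like(v) for k, v in
         (("W_r", params.W_r), ("U_r", params.U_r), ("W_z", params.W_z),
          ("U_z", params.U_z), ("W", params.W), ("U", params.U))}
    dX = np.zeros_like(X)
    dh_next = np.zeros(params.hidden)
    for t in range(n - 1, -1, -1):
        st = steps[t]
        h_prev = steps[t - 1].h if t > 0 else np.zeros(params.hidden)
        dh = dH_seq[t] + dh_next
        dz = dh * (h_prev - st.h_tilde)
        dh_prev = dh * st.z
        dh_tilde = dh * (1.0 - st.z)

        da_c = dh_tilde * (1.0 - st.h_tilde ** 2)
        g["W"] += np.outer(da_c, X[t])
        rh = st.r * h_prev
        g["U"] += np.outer(da_c, rh)
        drh = params.U.T @ da_c
        dr = drh * h_prev
        dh_prev = dh_prev + drh * st.r

        da_r = dr * st.r * (1.0 - st.r)
        g["W_r"] += np.outer(da_r, X[t])
        g["U_r"] += np.outer(da_r, h_prev)
        dh_prev = dh_prev + params.U_r.T @ da_r

        da_z = dz * st.z * (1.0 - st.z)
        g["W_z"] += np.outer(da_z, X[t])
        g["U_z"] += np.outer(da_z, h_prev)
        dh_prev = dh_prev + params.U_z.T @ da_z

        dX[t] = params.W.T @ da_c + params.W_r.T @ da_r + params.W_z.T @ da_z
        dh_next = dh_prev
    return g, dX


def _backward(state: ModelState, cache: dict, label: int) -> dict[str, np.ndarray]:
    grads = {k: np.zeros_like(v) for k, v in state.params().items()}
    probs = cache["probs"]
    att: AttentionOutput = cache["att"]
    D, X = cache["D"], cache["X"]
    n = X.shape[0]

    dlogits = probs.copy()
    dlogits[label] -= 1.0
    grads["W_o"] += np.outer(dlogits, cache["o_used"])
    grads["b_o"] += dlogits
    do = state.W_o.T @ dlogits
    if cache["drop_mask"] is not None:
        do = do * cache["drop_mask"]
    dr = do * (1.0 - att.o ** 2)

    dD = np.outer(dr, att.alpha)
    dalpha = D.T @ dr
    dm_hat = (dalpha - dalpha @ att.alpha) * att.alpha
    grads["p"] += att.H @ dm_hat
    dH = np.outer(state.p, dm_hat)
    dD += dH * (1.0 - att.H ** 2)

    dH_fwd = 0.5 * dD.T                     # dH_fwd[t] flows into forward h_t
    dH_bwd = 0.5 * dD.T[::-1]               # backward pass saw the reversed input
    gf, dXf = _gru_backward(cache["fsteps"], X, dH_fwd, state.fwd)
    gb, dXb = _gru_backward(cache["bsteps"], X[::-1], dH_bwd, state.bwd)
    for name, val in gf.items():
        grads[f"fwd.{name}"] += val
    for name, val in gb.items():
        grads[f"bwd.{name}"] += val
    dX = dXf + dXb[::-1]

    wi, pi, d1, d2 = cache["idx"]
    kw, kp = state.config.k_word, state.config.k_pos
    half = state.config.k_dist // 2
    np.add.at(grads["word"], wi, dX[:, :kw])
    np.add.at(grads["pos"], pi, dX[:, kw:kw + kp])
    np.add.at(grads["dist1"], d1, dX[:, kw + kp:kw + kp + half])
    np.add.at(grads["dist2"], d2, dX[:, kw + kp + half:])
    return grads


def loss_and_grads(
    state: ModelState, inp: LinearizedInput, label: int,
    drop_mask: np.ndarray | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Cross-entropy of one instance and its analytic parameter gradients."""
    probs, cache = _forward(state, inp, drop_mask)
    loss = -float(np.log(max(probs[label], 1e-300)))
    return loss, _backward(state, cache, label)


# ---------------------------------------------------------------------------
# inference and training
# ---------------------------------------------------------------------------

def _input_of(inst: CandidateInstance | LinearizedInput) -> LinearizedInput:
    if isinstance(inst, LinearizedInput):
        return inst
    if inst.linearized is None:
        raise ValueError("candidate carries no linearized input")
    return inst.linearized


def predict(state: ModelState, inst: CandidateInstance | LinearizedInput):
    """Class probabilities over (none, Lives_In) plus the attention weights.

    Inference is deterministic: dropout is disabled.
    """
    inp = _input_of(inst)
    if len(inp) == 0:
        raise ValueError("empty token sequence")
    probs, cache = _forward(state, inp, drop_mask=None)
    return probs, cache["att"].alpha


def predict_label(state: ModelState, inst) -> int:
    probs, _ = predict(state, inst)
    return int(np.argmax(probs))


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


def train_model(
    instances: list[CandidateInstance],
    cfg: TrainConfig,
    word_tab: EmbeddingTable | None = None,
    pos_tab: EmbeddingTable | None = None,
    state: ModelState | None = None,
) -> ModelState:
    """Mini-batch Adam on the mean cross-entropy.

    One integer seed (cfg.seed) drives parameter initialization, batch
    shuffling and the per-instance dropout masks, so identical calls give
    identical states.  Pretrained word/POS tables may be supplied; missing
    tables are randomly initialized from the training vocabulary and
    learned end-to-end like every other parameter.
    """
    if not instances:
        raise ValueError("no training instances")
    labels = {i.label for i in instances}
    if len(labels) < 2:
        logger.warning("training set contains a single class %s", labels)

    rng = np.random.default_rng(cfg.seed)
    if state is None:
        inputs = [_input_of(i) for i in instances]
        if word_tab is None:
            word_tab = EmbeddingTable.create(
                (t for inp in inputs for t in inp.tokens), cfg.k_word, rng)
        if pos_tab is None:
            pos_tab = EmbeddingTable.create(
                (t for inp in inputs for t in inp.pos), cfg.k_pos, rng)
        s = max_abs_distance(inputs)
        state = init_state(cfg, word_tab, pos_tab, s, rng)

    params = state.params()
    opt = _Adam(params, cfg.learning_rate)
    h = state.fwd.hidden
    keep = 1.0 - cfg.dropout

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(instances))
        epoch_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            grads = {k: np.zeros_like(v) for k, v in params.items()}
            for idx in batch:
                inst = instances[idx]
                if cfg.dropout > 0.0:
                    mask = (rng.random(h) < keep).astype(float) / keep
                else:
                    mask = None
                loss, g = loss_and_grads(state, _input_of(inst), inst.label, mask)
                epoch_loss += loss
                for k in grads:
                    grads[k] += g[k] / len(batch)
            opt.step(params, grads)
        mean_loss = epoch_loss / len(instances)
        state.train_log.append(mean_loss)
        logger.info("epoch %d/%d: mean training loss %.4f", epoch + 1, cfg.epochs, mean_loss)
    return state


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(state: ModelState, path) -> None:
    """Single npz archive: every tensor plus a JSON metadata entry."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(state.config),
        "s": state.s,
        "word_vocab": sorted(state.word_tab.vocab, key=state.word_tab.vocab.get),
        "pos_vocab": sorted(state.pos_tab.vocab, key=state.pos_tab.vocab.get),
        "train_log": state.train_log,
    }
    with open(path, "wb") as fh:  # explicit handle: np.savez must not append .npz
        np.savez(fh, meta=np.array(json.dumps(meta)), **state.params())


def load_checkpoint(path) -> ModelState:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        cfg = TrainConfig(**meta["config"])
        arrays = {k: data[k] for k in data.files if k != "meta"}
    state = ModelState(
        word_tab=EmbeddingTable(
            vocab={w: i for i, w in enumerate(meta["word_vocab"])}, vectors=arrays["word"]),
        pos_tab=EmbeddingTable(
            vocab={w: i for i, w in enumerate(meta["pos_vocab"])}, vectors=arrays["pos"]),
        dist1=arrays["dist1"], dist2=arrays["dist2"], s=int(meta["s"]),
        fwd=GRUParams(**{n: arrays[f"fwd.{n}"] for n in ("W_r", "U_r", "W_z", "U_z", "W", "U")}),
        bwd=GRUParams(**{n: arrays[f"bwd.{n}"] for n in ("W_r", "U_r", "W_z", "U_z", "W", "U")}),
        p=arrays["p"], W_o=arrays["W_o"], b_o=arrays["b_o"],
        config=cfg, train_log=list(meta["train_log"]),
    )
    return state
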