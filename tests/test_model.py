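"""GRU equations, bidirectional merge, attention pooling, training loop,
and the analytic-gradient check."""

import math

import numpy as np
import pytest

from bbgru.embeddings import EmbeddingTable
from bbgru.model import (
    GRUParams,
    TrainConfig,
    _forward,
    attention_pool,
    bgru_forward,
    gru_step,
    init_state,
    load_checkpoint,
    loss_and_grads,
    predict,
    save_checkpoint,
    train_model,
)
from bbgru.parse import LinearizedInput


def _params(d, h, rng=None, zero=False):
    if zero:
        z = np.zeros
        return GRUParams(W_r=z((h, d)), U_r=z((h, h)), W_z=z((h, d)),
                         U_z=z((h, h)), W=z((h, d)), U=z((h, h)))
    return GRUParams.create(d, h, rng)


def _scalar_gru_step(x, h_prev, p: GRUParams):
    """Element-by-element reference evaluation of the gate equations,
    written independently of the vectorized implementation."""
    h = len(h_prev)
    r = np.empty(h)
    z = np.empty(h)
    h_tilde = np.empty(h)
    h_new = np.empty(h)
    for j in range(h):
        a_r = sum(p.W_r[j, i] * x[i] for i in range(len(x)))
        a_r += sum(p.U_r[j, i] * h_prev[i] for i in range(h))
        r[j] = 1.0 / (1.0 + math.exp(-a_r))
    for j in range(h):
        a_c = sum(p.W[j, i] * x[i] for i in range(len(x)))
        a_c += sum(p.U[j, i] * r[i] * h_prev[i] for i in range(h))
        h_tilde[j] = math.tanh(a_c)
    for j in range(h):
        a_z = sum(p.W_z[j, i] * x[i] for i in range(len(x)))
        a_z += sum(p.U_z[j, i] * h_prev[i] for i in range(h))
        z[j] = 1.0 / (1.0 + math.exp(-a_z))
    for j in range(h):
        h_new[j] = z[j] * h_prev[j] + (1.0 - z[j]) * h_tilde[j]
    return r, z, h_tilde, h_new


def test_zero_parameters_halve_previous_state():
    """With all-zero weights the gates sit at 1/2 and the candidate at 0,
    so the new state is exactly half the previous one."""
    h_prev = np.array([2.0, -4.0, 1.0])
    st = gru_step(np.array([1.0, 1.0]), h_prev, _params(2, 3, zero=True))
    assert np.allclose(st.r, 0.5) and np.allclose(st.z, 0.5)
    assert np.allclose(st.h_tilde, 0.0)
    assert np.allclose(st.h, 0.5 * h_prev)


def test_gru_step_matches_scalar_loop_on_fixed_case():
    p = GRUParams(W_r=np.array([[1.0, -1.0], [2.0, 0.0]]), U_r=np.eye(2),
                  W_z=np.array([[0.0, 1.0], [-1.0, 1.0]]), U_z=2 * np.eye(2),
                  W=np.array([[1.0, 1.0], [0.0, -2.0]]), U=np.array([[0.0, 1.0], [1.0, 0.0]]))
    x, h_prev = np.array([0.5, -1.0]), np.array([0.25, 0.75])
    st = gru_step(x, h_prev, p)
    r, z, h_tilde, h_new = _scalar_gru_step(x, h_prev, p)
    for got, want in ((st.r, r), (st.z, z), (st.h_tilde, h_tilde), (st.h, h_new)):
        assert np.max(np.abs(got - want)) < 1e-12


def test_gru_step_matches_scalar_loop_on_100_random_draws():
    rng = np.random.default_rng(42)
    for _ in range(100):
        d, h = int(rng.integers(1, 5)), int(rng.integers(1, 5))
        p = _params(d, h, rng)
        x, h_prev = rng.normal(size=d), rng.normal(size=h)
        st = gru_step(x, h_prev, p)
        r, z, h_tilde, h_new = _scalar_gru_step(x, h_prev, p)
        assert np.max(np.abs(st.h - h_new)) < 1e-10
        assert np.max(np.abs(st.r - r)) < 1e-10
        assert np.max(np.abs(st.z - z)) < 1e-10
        assert np.max(np.abs(st.h_tilde - h_tilde)) < 1e-10


def test_update_gate_limits():
    """Saturating the update gate retains the previous state; forcing it
    to zero hands the state over to the candidate memory."""
    rng = np.random.default_rng(0)
    d, h = 3, 4
    p = _params(d, h, rng)
    x, h_prev = rng.normal(size=d), rng.normal(size=h)
    p.W_z[:] = 0.0
    p.U_z[:] = 0.0
    big = 50.0
    p.W_z += big / d  # drive z towards 1
    x_pos = np.abs(x) + 1.0
    st = gru_step(x_pos, h_prev, p)
    assert np.allclose(st.h, h_prev, atol=1e-8)
    p.W_z -= 2 * big / d  # drive z towards 0
    st = gru_step(x_pos, h_prev, p)
    assert np.allclose(st.h, st.h_tilde, atol=1e-8)


def test_gate_activations_stay_in_range():
    rng = np.random.default_rng(3)
    st = gru_step(rng.normal(size=4) * 10, rng.normal(size=5) * 10, _params(4, 5, rng))
    assert np.all((st.r > 0) & (st.r < 1))
    assert np.all((st.z > 0) & (st.z < 1))
    assert np.all((st.h_tilde > -1) & (st.h_tilde < 1))


def test_bgru_single_step_with_tied_directions():
    rng = np.random.default_rng(1)
    p = _params(3, 4, rng)
    X = rng.normal(size=(1, 3))
    D = bgru_forward(X, p, p)
    st = gru_step(X[0], np.zeros(4), p)
    assert np.allclose(D[:, 0], st.h)  # mean of two equal states


def test_bgru_reversal_symmetry():
    """Reversing the input and swapping direction parameters reverses D."""
    rng = np.random.default_rng(2)
    fwd, bwd = _params(3, 4, rng), _params(3, 4, rng)
    X = rng.normal(size=(5, 3))
    D = bgru_forward(X, fwd, bwd)
    D_rev = bgru_forward(X[::-1], bwd, fwd)
    assert np.allclose(D, D_rev[:, ::-1])


def test_bgru_composes_gru_steps():
    rng = np.random.default_rng(4)
    fwd, bwd = _params(2, 3, rng), _params(2, 3, rng)
    X = rng.normal(size=(3, 2))
    hf = np.zeros(3)
    fstates = []
    for t in range(3):
        hf = gru_step(X[t], hf, fwd).h
        fstates.append(hf)
    hb = np.zeros(3)
    bstates = {}
    for t in (2, 1, 0):
        hb = gru_step(X[t], hb, bwd).h
        bstates[t] = hb
    D = bgru_forward(X, fwd, bwd)
    for t in range(3):
        assert np.allclose(D[:, t], (fstates[t] + bstates[t]) / 2.0)


def test_bgru_rejects_empty_sequence():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        bgru_forward(np.empty((0, 3)), _params(3, 2, rng), _params(3, 2, rng))


def test_attention_uniform_at_zero_scoring_vector():
    rng = np.random.default_rng(0)
    D = rng.normal(size=(4, 6))
    att = attention_pool(D, np.zeros(4))
    assert np.allclose(att.alpha, 1.0 / 6.0)


def test_attention_weights_normalized_and_shift_invariant():
    rng = np.random.default_rng(1)
    for _ in range(20):
        D, p = rng.normal(size=(3, 5)), rng.normal(size=3)
        att = attention_pool(D, p)
        assert abs(att.alpha.sum() - 1.0) < 1e-12
        assert np.all(att.alpha >= 0)
        shifted = attention_pool(D, p)
        shifted_alpha = np.exp(att.m_hat + 7.5)
        shifted_alpha /= shifted_alpha.sum()
        assert np.allclose(att.alpha, shifted_alpha, atol=1e-12)


def test_attention_closed_form_two_tokens():
    """Scores (ln 3, 0) give weights (0.75, 0.25)."""
    # pick D, p with p^T tanh(D) = (ln 3, 0)
    D = np.arctanh(np.array([[math.log(3.0) / 2.0, 0.0]]))
    att = attention_pool(D, np.array([2.0]))
    assert np.allclose(att.alpha, [0.75, 0.25], atol=1e-12)


def test_pooled_output_bounded():
    rng = np.random.default_rng(9)
    att = attention_pool(rng.normal(size=(4, 7)) * 5, rng.normal(size=4))
    assert np.all((att.o > -1) & (att.o < 1))
    assert att.r.shape == (4,) and att.o.shape == (4,)


# ---------------------------------------------------------------------------
# end-to-end model behaviour
# ---------------------------------------------------------------------------

def _tiny_instances(n_pos=3, n_neg=3):
    """Separable toy candidates: the cue verb marks the positives."""
    from bbgru.candidates import CandidateInstance
    from bbgru.standoff import Entity

    def ent(eid, etype):
        return Entity(id=eid, type=etype, spans=((0, 1),), surface="x")

    insts = []
    for i in range(n_pos + n_neg):
        pos = i < n_pos
        verb = "inhabits" if pos else "resembles"
        lin = LinearizedInput(tokens=["entity_1", verb, "entity_2"],
                              pos=["NNP", "VBZ", "NNP"], e1_pos=0, e2_pos=2)
        insts.append(CandidateInstance(
            doc_id="d", sentence_index=0, e1=ent("T1", "Bacteria"),
            e2=ent("T2", "Habitat"), tokens=["entity_1", verb, "entity_2"],
            e1_pos=0, e2_pos=2, label=int(pos), linearized=lin))
    return insts


def _tiny_cfg(**kw):
    defaults = dict(k_word=8, k_pos=4, k_dist=4, hidden=6, epochs=5, seed=3,
                    dropout=0.0, batch_size=2)
    defaults.update(kw)
    return TrainConfig(**defaults)


def test_predict_probabilities_sum_to_one_and_deterministic():
    insts = _tiny_instances()
    state = train_model(insts, _tiny_cfg(epochs=1))
    p1, a1 = predict(state, insts[0])
    p2, a2 = predict(state, insts[0])
    assert abs(p1.sum() - 1.0) < 1e-12
    assert np.array_equal(p1, p2) and np.array_equal(a1, a2)
    assert abs(a1.sum() - 1.0) < 1e-9


def test_overfit_single_positive_instance():
    insts = _tiny_instances(n_pos=1, n_neg=1)
    state = train_model(insts, _tiny_cfg(epochs=60, batch_size=2, learning_rate=1e-2))
    probs, _ = predict(state, insts[0])
    assert probs[1] > 0.9


def test_zero_epochs_returns_initialization():
    insts = _tiny_instances()
    a = train_model(insts, _tiny_cfg(epochs=0))
    b = train_model(insts, _tiny_cfg(epochs=0))
    for k, v in a.params().items():
        assert np.array_equal(v, b.params()[k]), k
    assert a.train_log == []


def test_training_loss_descends_on_planted_cue_corpus():
    from bbgru import pipeline
    from bbgru.synth import SynthConfig, generate_corpus, write_corpus
    import tempfile

    with tempfile.TemporaryDirectory() as d:
        write_corpus(generate_corpus(SynthConfig(n_docs=8, seed=7)), d)
        insts, _ = pipeline.build_dataset(pipeline.load_corpus_dir(d))
    state = train_model(insts, TrainConfig(seed=7, epochs=3, k_word=16, k_pos=8,
                                           k_dist=8, hidden=24))
    assert state.train_log[2] < state.train_log[0]


def test_capacity_on_separable_instances():
    insts = _tiny_instances(10, 10)
    state = train_model(insts, _tiny_cfg(epochs=30))
    acc = np.mean([int(np.argmax(predict(state, i)[0])) == i.label for i in insts])
    assert acc == 1.0


def test_single_class_training_warns_but_trains(caplog):
    insts = _tiny_instances(n_pos=0, n_neg=3)
    with caplog.at_level("WARNING"):
        state = train_model(insts, _tiny_cfg(epochs=1))
    assert any("single class" in r.message for r in caplog.records)
    assert len(state.train_log) == 1


def test_fixed_seed_training_is_bit_identical():
    insts = _tiny_instances()
    a = train_model(insts, _tiny_cfg(epochs=2, dropout=0.5))
    b = train_model(insts, _tiny_cfg(epochs=2, dropout=0.5))
    for k, v in a.params().items():
        assert np.array_equal(v, b.params()[k]), k


def test_checkpoint_round_trip(tmp_path):
    insts = _tiny_instances()
    state = train_model(insts, _tiny_cfg(epochs=1))
    save_checkpoint(state, tmp_path / "m.ckpt")
    loaded = load_checkpoint(tmp_path / "m.ckpt")
    for k, v in state.params().items():
        assert np.array_equal(v, loaded.params()[k]), k
    p1, _ = predict(state, insts[0])
    p2, _ = predict(loaded, insts[0])
    assert np.array_equal(p1, p2)


def test_numerical_gradient_check():
    """Analytic gradients agree with central differences to 1e-4 relative
    error for every parameter group on a tiny instance."""
    rng = np.random.default_rng(0)
    cfg = _tiny_cfg(k_word=6, k_pos=4, hidden=5)
    word_tab = EmbeddingTable.create(["entity_1", "inhabits", "entity_2", "the"],
                                     cfg.k_word, rng)
    pos_tab = EmbeddingTable.create(["NNP", "VBZ", "DT"], cfg.k_pos, rng)
    state = init_state(cfg, word_tab, pos_tab, s=3, rng=rng)
    inp = LinearizedInput(tokens=["the", "entity_1", "inhabits", "entity_2"],
                          pos=["DT", "NNP", "VBZ", "NNP"], e1_pos=1, e2_pos=3)
    label = 1

    def loss():
        probs, _ = _forward(state, inp, None)
        return -np.log(probs[label])

    _, grads = loss_and_grads(state, inp, label)
    eps = 1e-6
    for name, arr in state.params().items():
        num = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + eps
            lp = loss()
            arr[idx] = orig - eps
            lm = loss()
            arr[idx] = orig
            num[idx] = (lp - lm) / (2 * eps)
        scale = max(np.abs(num).max(), np.abs(grads[name]).max(), 1e-8)
        rel = np.abs(num - grads[name]).max() / scale
        assert rel < 1e-4, f"{name}: relative error {rel:.2e}"
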