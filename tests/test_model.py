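import numpy as np
import pytest

from mvha.autodiff import Tensor
from mvha.model import (ModelConfig, MVHAModel, _BiLSTM, _KnowledgeAttention,
                        ablation_variant, build_model, ce_loss, ce_loss_logits,
                        count_parameters, load_checkpoint, save_checkpoint)
from mvha.records import HIGH_FREQUENCY, NUMERIC, ChannelSpec, ValidationError

from oracle import bilstm_ref, forward_ref

TINY = dict(num_filters=2, conv_kernels_highfreq=(3,), conv_kernels_numeric=(2,),
            pool_width=1, use_batchnorm=False, lstm_layers=1, lstm_hidden=2,
            attn_hidden_fl=2, attn_hidden_tr=2, fc_out=2, dropout=0.0)
SPECS = [ChannelSpec("W", HIGH_FREQUENCY, 2.0), ChannelSpec("N", NUMERIC, 1.0)]
M = 3


def tiny_model(seed=0, variant="MVHA", **over):
    cfg = ModelConfig(seed=seed, **{**TINY, **over})
    return MVHAModel(cfg, SPECS, M, step_seconds=4.0, variant=variant)


def tiny_batch(b=2, seed=0):
    rng = np.random.default_rng(seed)
    return {
        "segments": {"W": rng.normal(size=(b, M, 8)), "N": rng.normal(size=(b, M, 4))},
        "fluct": rng.random((b, 2, M)),
        "trend": rng.random((b, 2)),
        "tr": rng.random((b, (M - 1) * 2)),
        "channel_order": ["W", "N"],
    }


# ------------------------------------------------------------ attention math

def test_fluct_attention_hand_softmax():
    # scores (1, 2) from W passing both rows through unity -> softmax(1, 2)
    attn = _KnowledgeAttention("t", n_features=1, hidden=1,
                               rng=np.random.default_rng(0))
    attn.params["t/W"].data = np.array([[1.0], [1.0]])
    attn.params["t/b"].data = np.array([0.0])
    attn.params["t/V"].data = np.array([1.0])
    o = Tensor(np.array([[[1.0, 2.0]]]))          # (B=1, U=1, M=2)
    alpha, of = attn.forward(o, np.array([[0.0, 0.0]]))
    e = np.exp(1.0)
    np.testing.assert_allclose(alpha.data, [[1 / (1 + e), e / (1 + e)]], atol=1e-12)
    np.testing.assert_allclose(of.data, o.data * alpha.data[:, None, :], atol=1e-12)


def test_trend_attention_hand_softmax_and_fusion():
    # scores (0, ln 3) -> beta (0.25, 0.75); d = 0.25 x1 + 0.75 x2
    attn = _KnowledgeAttention("t", n_features=1, hidden=1,
                               rng=np.random.default_rng(0))
    attn.params["t/W"].data = np.array([[0.0], [1.0]])  # score = knowledge row
    attn.params["t/b"].data = np.array([0.0])
    attn.params["t/V"].data = np.array([1.0])
    x = Tensor(np.array([[[2.0, 4.0]]]))
    beta, attended = attn.forward(x, np.array([[0.0, np.log(3.0)]]))
    np.testing.assert_allclose(beta.data, [[0.25, 0.75]], atol=1e-12)
    d = attended.sum(axis=2)
    np.testing.assert_allclose(d.data, [[0.25 * 2 + 0.75 * 4]], atol=1e-12)


def test_attention_uniform_for_identical_columns():
    attn = _KnowledgeAttention("t", n_features=3, hidden=4,
                               rng=np.random.default_rng(1))
    col = np.random.default_rng(2).normal(size=3)
    o = Tensor(np.tile(col[None, :, None], (1, 1, 5)))
    alpha, _ = attn.forward(o, np.full((1, 5), 0.7))
    np.testing.assert_allclose(alpha.data, np.full((1, 5), 0.2), atol=1e-12)


def test_attention_simplex_invariants_over_many_random_trials():
    rng = np.random.default_rng(3)
    attn = _KnowledgeAttention("t", n_features=4, hidden=3, rng=rng)
    for _ in range(1000):
        o = Tensor(rng.normal(scale=rng.uniform(0.1, 50), size=(2, 4, 6)))
        weights, _ = attn.forward(o, rng.random((2, 6)))
        assert (weights.data >= 0).all()
        np.testing.assert_allclose(weights.data.sum(axis=1), 1.0, atol=1e-6)


def test_fluct_attention_monotone_in_sd_feature():
    # SD row passed through positively, identical feature columns:
    # alpha strictly increases with segment SD
    attn = _KnowledgeAttention("t", n_features=2, hidden=2,
                               rng=np.random.default_rng(4))
    attn.params["t/W"].data = np.vstack([np.zeros((2, 2)), np.ones((1, 2))])
    attn.params["t/V"].data = np.array([1.0, 1.0])
    o = Tensor(np.ones((1, 2, 5)))
    sd = np.array([[0.1, 0.5, 0.2, 0.9, 0.4]])
    alpha, _ = attn.forward(o, sd)
    assert (np.argsort(alpha.data[0]) == np.argsort(sd[0])).all()
    assert (np.diff(alpha.data[0][np.argsort(sd[0])]) > 0).all()


# ----------------------------------------------------------------- Bi-LSTM

def test_lstm_zero_weights_give_zero_outputs():
    # sigmoid(0)=0.5 gates, tanh(0)=0 candidate -> c=0, h=0 at every step
    lstm = _BiLSTM("z", in_dim=3, hidden=4, layers=2, rng=np.random.default_rng(0))
    for p in lstm.params.values():
        p.data = np.zeros_like(p.data)
    h = lstm.forward(Tensor(np.random.default_rng(1).normal(size=(2, 5, 3))))
    assert h.shape == (2, 5, 8)
    np.testing.assert_array_equal(h.data, 0.0)


def test_lstm_matches_loop_reference():
    rng = np.random.default_rng(5)
    lstm = _BiLSTM("z", in_dim=3, hidden=2, layers=2, rng=rng)
    x = rng.normal(size=(4, M, 3))
    h = lstm.forward(Tensor(x))
    params = {k: v.data for k, v in lstm.params.items()}
    for b in range(4):
        ref = bilstm_ref([x[b, t] for t in range(M)], params, "z", 2, 2)
        np.testing.assert_allclose(h.data[b].T, ref, atol=1e-9)


def test_default_config_hidden_width():
    cfg = ModelConfig()  # 16 hidden units per direction, 3 layers
    lstm = _BiLSTM("z", in_dim=cfg.num_filters, hidden=cfg.lstm_hidden,
                   layers=cfg.lstm_layers, rng=np.random.default_rng(0))
    h = lstm.forward(Tensor(np.zeros((1, M, 8))))
    assert h.shape == (1, M, 32)  # J = 2 x 16


# ------------------------------------------------------------- forward pass

def test_forward_shapes_and_simplex():
    model = tiny_model()
    out = model.forward(tiny_batch(), training=False)
    assert out.probs.shape == (2, 2)
    np.testing.assert_allclose(out.probs.data.sum(axis=1), 1.0, atol=1e-9)
    assert out.alpha["W"].shape == (2, M) and out.beta.shape == (2, 2)
    np.testing.assert_allclose(out.alpha["N"].sum(axis=1), 1.0, atol=1e-9)
    np.testing.assert_allclose(out.beta.sum(axis=1), 1.0, atol=1e-9)


def test_forward_matches_independent_loop_reference():
    model = tiny_model(seed=9)
    # give the zero-initialized head nonzero weights so the check is not trivial
    rng = np.random.default_rng(10)
    model.params["head/Whd"].data = rng.normal(size=(2, 2))
    model.params["head/Wtr"].data = rng.normal(size=((M - 1) * 2, 2))
    model.params["head/b"].data = rng.normal(size=2)
    batch = tiny_batch(b=3, seed=11)
    out = model.forward(batch, training=False)
    params = {k: v.data for k, v in model.params.items()}
    cfg = dict(num_filters=2, lstm_hidden=2, lstm_layers=1, fc_out=2)
    for b in range(3):
        one = {"segments": {n: batch["segments"][n][b] for n in ("W", "N")},
               "fluct": batch["fluct"][b], "trend": batch["trend"][b],
               "tr": batch["tr"][b]}
        probs, alphas, beta = forward_ref(one, params, ["W", "N"],
                                          [HIGH_FREQUENCY, NUMERIC], cfg)
        np.testing.assert_allclose(out.probs.data[b], probs, atol=1e-6)
        np.testing.assert_allclose(out.beta[b], beta, atol=1e-6)
        for n in ("W", "N"):
            np.testing.assert_allclose(out.alpha[n][b], alphas[n], atol=1e-6)


def test_forward_deterministic_and_seeded_build():
    m1, m2 = tiny_model(seed=4), tiny_model(seed=4)
    for k in m1.params:
        np.testing.assert_array_equal(m1.params[k].data, m2.params[k].data)
    b = tiny_batch(seed=5)
    o1 = m1.forward(b, training=False)
    o2 = m2.forward(b, training=False)
    np.testing.assert_array_equal(o1.probs.data, o2.probs.data)
    m3 = tiny_model(seed=6)
    assert any(not np.array_equal(m1.params[k].data, m3.params[k].data)
               for k in m1.params)


def test_zero_head_gives_even_probabilities():
    model = tiny_model()  # heads are zero-initialized
    out = model.forward(tiny_batch(), training=False)
    np.testing.assert_allclose(out.probs.data, 0.5, atol=1e-12)
    np.testing.assert_array_equal(out.labels, 0)  # 0.5/0.5 tie -> class 0


def test_gradients_match_finite_differences_on_tiny_model():
    model = tiny_model(seed=3, use_batchnorm=True)
    batch = tiny_batch(b=4, seed=1)
    y = np.array([0, 1, 1, 0])

    def reset_bn():
        for br in model.branches.values():
            for r in br.running:
                r.clear()
                r.update({"mean": np.zeros(2), "var": np.ones(2)})

    def loss():
        reset_bn()
        return ce_loss_logits(model.forward(batch, training=True).logits, y)

    base = loss()
    for p in model.parameters():
        p.grad = None
    base.backward()
    rng = np.random.default_rng(0)
    for name in rng.choice(sorted(model.params), size=8, replace=False):
        p = model.params[name]
        flat = p.data.reshape(-1)
        i = int(rng.integers(flat.size))
        old = flat[i]
        eps = 1e-6
        flat[i] = old + eps
        up = float(loss().data)
        flat[i] = old - eps
        down = float(loss().data)
        flat[i] = old
        num = (up - down) / (2 * eps)
        assert p.grad.reshape(-1)[i] == pytest.approx(num, abs=1e-4), name


# ------------------------------------------------------------------- loss

def test_ce_loss_closed_forms():
    assert float(ce_loss(Tensor([[1.0, 0.0]]), np.array([0])).data) \
        == pytest.approx(0.0, abs=1e-9)
    assert float(ce_loss(Tensor([[0.5, 0.5]]), np.array([1])).data) \
        == pytest.approx(np.log(2), abs=1e-12)
    two = Tensor([[0.5, 0.5], [0.5, 0.5]])
    assert float(ce_loss(two, np.array([0, 1]), reduction="sum").data) \
        == pytest.approx(2 * np.log(2), abs=1e-12)
    assert float(ce_loss(two, np.array([0, 1]), reduction="mean").data) \
        == pytest.approx(np.log(2), abs=1e-12)


def test_ce_loss_logits_agrees_with_probability_form():
    rng = np.random.default_rng(0)
    logits = rng.normal(size=(5, 2))
    y = rng.integers(0, 2, size=5)
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs = e / e.sum(axis=1, keepdims=True)
    assert float(ce_loss_logits(Tensor(logits), y).data) == pytest.approx(
        float(ce_loss(Tensor(probs), y, reduction="mean").data), abs=1e-9)


def test_ce_loss_shape_validation():
    with pytest.raises(ValidationError):
        ce_loss(Tensor([[0.5, 0.5]]), np.array([0, 1]))


# ------------------------------------------------------- variants & counting

def test_count_parameters_plain_linear_map():
    w, b = np.zeros((3, 2)), np.zeros(2)
    assert count_parameters([w, b]) == 8


def test_mvha_has_more_parameters_than_fluct_only_variant():
    full = tiny_model(seed=0)
    fattn = tiny_model(seed=0, variant="CLSTM-FAttn")
    assert count_parameters(full) > count_parameters(fattn)


def test_unknown_variant_rejected():
    with pytest.raises(ValidationError):
        tiny_model(variant="CLSTM-XAttn")


def test_cnn_ecg_variant_uses_only_high_frequency_channel():
    model = tiny_model(variant="CNN (ECG)")
    assert model.channel_names == ["W"]
    out = model.forward(tiny_batch(), training=False)  # extra channels ignored
    assert out.probs.shape == (2, 2)
    assert out.beta is None and out.alpha == {}


def test_fluct_only_variant_equals_mvha_with_constant_trend_scores():
    full = tiny_model(seed=8)
    fattn = tiny_model(seed=8, variant="CLSTM-FAttn")
    for k, p in fattn.params.items():
        p.data = full.params[k].data.copy()
    # constant trend scores in MVHA -> uniform beta == CLSTM-FAttn's fusion
    full.params["trend/W"].data[:] = 0.0
    full.params["trend/V"].data[:] = 0.0
    batch = tiny_batch(seed=2)
    np.testing.assert_allclose(full.forward(batch, training=False).probs.data,
                               fattn.forward(batch, training=False).probs.data,
                               atol=1e-12)


def test_kernel_wider_than_segment_rejected_at_build():
    with pytest.raises(ValidationError):
        tiny_model(conv_kernels_numeric=(5,))  # numeric segments hold 4 samples


# -------------------------------------------------------------- checkpoints

def test_checkpoint_roundtrip(tmp_path):
    model = tiny_model(seed=13, use_batchnorm=True)
    batch = tiny_batch(seed=14)
    model.forward(batch, training=True)  # populate running stats
    ref = model.forward(batch, training=False).probs.data
    path = tmp_path / "model.npz"
    save_checkpoint(model, path)
    assert (tmp_path / "model.txt").exists()
    clone = load_checkpoint(path)
    np.testing.assert_array_equal(clone.forward(batch, training=False).probs.data,
                                  ref)
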