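"""Architecture contracts for the seq2seq and transformer cores."""

import numpy as np
import pytest

from retroseq.data import to_seq_pairs
from retroseq.models import (
    ModelConfig,
    _log_softmax,
    build_model,
    build_seq2seq,
    build_transformer,
    load_checkpoint,
    save_checkpoint,
)
from retroseq.nn import no_grad
from retroseq.training import _pad_batch
from retroseq.vocab import build_vocabulary


@pytest.fixture(scope="module")
def vocab(tiny_corpora):
    large, small = tiny_corpora
    return build_vocabulary([large, small])


@pytest.fixture(scope="module")
def batch(tiny_corpora, vocab):
    pairs = to_seq_pairs(tiny_corpora[1])[:6]
    src = _pad_batch([vocab.encode(p.source) for p in pairs])
    tgt = _pad_batch([[vocab.bos_id] + vocab.encode(p.target)[:8] for p in pairs])
    return src, tgt


def small_cfg(arch, **kw):
    base = dict(seed=1, max_steps=5)
    base.update(kw)
    if arch == "transformer":
        return ModelConfig.desk_transformer(**base)
    return ModelConfig.desk_seq2seq(**base)


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(architecture="transformer", model_dim=50, n_heads=4)
    with pytest.raises(ValueError):
        ModelConfig(architecture="mlp")
    with pytest.raises(ValueError):
        ModelConfig(hidden_dim=0)


def test_transformer_reference_depth_default():
    cfg = ModelConfig()
    assert cfg.n_decoder_layers == 6
    assert cfg.n_encoder_layers == 6


@pytest.mark.parametrize("arch", ["seq2seq", "transformer"])
def test_forward_outputs_distributions(arch, vocab, batch):
    src, tgt = batch
    model = build_model(small_cfg(arch), vocab)
    with no_grad():
        logits = model.forward_teacher(src, tgt, train=False)
    probs = np.exp(_log_softmax(logits.data))
    assert probs.shape == (src.shape[0], tgt.shape[1], len(vocab))
    assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-4)


@pytest.mark.parametrize("arch", ["seq2seq", "transformer"])
def test_seeded_init_deterministic(arch, vocab):
    m1 = build_model(small_cfg(arch), vocab)
    m2 = build_model(small_cfg(arch), vocab)
    for k in m1.params:
        assert np.array_equal(m1.params[k].data, m2.params[k].data)
    m3 = build_model(small_cfg(arch, seed=2), vocab)
    assert any(not np.array_equal(m1.params[k].data, m3.params[k].data) for k in m1.params)


def test_parameter_count_monotone_in_width(vocab):
    small = build_seq2seq(small_cfg("seq2seq", hidden_dim=32), vocab)
    big = build_seq2seq(small_cfg("seq2seq", hidden_dim=64), vocab)
    assert big.n_parameters() > small.n_parameters()
    t_small = build_transformer(small_cfg("transformer", model_dim=32, ff_dim=64), vocab)
    t_big = build_transformer(small_cfg("transformer", model_dim=64, ff_dim=128), vocab)
    assert t_big.n_parameters() > t_small.n_parameters()


def test_causal_mask_blocks_future(vocab, batch):
    """Changing a future target token must not change earlier logits."""
    src, tgt = batch
    model = build_transformer(small_cfg("transformer"), vocab)
    with no_grad():
        base = model.forward_teacher(src, tgt, train=False).data
        tgt2 = tgt.copy()
        tgt2[:, -1] = (tgt2[:, -1] + 1) % len(vocab)
        mod = model.forward_teacher(src, tgt2, train=False).data
    assert np.allclose(base[:, :-1, :], mod[:, :-1, :], atol=1e-5)
    assert not np.allclose(base[:, -1, :], mod[:, -1, :], atol=1e-5)


@pytest.mark.parametrize("arch", ["seq2seq", "transformer"])
def test_decoding_invariant_to_pad_extension(arch, vocab, batch):
    src, tgt = batch
    model = build_model(small_cfg(arch), vocab)
    padded = np.concatenate([src, np.zeros((src.shape[0], 4), np.int64)], axis=1)
    with no_grad():
        m1 = model.encode(src, train=False)
        m2 = model.encode(padded, train=False)
    s1, s2 = model.init_state(m1), model.init_state(m2)
    prev = np.full(src.shape[0], vocab.bos_id, dtype=np.int64)
    lp1 = model.step(s1, prev)
    lp2 = model.step(s2, prev)
    assert np.allclose(lp1, lp2, atol=1e-4)


@pytest.mark.parametrize("arch", ["seq2seq", "transformer"])
def test_cached_step_matches_teacher_forced(arch, vocab, batch):
    src, tgt = batch
    model = build_model(small_cfg(arch), vocab)
    with no_grad():
        memory = model.encode(src, train=False)
        full = _log_softmax(model.forward_teacher(src, tgt, train=False).data)
    state = model.init_state(memory)
    for t in range(tgt.shape[1]):
        lp = model.step(state, tgt[:, t])
        assert np.allclose(lp, full[:, t, :], atol=1e-4)


@pytest.mark.parametrize("arch", ["seq2seq", "transformer"])
def test_checkpoint_roundtrip_bit_identical(arch, vocab, batch, tmp_path):
    src, tgt = batch
    model = build_model(small_cfg(arch), vocab)
    with no_grad():
        before = model.forward_teacher(src, tgt, train=False).data
    save_checkpoint(model, tmp_path / "ckpt", history=[{"step": 0}])
    loaded, history = load_checkpoint(tmp_path / "ckpt")
    assert history == [{"step": 0}]
    assert loaded.config == model.config
    with no_grad():
        after = loaded.forward_teacher(src, tgt, train=False).data
    assert np.array_equal(before, after)


def test_state_dict_shape_guard(vocab):
    m1 = build_transformer(small_cfg("transformer"), vocab)
    m2 = build_transformer(small_cfg("transformer", model_dim=32, ff_dim=64), vocab)
    with pytest.raises(ValueError):
        m1.load_state_dict(m2.state_dict())
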