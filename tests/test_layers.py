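"""Finite-difference gradient checks and behaviour tests for nn layers."""

import numpy as np
import pytest

from brainfuse import nn
from brainfuse.nn import layers as L
from brainfuse.nn.autograd import Tensor

from conftest import fd_check_params, to_float64


def _loss(module, x, weights):
    """Deterministic scalar probe touching every output element."""
    return (module(Tensor(x, requires_grad=True)) * Tensor(weights)).sum()


def _run_param_check(module, x, rng, **kw):
    to_float64(module)
    out = module(Tensor(x))
    weights = rng.normal(size=out.shape)
    module.zero_grad()
    _loss(module, x, weights).backward()
    fd_check_params(lambda: _loss(module, x, weights),
                    list(module.named_parameters()), rng, **kw)


def _run_input_check(module, x, rng, eps=1e-6, rtol=1e-5, atol=1e-8):
    to_float64(module)
    out = module(Tensor(x))
    weights = rng.normal(size=out.shape)
    xt = Tensor(x.copy(), requires_grad=True)
    (module(xt) * Tensor(weights)).sum().backward()
    num = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        xp = x.copy(); xp[idx] += eps
        xm = x.copy(); xm[idx] -= eps
        fp = (module(Tensor(xp)) * Tensor(weights)).sum().item()
        fm = (module(Tensor(xm)) * Tensor(weights)).sum().item()
        num[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    np.testing.assert_allclose(xt.grad, num, rtol=rtol, atol=atol)


def test_linear_grads(rng):
    lin = nn.Linear(5, 3, rng)
    x = rng.normal(size=(4, 5))
    _run_param_check(lin, x, rng)
    _run_input_check(lin, x, rng)


def test_conv3d_grads_im2col(rng):
    conv = nn.Conv3d(2, 3, 3, rng)
    x = rng.normal(size=(2, 2, 4, 5, 4))
    _run_param_check(conv, x, rng, rtol=3e-4)
    _run_input_check(conv, x, rng, rtol=1e-4, atol=1e-7)


def test_conv3d_grads_shift_accumulate(rng, monkeypatch):
    """Force the large-volume fallback path and check it agrees with FD."""
    monkeypatch.setattr(L, "_IM2COL_BYTE_LIMIT", 0)
    conv = nn.Conv3d(2, 3, 3, rng)
    x = rng.normal(size=(2, 2, 4, 5, 4))
    _run_param_check(conv, x, rng, rtol=3e-4)
    _run_input_check(conv, x, rng, rtol=1e-4, atol=1e-7)


def test_conv3d_paths_agree(rng, monkeypatch):
    conv = nn.Conv3d(1, 4, 3, rng)
    x = np.asarray(rng.normal(size=(3, 1, 6, 6, 6)), np.float32)
    out_gemm = conv(Tensor(x)).data
    monkeypatch.setattr(L, "_IM2COL_BYTE_LIMIT", 0)
    out_shift = conv(Tensor(x)).data
    np.testing.assert_allclose(out_gemm, out_shift, rtol=1e-5, atol=1e-6)


def test_conv3d_same_padding_shape(rng):
    conv = nn.Conv3d(1, 2, 3, rng)
    out = conv(Tensor(np.zeros((2, 1, 7, 8, 9))))
    assert out.shape == (2, 2, 7, 8, 9)


def test_conv1d_grads(rng):
    conv = nn.Conv1d(3, 4, 1, rng)
    x = rng.normal(size=(2, 3, 6))
    _run_param_check(conv, x, rng, rtol=3e-4)
    _run_input_check(conv, x, rng, rtol=1e-4, atol=1e-7)


def test_batchnorm_train_grads(rng):
    bn = nn.BatchNorm3d(3)
    x = rng.normal(size=(4, 3, 2, 3, 2))
    _run_param_check(bn, x, rng, rtol=3e-4, atol=1e-6)
    _run_input_check(bn, x, rng, rtol=1e-4, atol=1e-6)


def test_batchnorm_eval_grads(rng):
    bn = nn.BatchNorm3d(3)
    # give the running stats something non-trivial first
    bn(Tensor(rng.normal(size=(4, 3, 2, 2, 2)).astype(np.float32)))
    bn.eval()
    x = rng.normal(size=(2, 3, 2, 2, 2))
    _run_param_check(bn, x, rng, rtol=3e-4)
    _run_input_check(bn, x, rng, rtol=1e-4, atol=1e-7)


def test_batchnorm_normalizes_in_train_mode(rng):
    bn = nn.BatchNorm3d(2)
    x = rng.normal(2.0, 3.0, size=(8, 2, 3, 3, 3)).astype(np.float32)
    out = bn(Tensor(x)).data
    np.testing.assert_allclose(out.mean(axis=(0, 2, 3, 4)), 0.0, atol=1e-5)
    np.testing.assert_allclose(out.std(axis=(0, 2, 3, 4)), 1.0, atol=1e-3)


def test_batchnorm_eval_constant_input_is_finite():
    bn = nn.BatchNorm3d(2)
    bn.eval()
    out = bn(Tensor(np.zeros((3, 2, 2, 2, 2), dtype=np.float32)))
    assert np.all(np.isfinite(out.data))


def test_maxpool_shapes_and_values():
    pool = nn.MaxPool3d(2)
    x = np.arange(2 * 1 * 4 * 4 * 4, dtype=np.float64).reshape(2, 1, 4, 4, 4)
    out = pool(Tensor(x))
    assert out.shape == (2, 1, 2, 2, 2)
    # in each 2x2x2 window of this ramp, the max is the last corner
    assert out.data[0, 0, 0, 0, 0] == x[0, 0, 1, 1, 1]
    # odd trailing slices are cropped; size-1 dims pass through
    assert pool(Tensor(np.zeros((1, 1, 5, 3, 1)))).shape == (1, 1, 2, 1, 1)


def test_maxpool_grads(rng):
    pool = nn.MaxPool3d(2)
    x = rng.normal(size=(2, 2, 4, 4, 4))
    _run_input_check(pool, x, rng)


def test_maxpool_rejects_other_kernels():
    with pytest.raises(ValueError):
        nn.MaxPool3d(3)


def test_layernorm_grads(rng):
    ln = nn.LayerNorm(6)
    x = rng.normal(size=(3, 4, 6))
    _run_param_check(ln, x, rng, rtol=3e-4, atol=1e-6)
    _run_input_check(ln, x, rng, rtol=1e-4, atol=1e-6)


def test_layernorm_normalizes_last_axis(rng):
    ln = nn.LayerNorm(8)
    out = ln(Tensor(rng.normal(5.0, 2.0, size=(4, 8)))).data
    np.testing.assert_allclose(out.mean(axis=-1), 0.0, atol=1e-6)
    np.testing.assert_allclose(out.std(axis=-1), 1.0, atol=1e-3)


def test_dropout_train_and_eval(rng):
    drop = nn.Dropout(0.5, rng)
    x = np.ones((200, 50), dtype=np.float32)
    out = drop(Tensor(x)).data
    kept = out != 0
    assert 0.3 < kept.mean() < 0.7
    np.testing.assert_allclose(out[kept], 2.0)   # inverted scaling
    drop.eval()
    np.testing.assert_array_equal(drop(Tensor(x)).data, x)
    with pytest.raises(ValueError):
        nn.Dropout(1.0, rng)


def test_attention_grads(rng):
    attn = nn.MultiHeadSelfAttention(8, 2, rng)
    x = rng.normal(size=(2, 3, 8))
    _run_param_check(attn, x, rng, rtol=3e-4, atol=1e-6)
    _run_input_check(attn, x, rng, rtol=1e-4, atol=1e-6)


def test_attention_rows_sum_to_one(rng):
    attn = nn.MultiHeadSelfAttention(8, 2, rng)
    attn.record_attention = True
    attn(Tensor(rng.normal(size=(2, 5, 8)).astype(np.float32)))
    a = attn.last_attention
    assert a.shape == (2, 2, 5, 5)
    np.testing.assert_allclose(a.sum(axis=-1), 1.0, atol=1e-5)


def test_transformer_layer_grads(rng):
    layer = nn.TransformerEncoderLayer(8, 2, 16, 0.0, rng)
    x = rng.normal(size=(2, 3, 8))
    _run_param_check(layer, x, rng, rtol=5e-4, atol=1e-6)


def test_positional_encoding_properties():
    pe = nn.sinusoidal_positional_encoding(10, 8)
    assert pe.shape == (10, 8)
    np.testing.assert_allclose(pe[0, 0::2], 0.0)   # sin(0)
    np.testing.assert_allclose(pe[0, 1::2], 1.0)   # cos(0)
    assert np.all(np.abs(pe) <= 1.0 + 1e-6)
    with pytest.raises(ValueError):
        nn.sinusoidal_positional_encoding(4, 7)


def test_adam_matches_manual_update():
    p = nn.Parameter(np.array([1.0, -2.0], dtype=np.float32))
    opt = nn.Adam([p], lr=0.1, weight_decay=0.0)
    g = np.array([0.5, -1.5], dtype=np.float32)
    p.grad = g.copy()
    opt.step()
    # first step: mhat = g, vhat = g^2 -> update = lr * g/(|g|+eps)
    expected = np.array([1.0, -2.0]) - 0.1 * g / (np.abs(g) + 1e-8)
    np.testing.assert_allclose(p.data, expected, rtol=1e-6)
    assert p.data.dtype == np.float32


def test_adam_weight_decay_shrinks_weights():
    p = nn.Parameter(np.array([10.0], dtype=np.float32))
    opt = nn.Adam([p], lr=0.01, weight_decay=1.0)
    p.grad = np.zeros(1, dtype=np.float32)
    opt.step()
    assert p.data[0] < 10.0


def test_adam_state_roundtrip(rng):
    p = nn.Parameter(rng.normal(size=4).astype(np.float32))
    opt = nn.Adam([p], lr=0.05)
    p.grad = np.ones(4, dtype=np.float32)
    opt.step()
    state = opt.state_dict()
    opt2 = nn.Adam([p], lr=0.05)
    opt2.load_state_dict(state)
    assert opt2.t == opt.t
    np.testing.assert_array_equal(opt2._m[0], opt._m[0])


def test_module_state_dict_roundtrip(rng):
    lin = nn.Linear(3, 2, rng)
    state = lin.state_dict()
    lin2 = nn.Linear(3, 2, np.random.default_rng(999))
    lin2.load_state_dict(state)
    np.testing.assert_array_equal(lin.weight.data, lin2.weight.data)
    with pytest.raises(ValueError, match="shape mismatch"):
        nn.Linear(4, 2, rng).load_state_dict(state)
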