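"""Neural-network building blocks on top of the autograd core.

Layers follow the familiar module pattern: parameters are discovered by
attribute assignment, ``train()``/``eval()`` toggle batch-norm/dropout
behaviour, and ``state_dict``/``load_state_dict`` serialize weights by
dotted name.

The 3D convolution supports two equivalent execution paths: an im2col
path (one batched GEMM per layer, fastest at desk scale) and a
shift-accumulate path used automatically when the im2col buffer would be
large (e.g. full-resolution 96x128x96 volumes).
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Parameter, Tensor, concatenate, softmax

__all__ = [
    "Module", "ModuleList", "Linear", "Conv3d", "Conv1d", "BatchNorm3d",
    "MaxPool3d", "LayerNorm", "Dropout", "MultiHeadSelfAttention",
    "TransformerEncoderLayer", "sinusoidal_positional_encoding",
]

# im2col buffers above this many bytes fall back to shift-accumulate
_IM2COL_BYTE_LIMIT = 192 * 1024 * 1024


class Module:
    """Base class: tracks parameters/submodules and training mode."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, array):
        self._buffers[name] = name
        object.__setattr__(self, name, array)

    def parameters(self):
        yield from self._params.values()
        for mod in self._modules.values():
            yield from mod.parameters()

    def named_parameters(self, prefix=""):
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, mod in self._modules.items():
            yield from mod.named_parameters(prefix + mname + ".")

    def named_buffers(self, prefix=""):
        for name in self._buffers:
            yield prefix + name, getattr(self, name)
        for mname, mod in self._modules.items():
            yield from mod.named_buffers(prefix + mname + ".")

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        state = {("param." + n): p.data.copy() for n, p in self.named_parameters()}
        state.update({("buffer." + n): np.asarray(b).copy()
                      for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        for key, value in state.items():
            kind, name = key.split(".", 1)
            if kind == "param":
                if params[name].data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {name}: "
                        f"{params[name].data.shape} vs {value.shape}")
                params[name].data = value.copy()
            else:
                obj = self
                *path, leaf = name.split(".")
                for part in path:
                    obj = getattr(obj, part)
                object.__setattr__(obj, leaf, value.copy())

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._items = []
        for mod in modules:
            self.append(mod)

    def append(self, mod: Module):
        setattr(self, str(len(self._items)), mod)
        self._items.append(mod)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / math.sqrt(fan_in) if fan_in > 0 else 0.0
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(_kaiming_uniform(rng, (in_features, out_features), in_features))
        self.bias = Parameter(_kaiming_uniform(rng, (out_features,), in_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


def _conv3d_forward(x: np.ndarray, w: np.ndarray, pad: tuple):
    """Returns (out, cols_or_None, xp). Channels-first layout (B,C,D,H,W)."""
    B, Cin, D, H, W = x.shape
    Cout, _, k1, k2, k3 = w.shape
    p1, p2, p3 = pad
    xp = np.pad(x, ((0, 0), (0, 0), (p1, p1), (p2, p2), (p3, p3)))
    Do, Ho, Wo = D + 2 * p1 - k1 + 1, H + 2 * p2 - k2 + 1, W + 2 * p3 - k3 + 1
    n_off = k1 * k2 * k3
    col_bytes = B * Cin * n_off * Do * Ho * Wo * x.itemsize
    if col_bytes <= _IM2COL_BYTE_LIMIT:
        views = [xp[:, :, i:i + Do, j:j + Ho, l:l + Wo]
                 for i in range(k1) for j in range(k2) for l in range(k3)]
        cols = np.stack(views, axis=2).reshape(B, Cin * n_off, Do * Ho * Wo)
        w2 = w.reshape(Cout, Cin * n_off)
        out = np.matmul(w2, cols).reshape(B, Cout, Do, Ho, Wo)
        return out, cols, xp
    out = np.zeros((B, Do, Ho, Wo, Cout), dtype=x.dtype)
    for i in range(k1):
        for j in range(k2):
            for l in range(k3):
                view = xp[:, :, i:i + Do, j:j + Ho, l:l + Wo]
                out += np.tensordot(view, w[:, :, i, j, l], axes=([1], [1]))
    out = np.ascontiguousarray(np.moveaxis(out, -1, 1))
    return out, None, xp


def conv3d(x: Tensor, w: Tensor, bias: Tensor | None, pad: tuple) -> Tensor:
    out_data, cols, xp = _conv3d_forward(x.data, w.data, pad)
    B, Cin, D, H, W = x.data.shape
    Cout, _, k1, k2, k3 = w.data.shape
    Do, Ho, Wo = out_data.shape[2:]
    p1, p2, p3 = pad
    n_off = k1 * k2 * k3

    def grad_x(g):
        gxp = np.zeros_like(xp)
        if cols is not None:
            w2 = w.data.reshape(Cout, Cin * n_off)
            gcols = np.matmul(w2.T, g.reshape(B, Cout, -1))
            gcols = gcols.reshape(B, Cin, n_off, Do, Ho, Wo)
            o = 0
            for i in range(k1):
                for j in range(k2):
                    for l in range(k3):
                        gxp[:, :, i:i + Do, j:j + Ho, l:l + Wo] += gcols[:, :, o]
                        o += 1
        else:
            g_last = np.moveaxis(g, 1, -1)  # (B,Do,Ho,Wo,Cout)
            for i in range(k1):
                for j in range(k2):
                    for l in range(k3):
                        contrib = np.tensordot(g_last, w.data[:, :, i, j, l],
                                               axes=([4], [0]))  # (B,Do,Ho,Wo,Cin)
                        gxp[:, :, i:i + Do, j:j + Ho, l:l + Wo] += \
                            np.moveaxis(contrib, -1, 1)
        if p1 or p2 or p3:
            return gxp[:, :, p1:p1 + D, p2:p2 + H, p3:p3 + W]
        return gxp

    def grad_w(g):
        if cols is not None:
            gw = np.einsum("bon,bkn->ok", g.reshape(B, Cout, -1), cols)
            return gw.reshape(w.data.shape)
        gw = np.zeros_like(w.data)
        g_last = np.moveaxis(g, 1, -1)
        for i in range(k1):
            for j in range(k2):
                for l in range(k3):
                    view = xp[:, :, i:i + Do, j:j + Ho, l:l + Wo]
                    gw[:, :, i, j, l] = np.tensordot(
                        g_last, view, axes=([0, 1, 2, 3], [0, 2, 3, 4]))
        return gw

    links = [(x, grad_x), (w, grad_w)]
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, -1, 1, 1, 1)
        links.append((bias, lambda g: g.sum(axis=(0, 2, 3, 4))))
    return Tensor._make(out_data, links)


class Conv3d(Module):
    """3D convolution, stride 1, 'same' padding for odd kernels."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        k = kernel_size
        fan_in = in_channels * k ** 3
        self.weight = Parameter(_kaiming_uniform(
            rng, (out_channels, in_channels, k, k, k), fan_in))
        self.bias = Parameter(_kaiming_uniform(rng, (out_channels,), fan_in))
        self.pad = (k // 2, k // 2, k // 2)

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, self.pad)


def conv1d(x: Tensor, w: Tensor, bias: Tensor | None, pad: int) -> Tensor:
    """1D convolution over the last axis; x (B,C,T), w (Cout,Cin,k)."""
    B, Cin, T = x.data.shape
    Cout, _, k = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    To = T + 2 * pad - k + 1
    views = [xp[:, :, i:i + To] for i in range(k)]
    cols = np.stack(views, axis=2).reshape(B, Cin * k, To)
    w2 = w.data.reshape(Cout, Cin * k)
    out = np.matmul(w2, cols)

    def grad_x(g):
        gcols = np.matmul(w2.T, g).reshape(B, Cin, k, To)
        gxp = np.zeros_like(xp)
        for i in range(k):
            gxp[:, :, i:i + To] += gcols[:, :, i]
        return gxp[:, :, pad:pad + T] if pad else gxp

    def grad_w(g):
        return np.einsum("bot,bkt->ok", g, cols).reshape(w.data.shape)

    links = [(x, grad_x), (w, grad_w)]
    if bias is not None:
        out = out + bias.data.reshape(1, -1, 1)
        links.append((bias, lambda g: g.sum(axis=(0, 2))))
    return Tensor._make(out, links)


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        fan_in = in_channels * kernel_size
        self.weight = Parameter(_kaiming_uniform(
            rng, (out_channels, in_channels, kernel_size), fan_in))
        self.bias = Parameter(_kaiming_uniform(rng, (out_channels,), fan_in))
        self.pad = kernel_size // 2

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, self.pad)


class BatchNorm3d(Module):
    """Batch normalization over (B, spatial) per channel, with running stats.

    Running statistics are frozen at inference, so constant (even all-zero)
    inputs stay finite in eval mode.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_var", np.ones(num_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        # fused forward/backward: far fewer large-array passes than the
        # equivalent composition of elementwise autograd ops
        shape = (1, -1) + (1,) * (x.ndim - 2)
        axes = (0,) + tuple(range(2, x.ndim))
        xd = x.data
        gamma, beta = self.weight, self.bias
        if self.training:
            m = float(np.prod([xd.shape[a] for a in axes]))
            mu = xd.mean(axis=axes)
            xc = xd - mu.reshape(shape)
            var = np.mean(xc * xc, axis=axes)
            mom = self.momentum
            self.running_mean = ((1 - mom) * self.running_mean
                                 + mom * mu.astype(np.float32))
            self.running_var = ((1 - mom) * self.running_var
                                + mom * var.astype(np.float32))
            invstd = (1.0 / np.sqrt(var + self.eps)).astype(xd.dtype)
            xhat = xc * invstd.reshape(shape)
            out = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)

            def grad_x(g):
                dxhat = g * gamma.data.reshape(shape)
                s1 = dxhat.sum(axis=axes)
                s2 = (dxhat * xhat).sum(axis=axes)
                return (invstd.reshape(shape) / m) * (
                    m * dxhat - s1.reshape(shape) - xhat * s2.reshape(shape))

            links = [
                (x, grad_x),
                (gamma, lambda g: (g * xhat).sum(axis=axes)),
                (beta, lambda g: g.sum(axis=axes)),
            ]
            return Tensor._make(out, links)
        invstd = (1.0 / np.sqrt(self.running_var + self.eps)).astype(xd.dtype)
        scale = (gamma.data * invstd).reshape(shape)
        shift = (beta.data - gamma.data * invstd * self.running_mean).reshape(shape)
        out = xd * scale + shift
        xhat_needed = gamma.requires_grad

        def grad_x_eval(g):
            return g * scale

        links = [(x, grad_x_eval)]
        if xhat_needed:
            links += [
                (gamma, lambda g: (g * (xd - self.running_mean.reshape(shape))
                                   * invstd.reshape(shape)).sum(axis=axes)),
                (beta, lambda g: g.sum(axis=axes)),
            ]
        return Tensor._make(out, links)


class MaxPool3d(Module):
    """Non-overlapping max pooling; trailing odd slices are cropped, and
    dimensions of size 1 are passed through unchanged."""

    def __init__(self, kernel_size: int = 2):
        super().__init__()
        if kernel_size != 2:
            raise ValueError("only kernel_size=2 pooling is supported")

    def forward(self, x: Tensor) -> Tensor:
        # fused forward/backward via argmax over gathered 2x2x2 windows
        B, C, D, H, W = x.shape

        def eff(n):  # (cropped length, window)
            return (n // 2 * 2, 2) if n >= 2 else (n, 1)

        (dc, kd), (hc, kh), (wc, kw) = eff(D), eff(H), eff(W)
        Do, Ho, Wo = dc // kd, hc // kh, wc // kw
        K = kd * kh * kw
        windows = np.ascontiguousarray(
            x.data[:, :, :dc, :hc, :wc]
            .reshape(B, C, Do, kd, Ho, kh, Wo, kw)
            .transpose(0, 1, 2, 4, 6, 3, 5, 7)
        ).reshape(B, C, Do, Ho, Wo, K)
        idx = windows.argmax(axis=-1)
        out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

        def grad_fn(g):
            gw = np.zeros_like(windows)
            np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
            gx = np.zeros_like(x.data)
            gx[:, :, :dc, :hc, :wc] = (
                gw.reshape(B, C, Do, Ho, Wo, kd, kh, kw)
                .transpose(0, 1, 2, 5, 3, 6, 4, 7)
                .reshape(B, C, dc, hc, wc))
            return gx

        return Tensor._make(out, [(x, grad_fn)])


class LayerNorm(Module):
    """Normalization over the last axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim, dtype=np.float32))
        self.bias = Parameter(np.zeros(dim, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        xhat = (x - mu) / (var + self.eps).sqrt()
        return xhat * self.weight + self.bias


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(x.dtype)
        return x * Tensor(keep / (1.0 - self.p))


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over a token axis.

    When ``record_attention`` is set, the most recent softmax attention
    matrices (batch, heads, tokens, tokens) are kept on ``last_attention``
    for inspection.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)
        self.record_attention = False
        self.last_attention = None

    def _split(self, t: Tensor, B: int, T: int) -> Tensor:
        return t.reshape(B, T, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        q = self._split(self.wq(x), B, T)
        k = self._split(self.wk(x), B, T)
        v = self._split(self.wv(x), B, T)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.d_head))
        attn = softmax(scores, axis=-1)
        if self.record_attention:
            self.last_attention = attn.data.copy()
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, self.d_model)
        return self.wo(out)


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: attention and feed-forward sublayers with
    residual connections and layer normalization."""

    def __init__(self, d_model: int, n_heads: int, dim_feedforward: int,
                 dropout: float, rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, dim_feedforward, rng)
        self.ff2 = Linear(dim_feedforward, d_model, rng)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.ln1(x + self.drop1(self.attn(x)))
        x = self.ln2(x + self.drop2(self.ff2(self.ff1(x).relu())))
        return x


def sinusoidal_positional_encoding(n_positions: int, d_model: int) -> np.ndarray:
    """Standard sin/cos positional table of shape (n_positions, d_model)."""
    if d_model % 2 != 0:
        raise ValueError("d_model must be even for sinusoidal encoding")
    pos = np.arange(n_positions, dtype=np.float64)[:, None]
    i = np.arange(d_model // 2, dtype=np.float64)[None, :]
    angle = pos / np.power(10000.0, 2 * i / d_model)
    pe = np.zeros((n_positions, d_model), dtype=np.float32)
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe
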