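"""Per-modality deep feature extractors.

Two branch families, each emitting a 64-dimensional feature vector per
subject:

* :class:`SFCN` — a simple fully convolutional network for 3D structural
  maps: five blocks of [3x3x3 conv -> batch norm -> 2x2x2 max pool ->
  ReLU] with channel widths (32, 64, 128, 256, 256) by default, then a
  head of [1x1x1 conv to 64 channels -> batch norm -> ReLU -> average
  pooling]. With ``final_pool="fixed(3,4,3)"`` the head expects the
  canonical 96x128x96 input whose five halvings leave a 3x4x3 grid;
  ``"global"`` (the default) averages whatever grid remains, so smaller
  desk-scale volumes work identically.

* :class:`MEGEncoder` — treats each brain region's power spectrum as one
  token: a linear projection of the frequency bins to ``d_model``,
  optional sinusoidal positional encoding, a Transformer encoder
  self-attending over regions, two 1D convolutions over the region axis
  (channels 128 then 32, kernel size 1), average pooling over regions and
  a fully connected map to 64 features. PSD values are log-transformed
  and z-scored per region before encoding.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.autograd import Tensor

__all__ = ["SFCNConfig", "MEGEncoderConfig", "SFCN", "MEGEncoder",
           "FEATURE_DIM"]

FEATURE_DIM = 64  # every branch emits this many features per subject


@dataclass(frozen=True)
class SFCNConfig:
    conv_channels: tuple = (32, 64, 128, 256, 256)
    conv_kernel: int = 3
    pool_kernel: int = 2
    head_channels: int = FEATURE_DIM
    final_pool: str = "global"   # or "fixed(3,4,3)"

    def __post_init__(self):
        if len(self.conv_channels) != 5:
            raise ValueError(
                f"conv_channels must have 5 entries, got {len(self.conv_channels)}")
        if self.head_channels != FEATURE_DIM:
            raise ValueError(f"head_channels must be {FEATURE_DIM}")
        if self.final_pool != "global" and self.fixed_pool_shape() is None:
            raise ValueError(f"unrecognized final_pool {self.final_pool!r}")

    def fixed_pool_shape(self):
        m = re.fullmatch(r"fixed\((\d+),(\d+),(\d+)\)", self.final_pool)
        return tuple(int(g) for g in m.groups()) if m else None


@dataclass(frozen=True)
class MEGEncoderConfig:
    d_model: int = 64
    n_heads: int = 4
    n_layers: int = 2
    conv_channels: tuple = (128, 32)
    conv_kernel: int = 1
    fc_out: int = FEATURE_DIM
    dropout: float = 0.1
    dim_feedforward: int = 128
    positional_encoding: bool = True
    log_zscore: bool = True

    def __post_init__(self):
        if len(self.conv_channels) != 2:
            raise ValueError("conv_channels must have 2 entries")
        if self.fc_out != FEATURE_DIM:
            raise ValueError(f"fc_out must be {FEATURE_DIM}")


class SFCN(nn.Module):
    """Simple fully convolutional network for 3D maps -> 64 features."""

    def __init__(self, config: SFCNConfig, rng: np.random.Generator,
                 in_channels: int = 1):
        super().__init__()
        self.config = config
        blocks = []
        prev = in_channels
        for ch in config.conv_channels:
            block = nn.Module()
            block.conv = nn.Conv3d(prev, ch, config.conv_kernel, rng)
            block.bn = nn.BatchNorm3d(ch)
            block.pool = nn.MaxPool3d(config.pool_kernel)
            blocks.append(block)
            prev = ch
        self.blocks = nn.ModuleList(blocks)
        self.head_conv = nn.Conv3d(prev, config.head_channels, 1, rng)
        self.head_bn = nn.BatchNorm3d(config.head_channels)

    def _check_input(self, shape):
        fixed = self.config.fixed_pool_shape()
        if fixed is None:
            return
        spatial = shape[2:]
        for axis, dim in enumerate(spatial):
            if dim < 2 ** len(self.config.conv_channels):
                raise ValueError(
                    f"spatial dim {axis} has size {dim} < 32; fixed final "
                    f"pooling requires every dim >= 2^5")
        expected = tuple(d // 2 ** len(self.config.conv_channels)
                         for d in spatial)
        if expected != fixed:
            raise ValueError(
                f"fixed final pool {fixed} incompatible with input spatial "
                f"shape {tuple(spatial)}: pre-head grid would be {expected}")

    def forward(self, volumes) -> Tensor:
        """volumes: array or Tensor of shape (batch, 1, D, H, W) -> (batch, 64)."""
        x = volumes if isinstance(volumes, Tensor) else Tensor(
            np.asarray(volumes, dtype=np.float32))
        if x.ndim != 5:
            raise ValueError(f"expected (batch, channels, D, H, W), got {x.shape}")
        self._check_input(x.shape)
        for block in self.blocks:
            x = block.pool(block.bn(block.conv(x))).relu()
        x = self.head_bn(self.head_conv(x)).relu()
        feats = x.mean(axis=(2, 3, 4))   # average pool over remaining grid
        return feats


def log_zscore_psd(psd: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Log-power z-scored per region across frequency bins."""
    logp = np.log(np.maximum(psd, eps))
    mu = logp.mean(axis=-1, keepdims=True)
    sd = logp.std(axis=-1, keepdims=True)
    return (logp - mu) / (sd + eps)


class MEGEncoder(nn.Module):
    """Transformer-encoder branch for (regions x frequency-bins) PSD -> 64."""

    def __init__(self, config: MEGEncoderConfig, n_bins: int,
                 rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.n_bins = n_bins
        self.input_proj = nn.Linear(n_bins, config.d_model, rng)
        self.layers = nn.ModuleList([
            nn.TransformerEncoderLayer(config.d_model, config.n_heads,
                                       config.dim_feedforward, config.dropout, rng)
            for _ in range(config.n_layers)])
        c1, c2 = config.conv_channels
        self.conv1 = nn.Conv1d(config.d_model, c1, config.conv_kernel, rng)
        self.conv2 = nn.Conv1d(c1, c2, config.conv_kernel, rng)
        self.fc = nn.Linear(c2, config.fc_out, rng)
        self._pe_cache: dict = {}

    def set_record_attention(self, flag: bool):
        for layer in self.layers:
            layer.attn.record_attention = flag

    def attention_matrices(self):
        """Most recent per-layer attention, list of (B, heads, R, R) arrays."""
        return [layer.attn.last_attention for layer in self.layers]

    def forward(self, psd) -> Tensor:
        """psd: (batch, regions, bins) -> (batch, 64)."""
        arr = psd.data if isinstance(psd, Tensor) else np.asarray(
            psd, dtype=np.float32)
        if arr.ndim != 3:
            raise ValueError(f"expected (batch, regions, bins), got {arr.shape}")
        B, R, F = arr.shape
        if R < 2:
            raise ValueError(
                f"attention needs at least 2 regions, got {R}")
        if F != self.n_bins:
            raise ValueError(f"encoder built for {self.n_bins} bins, got {F}")
        if self.config.log_zscore:
            arr = log_zscore_psd(arr).astype(np.float32)
        x = self.input_proj(Tensor(arr))
        if self.config.positional_encoding:
            if R not in self._pe_cache:
                self._pe_cache[R] = nn.sinusoidal_positional_encoding(
                    R, self.config.d_model)
            x = x + Tensor(self._pe_cache[R][None])
        for layer in self.layers:
            x = layer(x)
        # 1D convolutions over the region axis: (B, R, d) -> (B, d, R)
        x = x.transpose(0, 2, 1)
        x = self.conv1(x).relu()
        x = self.conv2(x).relu()
        x = x.mean(axis=2)            # average pool over regions
        return self.fc(x)
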