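"""Multimodal feature fusion: outer-product tensor fusion and its low-rank form.

Given per-modality feature vectors ``z_1 .. z_M``, tensor fusion forms the
outer product ``Z = z_1' ⊗ ... ⊗ z_M'`` (each ``z_m' = [z_m; 1]`` when
``append_one`` — the constant slot preserves unimodal and lower-order
interaction terms) and maps it linearly to the fused representation
``h_k = <W_k, Z> + b_k``. Materializing ``Z`` costs ``prod_m d_m'``
parameters per output unit, so the model uses the standard low-rank
factorization of the weight tensor,

    W_k = sum_{i=1}^{r} F_1^(i)[:, k] ⊗ ... ⊗ F_M^(i)[:, k],

under which the fused vector is computed without ever building ``Z``:

    h = sum_{i=1}^{r}  (F_1^(i)T z_1') * ... * (F_M^(i)T z_M')  + b,

with ``*`` elementwise over the output axis. The dense route
(:func:`full_tensor_fusion`) is kept as the exact oracle the factorized
route is tested against; :class:`LowRankFusionLayer` is the trainable form.

Add and Concat baselines are included for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.autograd import Tensor

__all__ = [
    "LowRankFactors", "append_one", "full_tensor_fusion", "low_rank_fusion",
    "reconstruct_dense_weight", "random_low_rank_factors", "add_fusion",
    "concat_fusion", "lowrank_parameter_count", "LowRankFusionLayer",
]


@dataclass
class LowRankFactors:
    """Per-modality factor stacks parameterizing the fused-layer weight.

    ``factors[m]`` has shape ``(rank, d_m', d_out)`` where ``d_m'`` includes
    the appended constant slot when ``append_one`` is used.
    """

    factors: list          # M arrays of shape (rank, d_m', d_out)
    bias: np.ndarray       # (d_out,)

    def __post_init__(self):
        if len(self.factors) < 2:
            raise ValueError("need factor stacks for at least 2 modalities")
        ranks = {f.shape[0] for f in self.factors}
        douts = {f.shape[2] for f in self.factors}
        if len(ranks) != 1 or len(douts) != 1:
            raise ValueError("all factor stacks must share (rank, d_out)")
        if self.rank < 1:
            raise ValueError(f"rank must be >= 1, got {self.rank}")
        if self.bias.shape != (self.d_out,):
            raise ValueError("bias length must equal d_out")

    @property
    def rank(self) -> int:
        return int(self.factors[0].shape[0])

    @property
    def d_out(self) -> int:
        return int(self.factors[0].shape[2])


def _validate_inputs(features) -> list:
    feats = [np.asarray(z, dtype=np.float64) for z in features]
    if len(feats) < 2:
        raise ValueError(f"fusion needs at least 2 modalities, got {len(feats)}")
    for i, z in enumerate(feats):
        if z.ndim != 1:
            raise ValueError(f"modality {i}: expected a 1D feature vector")
        if not np.all(np.isfinite(z)):
            raise ValueError(f"modality {i}: non-finite feature values")
    return feats


def append_one(z: np.ndarray) -> np.ndarray:
    return np.concatenate([z, np.ones(1, dtype=z.dtype)])


def full_tensor_fusion(features, weight: np.ndarray, bias: np.ndarray,
                       append_ones: bool = True) -> np.ndarray:
    """Dense outer-product fusion: the exact (oracle) route.

    ``weight`` has shape ``(d_out, d_1', ..., d_M')``; the fused output is
    ``h_k = <W_k, Z> + b_k`` with ``Z`` the full outer-product tensor.
    """
    feats = _validate_inputs(features)
    if append_ones:
        feats = [append_one(z) for z in feats]
    dims = tuple(z.shape[0] for z in feats)
    if weight.shape[1:] != dims:
        raise ValueError(
            f"weight trailing dims {weight.shape[1:]} do not match "
            f"(1-appended) feature dims {dims}")
    tensor = feats[0]
    for z in feats[1:]:
        tensor = np.multiply.outer(tensor, z)
    h = weight.reshape(weight.shape[0], -1) @ tensor.reshape(-1)
    return h + np.asarray(bias, dtype=h.dtype)


def low_rank_fusion(features, factors: LowRankFactors,
                    append_ones: bool = True) -> np.ndarray:
    """Factorized fusion; never materializes the outer-product tensor."""
    feats = _validate_inputs(features)
    if len(feats) != len(factors.factors):
        raise ValueError(
            f"{len(feats)} modalities but {len(factors.factors)} factor stacks")
    if append_ones:
        feats = [append_one(z) for z in feats]
    prod = None
    for z, fm in zip(feats, factors.factors):
        if fm.shape[1] != z.shape[0]:
            raise ValueError(
                f"factor dim {fm.shape[1]} does not match feature dim {z.shape[0]}")
        proj = np.einsum("d,rdo->ro", z, fm)   # (rank, d_out)
        prod = proj if prod is None else prod * proj
    return prod.sum(axis=0) + factors.bias


def reconstruct_dense_weight(factors: LowRankFactors) -> np.ndarray:
    """Expand the factorization into the dense weight of the oracle route,
    shape ``(d_out, d_1', ..., d_M')``."""
    dims = [f.shape[1] for f in factors.factors]
    d_out, r = factors.d_out, factors.rank
    weight = np.zeros((d_out, *dims))
    for k in range(d_out):
        for i in range(r):
            term = factors.factors[0][i, :, k]
            for fm in factors.factors[1:]:
                term = np.multiply.outer(term, fm[i, :, k])
            weight[k] += term
    return weight


def random_low_rank_factors(dims, d_out: int, rank: int,
                            rng: np.random.Generator,
                            scale: float | None = None) -> LowRankFactors:
    """Random factors; ``dims`` are the (already 1-appended, if applicable)
    per-modality input dims."""
    factors = []
    for d in dims:
        s = scale if scale is not None else 1.0 / np.sqrt(d)
        factors.append(rng.normal(0.0, s, size=(rank, d, d_out)))
    return LowRankFactors(factors, np.zeros(d_out))


def add_fusion(features) -> np.ndarray:
    """Elementwise sum of the modality vectors (lengths must agree)."""
    feats = _validate_inputs(features)
    lengths = {z.shape[0] for z in feats}
    if len(lengths) != 1:
        raise ValueError(f"add fusion needs equal lengths, got {sorted(lengths)}")
    return np.sum(feats, axis=0)


def concat_fusion(features) -> np.ndarray:
    """Concatenation in the given modality order."""
    feats = _validate_inputs(features)
    return np.concatenate(feats)


def lowrank_parameter_count(rank: int, d_out: int, feature_dims,
                            append_ones: bool = True) -> int:
    """Trainable parameters of the low-rank layer:
    ``rank * d_out * sum(d_m + 1) + d_out`` with the appended constant."""
    extra = 1 if append_ones else 0
    return rank * d_out * sum(d + extra for d in feature_dims) + d_out


class LowRankFusionLayer(nn.Module):
    """Trainable low-rank fusion of M batched feature matrices.

    Applies dropout (rate ``drop_rate``) to each modality's features at
    train time, appends the constant slot, projects each modality through
    its rank-r factor stack, multiplies the per-rank projections
    elementwise and sums over ranks.
    """

    def __init__(self, feature_dims, d_out: int, rank: int,
                 rng: np.random.Generator, drop_rate: float = 0.1,
                 append_ones: bool = True):
        super().__init__()
        if rank < 1:
            raise ValueError(f"rank must be >= 1, got {rank}")
        self.feature_dims = tuple(int(d) for d in feature_dims)
        self.d_out = d_out
        self.rank = rank
        self.append_ones = append_ones
        self.drops = nn.ModuleList([nn.Dropout(drop_rate, rng)
                                    for _ in self.feature_dims])
        self._factor_params = []
        for m, d in enumerate(self.feature_dims):
            dprime = d + (1 if append_ones else 0)
            # variance 1/d' keeps each rank-term projection O(1); the
            # constant slot starts at unity so every projection begins at
            # 1 + z.W and the M-way product is near-linear in the features
            # at init -- gradients then flow as in an additive layer
            # instead of being gated by products of zero-mean terms
            init = rng.normal(0.0, 1.0 / np.sqrt(dprime),
                              size=(dprime, rank * d_out))
            if append_ones:
                init[-1] = 1.0
            fm = nn.Parameter(init)
            setattr(self, f"factor_{m}", fm)
            self._factor_params.append(fm)
        self.bias = nn.Parameter(np.zeros(d_out, dtype=np.float32))

    def forward(self, features: list) -> Tensor:
        if len(features) != len(self.feature_dims):
            raise ValueError(
                f"expected {len(self.feature_dims)} modalities, got {len(features)}")
        prod = None
        for z, fm, drop in zip(features, self._factor_params, self.drops):
            B = z.shape[0]
            z = drop(z)
            if self.append_ones:
                z = nn.concatenate([z, Tensor(np.ones((B, 1), dtype=z.dtype))],
                                   axis=1)
            proj = (z @ fm).reshape(B, self.rank, self.d_out)
            prod = proj if prod is None else prod * proj
        return prod.sum(axis=1) + self.bias

    def to_factors(self) -> LowRankFactors:
        """Export the trained factors in oracle layout (rank, d', d_out)."""
        factors = [np.ascontiguousarray(
            fm.data.reshape(fm.data.shape[0], self.rank, self.d_out)
            .transpose(1, 0, 2)).astype(np.float64)
            for fm in self._factor_params]
        return LowRankFactors(factors, self.bias.data.astype(np.float64))
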