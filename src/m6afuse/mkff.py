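"""Multi-kernel feature fusion (MKFF).

The encoded batch is embedded (padding code 0 maps to a frozen all-zero
vector) and projected point-wise to ``out_channel`` channels (O_embed).
Four parallel paths then read O_embed at different receptive fields:

    k1 = Conv1(O_embed)
    k2 = Conv3(Conv1(O_embed))         (point-wise bottleneck first)
    k3 = Conv5(Conv1(O_embed))
    k4 = Conv1(MaxPool3(O_embed))      (stride-1, length-preserving pool)

Each path emits out_channel/4 channels; their concatenation is fused
point-wise to MK_Fea.  Global-local dynamic fusion (GLDF) then weights
MK_Fea two ways: a global channel gate (average-pool over positions, a
1-channel convolution across the channel axis with adaptive kernel size
k_adp, sigmoid) and a local spatial map (squeeze/excitation convolutions
along positions with softmax over positions per channel).  The two
weighted maps are concatenated, fused point-wise, and added residually to
O_embed to give O_MKFF.  Every stage preserves the position count L_max.

Ablation variants are pure configuration: ``fusion_mode`` in
{gldf, cat, add, global, local} and ``kernel_combo`` subsets of
{k1, k2, k3, k4}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .config import ConfigError, ModelConfig
from .io_encoding import EncodedBatch


@dataclass
class FeatureMap:
    """Rank-3 feature array (batch x channels x positions) with a stage tag."""

    values: np.ndarray
    stage: str

    def __post_init__(self):
        if self.values.ndim != 3:
            raise ValueError("FeatureMap requires a rank-3 array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in stage {self.stage!r}")


@dataclass
class AttentionWeights:
    """Global channel gate (sigmoid range) and local spatial map (softmax)."""

    global_w: np.ndarray | None  # (batch, C, 1), entries in (0, 1)
    local_w: np.ndarray | None  # (batch, C, L), normalized along softmax axis


def adaptive_kernel_size(C: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Channel-adaptive attention kernel width.

    k_adp is the largest odd integer not exceeding |log2(C)/gamma +
    b/gamma| (ECA convention), floored at 1.  For the defaults gamma=2,
    b=1: C=128 gives 3, C=1024 gives 5.
    """
    if C < 1:
        raise ValueError("channel count must be >= 1")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    t = abs(math.log2(C) / gamma + b / gamma)
    k = int(math.floor(t))
    if k % 2 == 0:
        k -= 1
    return max(k, 1)


class EmbedProject(nn.Module):
    """Embedding lookup + point-wise projection producing O_embed."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        dtype = config.np_dtype
        gain = config.init_gain
        self.embedding = nn.Embedding(config.vocab, config.embed_dim, rng=rng, dtype=dtype, gain=gain)
        self.project = nn.Conv1d(config.embed_dim, config.out_channel, 1, rng=rng, dtype=dtype, gain=gain)

    def __call__(self, codes: np.ndarray, taps: dict | None = None) -> ad.Tensor:
        emb = self.embedding(codes)  # (B, embed_dim, L)
        if taps is not None:
            taps["embedding"] = emb
        return self.project(emb)


class MultiKernelExtract(nn.Module):
    """The four parallel receptive-field paths (k1..k4)."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        if config.out_channel % 4 != 0:
            raise ConfigError("out_channel must be divisible by 4")
        dtype = config.np_dtype
        c, c4 = config.out_channel, config.out_channel // 4
        self.pool_kernel = config.pool_kernel
        gain = config.init_gain
        self.k1 = nn.Conv1d(c, c4, 1, rng=rng, dtype=dtype, gain=gain)
        self.k2_bottleneck = nn.Conv1d(c, c4, 1, rng=rng, dtype=dtype, gain=gain)
        self.k2 = nn.Conv1d(c4, c4, 3, pad=1, rng=rng, dtype=dtype, gain=gain)
        self.k3_bottleneck = nn.Conv1d(c, c4, 1, rng=rng, dtype=dtype, gain=gain)
        self.k3 = nn.Conv1d(c4, c4, 5, pad=2, rng=rng, dtype=dtype, gain=gain)
        self.k4 = nn.Conv1d(c, c4, 1, rng=rng, dtype=dtype, gain=gain)

    def __call__(self, o_embed: ad.Tensor) -> dict[str, ad.Tensor]:
        relu = ad.relu
        k1 = relu(self.k1(o_embed))
        k2 = relu(self.k2(relu(self.k2_bottleneck(o_embed))))
        k3 = relu(self.k3(relu(self.k3_bottleneck(o_embed))))
        pooled = ad.maxpool1d(o_embed, kernel=self.pool_kernel, stride=1,
                              pad=self.pool_kernel // 2)
        k4 = relu(self.k4(pooled))
        return {"k1": k1, "k2": k2, "k3": k3, "k4": k4}


class ConcatFuse(nn.Module):
    """Channel concatenation of selected paths + point-wise fusion (MK_Fea)."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.combo = tuple(config.kernel_combo)
        in_ch = (config.out_channel // 4) * len(self.combo)
        self.fuse = nn.Conv1d(in_ch, config.out_channel, 1, rng=rng, dtype=config.np_dtype,
                              gain=config.init_gain)

    def __call__(self, paths: dict[str, ad.Tensor], taps: dict | None = None) -> ad.Tensor:
        cat = ad.concat([paths[name] for name in self.combo], axis=1)
        if taps is not None:
            taps["mkc"] = cat
        return ad.relu(self.fuse(cat))


class GlobalChannelFusion(nn.Module):
    """Global channel gate: average pool, cross-channel conv, sigmoid."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        k = adaptive_kernel_size(config.out_channel, config.gamma, config.b)
        self.k_adp = k
        # single-channel convolution sliding across the channel axis
        self.conv = nn.Conv1d(1, 1, k, pad=k // 2, rng=rng, dtype=config.np_dtype,
                              gain=config.init_gain)

    def __call__(self, mk_fea: ad.Tensor) -> tuple[ad.Tensor, ad.Tensor]:
        profile = ad.mean(mk_fea, axis=2)  # (B, C)
        as_seq = ad.reshape(profile, (profile.shape[0], 1, profile.shape[1]))
        weight = ad.sigmoid(self.conv(as_seq))  # (B, 1, C)
        weight = ad.reshape(weight, (weight.shape[0], weight.shape[2], 1))  # (B, C, 1)
        return weight, mk_fea * weight


class LocalSpatialFusion(nn.Module):
    """Local spatial map via a squeeze/excitation bottleneck + softmax."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        c, r = config.out_channel, config.reduction_ratio
        if c % r != 0:
            raise ConfigError("out_channel must be divisible by reduction_ratio")
        k = adaptive_kernel_size(c, config.gamma, config.b)
        self.k_adp = k
        dtype = config.np_dtype
        gain = config.init_gain
        self.squeeze = nn.Conv1d(c, c // r, k, pad=k // 2, rng=rng, dtype=dtype, gain=gain)
        self.excitation = nn.Conv1d(c // r, c, k, pad=k // 2, rng=rng, dtype=dtype, gain=gain)
        self.softmax_axis = 2 if config.softmax_axis == "positions" else 1

    def __call__(self, mk_fea: ad.Tensor) -> tuple[ad.Tensor, ad.Tensor]:
        squeezed = self.squeeze(mk_fea)
        logits = self.excitation(squeezed)
        weight = ad.softmax(logits, axis=self.softmax_axis)
        return weight, mk_fea * weight


class GLDFCombine(nn.Module):
    """Combine the weighted maps and close the residual to O_embed."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.mode = config.fusion_mode
        c = config.out_channel
        in_ch = {"gldf": 2 * c, "add": c, "global": c, "local": c}.get(self.mode)
        self.combine = (
            nn.Conv1d(in_ch, c, 1, rng=rng, dtype=config.np_dtype, gain=config.init_gain)
            if in_ch is not None else None
        )

    def __call__(self, global_fea, local_fea, mk_fea, o_embed) -> ad.Tensor:
        if self.mode == "cat":
            gldf = mk_fea  # plain concatenation variant: Eq-6 output passes through
        elif self.mode == "add":
            gldf = ad.relu(self.combine(global_fea + local_fea))
        elif self.mode == "global":
            gldf = ad.relu(self.combine(global_fea))
        elif self.mode == "local":
            gldf = ad.relu(self.combine(local_fea))
        else:  # gldf
            gldf = ad.relu(self.combine(ad.concat([global_fea, local_fea], axis=1)))
        return o_embed + gldf


class MKFF(nn.Module):
    """Full multi-kernel feature fusion stack: codes -> O_MKFF."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        self.embed = EmbedProject(config, rng)
        self.extract = MultiKernelExtract(config, rng)
        self.concat_fuse = ConcatFuse(config, rng)
        self.needs_global = config.fusion_mode in ("gldf", "add", "global")
        self.needs_local = config.fusion_mode in ("gldf", "add", "local")
        self.global_fusion = GlobalChannelFusion(config, rng) if self.needs_global else None
        self.local_fusion = LocalSpatialFusion(config, rng) if self.needs_local else None
        self.gldf = GLDFCombine(config, rng)

    def __call__(self, codes: np.ndarray, taps: dict | None = None) -> ad.Tensor:
        o_embed = self.embed(codes, taps=taps)
        paths = self.extract(o_embed)
        mk_fea = self.concat_fuse(paths, taps=taps)
        global_fea = local_fea = None
        if self.needs_global:
            gw, global_fea = self.global_fusion(mk_fea)
            if taps is not None:
                taps["global_weight"] = gw
        if self.needs_local:
            lw, local_fea = self.local_fusion(mk_fea)
            if taps is not None:
                taps["local_weight"] = lw
        o_mkff = self.gldf(global_fea, local_fea, mk_fea, o_embed)
        if taps is not None:
            taps["o_embed"] = o_embed
            taps["mk_fea"] = mk_fea
            taps["o_mkff"] = o_mkff
        return o_mkff


# -- functional wrappers exposing the staged API -----------------------


def embed_project(batch: EncodedBatch, config: ModelConfig, params: EmbedProject) -> FeatureMap:
    with ad.no_grad():
        return FeatureMap(params(batch.codes).data, "O_embed")


def multi_kernel_extract(o_embed: FeatureMap, config: ModelConfig,
                         params: MultiKernelExtract) -> tuple[FeatureMap, ...]:
    with ad.no_grad():
        paths = params(ad.Tensor(o_embed.values))
    return tuple(FeatureMap(paths[k].data, k) for k in ("k1", "k2", "k3", "k4"))


def concat_fuse(paths: dict[str, FeatureMap], config: ModelConfig,
                params: ConcatFuse) -> FeatureMap:
    with ad.no_grad():
        out = params({k: ad.Tensor(v.values) for k, v in paths.items()})
    return FeatureMap(out.data, "MK_Fea")


def global_channel_fusion(mk_fea: FeatureMap, config: ModelConfig,
                          params: GlobalChannelFusion) -> tuple[np.ndarray, FeatureMap]:
    with ad.no_grad():
        w, fea = params(ad.Tensor(mk_fea.values))
    return w.data, FeatureMap(fea.data, "Global_Fea")


def local_spatial_fusion(mk_fea: FeatureMap, config: ModelConfig,
                         params: LocalSpatialFusion) -> tuple[np.ndarray, FeatureMap]:
    with ad.no_grad():
        w, fea = params(ad.Tensor(mk_fea.values))
    return w.data, FeatureMap(fea.data, "Local_Fea")


def mkff_forward(batch: EncodedBatch, config: ModelConfig, params: MKFF) -> FeatureMap:
    with ad.no_grad():
        return FeatureMap(params(batch.codes).data, "O_MKFF")
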