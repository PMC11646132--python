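"""Downsampling residual feature embedding (DRFE) and the contrastive loss.

A stem of two equal-length kernel-5 convolutions reads O_MKFF, then a
stack of downsampling-residual (DR) blocks progressively halves the
position axis: each block max-pools (kernel 3, stride 2, pad 1) and adds
the pooled map residually to a double equal-length convolution of itself.
Three blocks take 800 positions to 100, compressing the padded feature
space eightfold before the classifier head.

Representation learning on the compressed embedding uses the margin
contrastive loss on flattened X_DRFE vectors:

    L = 1/2 [ (1-K) D^2 + K max(0, M - D)^2 ]

with K=0 for a same-class pair, K=1 otherwise, D the Euclidean distance
and M the margin (default 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .config import ConfigError, ModelConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContrastivePairLoss:
    """One evaluated pair of the margin contrastive loss."""

    K: int  # 0 same class, 1 different class
    D: float  # Euclidean distance between flattened embeddings
    M: float  # margin
    value: float  # non-negative loss


class Stem(nn.Module):
    """Two equal-length kernel-5 convolutions (ReLU after each)."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        c, dtype, gain = config.out_channel, config.np_dtype, config.init_gain
        self.conv1 = nn.Conv1d(c, c, 5, pad=2, rng=rng, dtype=dtype, gain=gain)
        self.conv2 = nn.Conv1d(c, c, 5, pad=2, rng=rng, dtype=dtype, gain=gain)

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        return ad.relu(self.conv2(ad.relu(self.conv1(x))))


class DRBlock(nn.Module):
    """Strided max-pool followed by a residual equal-length double conv."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        c, dtype = config.out_channel, config.np_dtype
        self.pool_kernel = config.pool_kernel
        self.stride = config.dr_pool_stride
        gain = config.init_gain
        self.conv1 = nn.Conv1d(c, c, 5, pad=2, rng=rng, dtype=dtype, gain=gain)
        self.conv2 = nn.Conv1d(c, c, 5, pad=2, rng=rng, dtype=dtype, gain=gain)

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        if x.shape[2] < self.pool_kernel:
            raise ConfigError(
                f"position axis of length {x.shape[2]} is shorter than the pool kernel; "
                "use fewer DR blocks"
            )
        x_down = ad.maxpool1d(x, kernel=self.pool_kernel, stride=self.stride,
                              pad=self.pool_kernel // 2)
        branch = ad.relu(self.conv2(ad.relu(self.conv1(x_down))))
        return branch + x_down


class DRFE(nn.Module):
    """Stem followed by ``n_dr_blocks`` sequential DR blocks."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.stem = Stem(config, rng)
        self.blocks = [DRBlock(config, rng) for _ in range(config.n_dr_blocks)]

    def __call__(self, o_mkff: ad.Tensor) -> ad.Tensor:
        x = self.stem(o_mkff)
        for block in self.blocks:
            x = block(x)
        return x


# -- functional wrappers -----------------------------------------------


def stem_forward(o_mkff, params: Stem):
    from .mkff import FeatureMap

    values = o_mkff.values if hasattr(o_mkff, "values") else np.asarray(o_mkff)
    with ad.no_grad():
        return FeatureMap(params(ad.Tensor(values)).data, "stem")


def dr_block(x, config: ModelConfig, params: DRBlock):
    from .mkff import FeatureMap

    values = x.values if hasattr(x, "values") else np.asarray(x)
    with ad.no_grad():
        return FeatureMap(params(ad.Tensor(values)).data, "X_DRFE")


def drfe_forward(o_mkff, config: ModelConfig, params: DRFE):
    from .mkff import FeatureMap

    values = o_mkff.values if hasattr(o_mkff, "values") else np.asarray(o_mkff)
    with ad.no_grad():
        return FeatureMap(params(ad.Tensor(values)).data, "X_DRFE")


# -- contrastive objective ---------------------------------------------


def contrastive_loss(f_i: np.ndarray, f_j: np.ndarray, same_class: bool,
                     M: float) -> ContrastivePairLoss:
    """Evaluate the margin contrastive loss for one pair of embeddings."""
    f_i, f_j = np.asarray(f_i, dtype=np.float64).ravel(), np.asarray(f_j, dtype=np.float64).ravel()
    if f_i.shape != f_j.shape:
        raise ValueError(f"embedding dimension mismatch: {f_i.shape} vs {f_j.shape}")
    if M <= 0:
        raise ValueError("margin must be positive")
    D = float(np.linalg.norm(f_i - f_j))
    K = 0 if same_class else 1
    value = 0.5 * ((1 - K) * D**2 + K * max(0.0, M - D) ** 2)
    return ContrastivePairLoss(K=K, D=D, M=M, value=value)


def _pair_indices(n: int, pair_mode: str, pair_seed) -> tuple[np.ndarray, np.ndarray]:
    if pair_mode == "all":
        left, right = np.triu_indices(n, k=1)
        return left, right
    rng = np.random.default_rng(pair_seed)
    perm = rng.permutation(n)
    m = n // 2  # odd leftover dropped
    return perm[0 : 2 * m : 2], perm[1 : 2 * m : 2]


def batch_contrastive(features, labels, M: float, pair_seed,
                      pair_mode: str = "random") -> ad.Tensor:
    """Mean contrastive loss over a seeded random disjoint pairing.

    ``features`` may be a Tensor (differentiable path used in training)
    or an array.  Samples are shuffled with ``pair_seed`` and paired
    (2t, 2t+1); an odd leftover is dropped.  ``pair_mode='all'`` averages
    over all n(n-1)/2 pairs instead.
    """
    feats = features if isinstance(features, ad.Tensor) else ad.Tensor(np.asarray(features))
    labels = np.asarray(labels)
    n = feats.shape[0]
    if n < 2:
        logger.warning("batch of %d: contrastive loss undefined, returning 0", n)
        return ad.Tensor(np.zeros((), dtype=feats.dtype))
    left, right = _pair_indices(n, pair_mode, pair_seed)
    a = ad.take_rows(feats, left)
    b = ad.take_rows(feats, right)
    diff = a - b
    ssq = ad._sum(diff * diff, axis=1)  # D^2 per pair
    dist = ad.sqrt(ssq)
    K = (labels[left] != labels[right]).astype(feats.data.dtype)
    hinge = ad.relu(float(M) - dist)
    per_pair = 0.5 * ((1.0 - K) * ssq + K * (hinge * hinge))
    return ad.mean(per_pair)
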