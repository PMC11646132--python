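"""Model and training configuration.

Defaults follow the published hyperparameter choices for the rice m6A
peak-sequence task: maximum padded length 800, out channel 128, channel
attention hyperparameters gamma=2 / b=1, reduction ratio 4, three
downsampling-residual blocks, contrastive margin 2, batch size 128, and a
0.5 decision threshold.  Everything architectural that the task leaves
open (embedding width, pooling stride, softmax axis, nonlinearity
placement) is an explicit field here so ablations and sweeps are pure
configuration changes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import yaml

FUSION_MODES = ("gldf", "cat", "add", "global", "local")
KERNEL_PATHS = ("k1", "k2", "k3", "k4")


class ConfigError(ValueError):
    """Raised for inconsistent architecture/training settings."""


@dataclass
class ModelConfig:
    # architecture
    L_max: int = 800
    vocab: int = 5
    embed_dim: int = 64
    out_channel: int = 128
    gamma: float = 2.0
    b: float = 1.0
    reduction_ratio: int = 4
    kernel_sizes: tuple[int, ...] = (1, 3, 5)
    pool_kernel: int = 3
    n_dr_blocks: int = 3
    dr_pool_stride: int = 2
    margin: float = 2.0
    threshold: float = 0.5
    softmax_axis: str = "positions"  # or "channels"
    # variants (ablations)
    use_mkff: bool = True
    use_drfe: bool = True
    use_cl: bool = True
    fusion_mode: str = "gldf"
    kernel_combo: tuple[str, ...] = ("k1", "k2", "k3", "k4")
    # input handling
    padding_side: str = "left"
    ambiguous_policy: str = "strict"  # or "map_to_pad"
    truncate: bool = False
    #: multiplier on He/unit init scales; the default keeps initial
    #: embedding distances commensurate with the contrastive margin so
    #: neither loss term dominates at the start of training
    init_gain: float = 0.5
    # training
    batch_size: int = 128
    lr: float = 3e-3
    epochs: int = 50
    patience: int = 5
    seed: int = 0
    pair_mode: str = "random"  # or "all"
    dtype: str = "float32"

    def __post_init__(self):
        if self.L_max < 1:
            raise ConfigError("L_max must be positive")
        if self.out_channel % 4 != 0:
            raise ConfigError("out_channel must be divisible by 4 (one quarter per kernel path)")
        if self.out_channel % self.reduction_ratio != 0:
            raise ConfigError("out_channel must be divisible by reduction_ratio")
        if any(k < 1 or k % 2 == 0 for k in self.kernel_sizes):
            raise ConfigError("kernel sizes must be odd and positive")
        if self.fusion_mode not in FUSION_MODES:
            raise ConfigError(f"fusion_mode must be one of {FUSION_MODES}")
        if not self.kernel_combo:
            raise ConfigError("kernel_combo must select at least one path")
        if any(k not in KERNEL_PATHS for k in self.kernel_combo):
            raise ConfigError(f"kernel_combo entries must be in {KERNEL_PATHS}")
        if not 0.0 < self.threshold < 1.0:
            raise ConfigError("threshold must lie in (0, 1)")
        if self.margin <= 0:
            raise ConfigError("margin must be positive")
        if self.softmax_axis not in ("positions", "channels"):
            raise ConfigError("softmax_axis must be 'positions' or 'channels'")
        if self.padding_side not in ("left", "right"):
            raise ConfigError("padding_side must be 'left' or 'right'")
        if self.ambiguous_policy not in ("strict", "map_to_pad"):
            raise ConfigError("ambiguous_policy must be 'strict' or 'map_to_pad'")
        if self.pair_mode not in ("random", "all"):
            raise ConfigError("pair_mode must be 'random' or 'all'")
        if self.n_dr_blocks < 0:
            raise ConfigError("n_dr_blocks must be >= 0")
        if self.final_length < 1:
            raise ConfigError(
                "downsampling collapses the sequence to length 0; use fewer DR blocks"
            )

    # -- derived geometry ----------------------------------------------
    @property
    def final_length(self) -> int:
        """Position count after the downsampling-residual stack."""
        length = self.L_max
        for _ in range(self.n_dr_blocks if self.use_drfe else 0):
            length = (length + 2 - self.pool_kernel) // self.dr_pool_stride + 1
        return length

    @property
    def head_in_features(self) -> int:
        length = self.final_length if self.use_drfe else self.L_max
        return self.out_channel * length

    @property
    def np_dtype(self):
        import numpy as np

        return {"float32": np.float32, "float64": np.float64}[self.dtype]

    # -- (de)serialization ---------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kernel_sizes"] = list(self.kernel_sizes)
        d["kernel_combo"] = list(self.kernel_combo)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("kernel_sizes", "kernel_combo"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
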