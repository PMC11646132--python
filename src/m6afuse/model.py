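"""Full network assembly, prediction, and the training objective.

The classifier chains the multi-kernel fusion stack (or, in the w/o-MKFF
variant, just the embedding + point-wise projection), the
downsampling-residual embedding (optional in the w/o-DRFE variant), and a
single-logit fully connected head with sigmoid.  A probability below the
threshold (default 0.5) is called negative; the boundary value itself is
called positive.

The training objective is the unweighted sum of binary cross-entropy over
the batch and the batch contrastive loss on flattened embeddings (omitted
in the w/o-CL variant):  L_total = L_cl + L_bce.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .config import ConfigError, ModelConfig
from .drfe import DRFE, batch_contrastive
from .io_encoding import EncodedBatch, batch_encode
from .mkff import MKFF, EmbedProject

#: Probability clipping for the BCE logarithms.
BCE_EPS = 1e-7

#: Stage names exposed by ``forward(..., taps=...)`` for interpretation.
TAP_STAGES = ("embedding", "o_embed", "mkc", "mk_fea", "o_mkff", "x_drfe", "features")


@dataclass(frozen=True)
class Prediction:
    """A predicted probability with its thresholded binary call."""

    probability: float
    label: int


@dataclass(frozen=True)
class LossBreakdown:
    """BCE, contrastive, and total loss for one batch.

    ``tensor`` is the differentiable total used by the trainer; the float
    fields are detached conveniences.
    """

    bce: float
    cl: float
    total: float
    tensor: ad.Tensor | None = None


class M6AClassifier(nn.Module):
    """End-to-end m6A peak-sequence classifier."""

    def __init__(self, config: ModelConfig, init_seed: int = 0):
        self.config = config
        rng = np.random.default_rng(init_seed)
        if config.use_mkff:
            self.mkff = MKFF(config, rng)
            self.embed_only = None
        else:
            self.mkff = None
            self.embed_only = EmbedProject(config, rng)
        self.drfe = DRFE(config, rng) if config.use_drfe else None
        self.head = nn.Linear(config.head_in_features, 1, rng=rng, dtype=config.np_dtype,
                              gain=config.init_gain)

    def forward(self, codes: np.ndarray, taps: dict | None = None) -> ad.Tensor:
        """Map integer codes (batch, L_max) to probabilities (batch,)."""
        if codes.ndim != 2 or codes.shape[1] != self.config.L_max:
            raise ValueError(
                f"expected codes of shape (n, {self.config.L_max}), got {codes.shape}"
            )
        if self.mkff is not None:
            x = self.mkff(codes, taps=taps)
        else:
            x = self.embed_only(codes, taps=taps)
            if taps is not None:
                taps["o_embed"] = x
                taps["o_mkff"] = x
        if self.drfe is not None:
            x = self.drfe(x)
        if taps is not None:
            taps["x_drfe"] = x
        flat = ad.reshape(x, (x.shape[0], x.shape[1] * x.shape[2]))
        if taps is not None:
            taps["features"] = flat
        logit = self.head(flat)
        prob = ad.sigmoid(ad.reshape(logit, (logit.shape[0],)))
        return prob

    __call__ = forward

    # -- persistence ---------------------------------------------------
    def save(self, path, extra: dict | None = None) -> None:
        """Single-file checkpoint: config JSON + all weights (+ metadata)."""
        meta = {"config": self.config.to_dict(), "extra": extra or {}}
        arrays = {f"param_{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> tuple["M6AClassifier", dict]:
        with np.load(path) as data:
            meta = json.loads(bytes(data["_meta"]).decode())
            arrays = [data[f"param_{i}"] for i in range(len(data.files) - 1)]
        config = ModelConfig.from_dict(meta["config"])
        model = cls(config, init_seed=0)
        model.load_state_arrays(arrays)
        return model, meta.get("extra", {})


def build_model(config: ModelConfig, init_seed: int = 0) -> M6AClassifier:
    """Build the network with deterministic weight initialization."""
    return M6AClassifier(config, init_seed=init_seed)


def predict_proba(model: M6AClassifier, batch: EncodedBatch,
                  batch_size: int = 256) -> np.ndarray:
    """Inference-mode probabilities for an encoded batch."""
    probs = []
    with ad.no_grad():
        for start in range(0, len(batch), batch_size):
            probs.append(model(batch.codes[start : start + batch_size]).data)
    return np.concatenate(probs) if probs else np.zeros(0)


def predict_records(model: M6AClassifier, records, batch_size: int = 256) -> list[Prediction]:
    batch = batch_encode(
        records, model.config.L_max, truncate=model.config.truncate,
        padding_side=model.config.padding_side,
        ambiguous_policy=model.config.ambiguous_policy,
    )
    probs = predict_proba(model, batch, batch_size=batch_size)
    calls = classify(probs, model.config.threshold)
    return [Prediction(float(p), int(c)) for p, c in zip(probs, calls)]


def bce_loss(y_hat, y) -> ad.Tensor:
    """Mean binary cross-entropy with probabilities clipped to [eps, 1-eps]."""
    y_hat = y_hat if isinstance(y_hat, ad.Tensor) else ad.Tensor(np.asarray(y_hat, dtype=float))
    y = np.asarray(y)
    if y_hat.shape[0] != y.shape[0]:
        raise ValueError(f"length mismatch: {y_hat.shape[0]} probabilities, {y.shape[0]} labels")
    p = ad.clip(y_hat, BCE_EPS, 1.0 - BCE_EPS)
    yf = y.astype(p.dtype)
    ll = yf * ad.log(p) + (1.0 - yf) * ad.log(1.0 - p)
    return -1.0 * ad.mean(ll)


def total_loss(y_hat, y, features, config: ModelConfig, pair_seed) -> LossBreakdown:
    """L_total = L_cl + L_bce (the contrastive term drops in w/o-CL)."""
    bce = bce_loss(y_hat, y)
    if config.use_cl:
        cl = batch_contrastive(features, y, config.margin, pair_seed,
                               pair_mode=config.pair_mode)
        total = bce + cl
        return LossBreakdown(bce=bce.item(), cl=cl.item(), total=total.item(), tensor=total)
    return LossBreakdown(bce=bce.item(), cl=0.0, total=bce.item(), tensor=bce)


def classify(y_hat, threshold: float = 0.5) -> np.ndarray:
    """Binary calls: negative iff probability < threshold."""
    if not 0.0 < threshold < 1.0:
        raise ConfigError("threshold must lie in (0, 1)")
    return (np.asarray(y_hat) >= threshold).astype(np.int64)
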