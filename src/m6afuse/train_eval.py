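"""Seeded training loop, stratified k-fold cross-validation, and metrics.

Evaluation follows the standard binary-classification panel for m6A site
predictors: accuracy (ACC) and Matthews correlation coefficient (MCC) at
the configured threshold, the area under the ROC curve (AUC), and the
area under the precision-recall curve (AUPR, average-precision
convention).  Cross-validation is stratified so both classes appear in
every fold, and reports mean +/- sample standard deviation over folds at
four decimals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    matthews_corrcoef,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from . import autodiff as ad
from . import nn
from .config import ModelConfig
from .io_encoding import EncodedBatch, batch_encode
from .model import M6AClassifier, build_model, classify, predict_proba, total_loss

logger = logging.getLogger(__name__)

METRIC_NAMES = ("ACC", "MCC", "AUC", "AUPR")


class DegenerateLabelsError(ValueError):
    """Ranking metrics are undefined when only one class is present."""


def compute_metrics(y, y_hat, threshold: float = 0.5,
                    allow_degenerate: bool = False) -> dict[str, float]:
    """ACC/MCC at the threshold plus AUC and AUPR from the probabilities."""
    y = np.asarray(y)
    y_hat = np.asarray(y_hat)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: labels {y.shape}, probabilities {y_hat.shape}")
    calls = classify(y_hat, threshold)
    acc = accuracy_score(y, calls)
    mcc = matthews_corrcoef(y, calls)  # zero-denominator convention: 0
    if len(np.unique(y)) < 2:
        if not allow_degenerate:
            raise DegenerateLabelsError("AUC/AUPR undefined with a single-class y")
        auc = aupr = float("nan")
    else:
        auc = roc_auc_score(y, y_hat)
        aupr = average_precision_score(y, y_hat)
    return {"ACC": float(acc), "MCC": float(mcc), "AUC": float(auc), "AUPR": float(aupr)}


@dataclass
class MetricsReport:
    """Per-fold and aggregate metrics (mean +/- sample std)."""

    per_fold: list[dict[str, float]]

    @property
    def n_folds(self) -> int:
        return len(self.per_fold)

    @property
    def mean(self) -> dict[str, float]:
        return {m: float(np.mean([f[m] for f in self.per_fold])) for m in METRIC_NAMES}

    @property
    def std(self) -> dict[str, float]:
        if self.n_folds < 2:
            return {m: 0.0 for m in METRIC_NAMES}
        return {m: float(np.std([f[m] for f in self.per_fold], ddof=1)) for m in METRIC_NAMES}

    def summary(self) -> str:
        mean, std = self.mean, self.std
        return "  ".join(f"{m}={mean[m]:.4f}±{std[m]:.4f}" for m in METRIC_NAMES)

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(fold=i, **f) for i, f in enumerate(self.per_fold)]
        rows.append(dict(fold="mean", **self.mean))
        rows.append(dict(fold="std", **self.std))
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"per_fold": self.per_fold, "mean": self.mean,
                       "std": self.std, "n_folds": self.n_folds}, fh, indent=2)


def _encode(records, config: ModelConfig) -> EncodedBatch:
    return batch_encode(records, config.L_max, truncate=config.truncate,
                        padding_side=config.padding_side,
                        ambiguous_policy=config.ambiguous_policy)


def train(model: M6AClassifier, train_records, val_records,
          config: ModelConfig | None = None) -> dict:
    """Minibatch gradient descent on L_total with early stopping.

    Uses Adam at ``config.lr``; each epoch re-shuffles with an
    epoch-derived seed, and each batch's contrastive pairing gets its own
    derived seed, so runs are fully reproducible.  Early stopping
    monitors validation AUC with ``config.patience``; the best weights
    are restored before returning.  Returns a history dict with
    per-epoch losses and validation metrics.
    """
    config = config or model.config
    if not train_records or not val_records:
        raise ValueError("train and validation splits must both be non-empty")
    train_batch = _encode(train_records, config)
    val_batch = _encode(val_records, config)
    if train_batch.labels is None or val_batch.labels is None:
        raise ValueError("training requires labeled records")

    optimizer = nn.Adam(model.parameters(), lr=config.lr)
    history = {"epoch": [], "train_loss": [], "train_bce": [], "train_cl": [],
               "val": []}
    best_auc, best_state, patience_left = -np.inf, None, config.patience
    n = len(train_batch)

    for epoch in range(config.epochs):
        rng = np.random.default_rng([config.seed % (2**31), 7, epoch])
        order = rng.permutation(n)
        losses, bces, cls_ = [], [], []
        for bi, start in enumerate(range(0, n, config.batch_size)):
            idx = order[start : start + config.batch_size]
            if idx.size < 2:
                continue
            taps: dict = {}
            probs = model(train_batch.codes[idx], taps=taps)
            breakdown = total_loss(probs, train_batch.labels[idx], taps["features"],
                                   config, pair_seed=[config.seed % (2**31), 11, epoch, bi])
            optimizer.zero_grad()
            breakdown.tensor.backward()
            optimizer.step()
            losses.append(breakdown.total)
            bces.append(breakdown.bce)
            cls_.append(breakdown.cl)
        val_probs = predict_proba(model, val_batch)
        val_metrics = compute_metrics(val_batch.labels, val_probs, config.threshold)
        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.mean(losses)))
        history["train_bce"].append(float(np.mean(bces)))
        history["train_cl"].append(float(np.mean(cls_)))
        history["val"].append(val_metrics)
        logger.info("epoch %d: loss=%.4f val_auc=%.4f", epoch,
                    history["train_loss"][-1], val_metrics["AUC"])
        if val_metrics["AUC"] >= best_auc:
            # ties keep the later epoch: equal ranking, better-calibrated
            # probabilities (BCE keeps dropping)
            if val_metrics["AUC"] > best_auc:
                patience_left = config.patience
            else:
                patience_left -= 1
            best_auc = val_metrics["AUC"]
            best_state = [a.copy() for a in model.state_arrays()]
        else:
            patience_left -= 1
        if patience_left <= 0:
            logger.info("early stop at epoch %d (best val AUC %.4f)", epoch, best_auc)
            break
    if best_state is not None:
        model.load_state_arrays(best_state)
    history["best_val_auc"] = float(best_auc)
    return history


def cross_validate(records, config: ModelConfig, k: int = 5,
                   seed: int | None = None) -> MetricsReport:
    """Stratified k-fold cross-validation of the configured model.

    Each fold trains on the remaining k-1 folds (its held-out fold serves
    as the validation set for early stopping and for the reported
    metrics, mirroring the 80/20 train/validation protocol at k=5).
    """
    records = list(records)
    labels = np.array([r.label for r in records])
    if None in labels:
        raise ValueError("cross-validation requires labeled records")
    seed = config.seed if seed is None else seed
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold = []
    for fold, (train_idx, val_idx) in enumerate(skf.split(np.zeros(len(records)), labels)):
        fold_val_labels = labels[val_idx]
        if len(np.unique(labels[train_idx])) < 2 or len(np.unique(fold_val_labels)) < 2:
            raise ValueError(f"fold {fold}: a class is absent; use fewer folds")
        model = build_model(config, init_seed=seed + fold)
        history = train(model, [records[i] for i in train_idx],
                        [records[i] for i in val_idx], config)
        val_batch = _encode([records[i] for i in val_idx], config)
        probs = predict_proba(model, val_batch)
        metrics = compute_metrics(fold_val_labels, probs, config.threshold)
        logger.info("fold %d: %s", fold,
                    "  ".join(f"{m}={metrics[m]:.4f}" for m in METRIC_NAMES))
        per_fold.append(metrics)
    return MetricsReport(per_fold=per_fold)
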