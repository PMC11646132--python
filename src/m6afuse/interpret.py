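"""Gradient-saliency motif discovery and embedding export.

The model's sensitivity to each input position is measured as the L2 norm
(over embedding dimensions) of the gradient of the predicted probability
with respect to the embedding vectors; padding positions are excluded, so
scores index into the original sequence.  A fixed sliding window (stride
1) then captures high-contribution regions: windows are scored by the sum
of per-position saliency and the top-k non-overlapping windows are
selected greedily (ties broken leftmost).  The corresponding
subsequences can be exported as FASTA for downstream multiple-alignment
motif tools; windows are written as BED (0-based, half-open).

Feature-space inspection exports flattened per-record vectors at four
stages — MP (the padded code vector itself), MKC (concatenated
multi-kernel features entering the fusion function), GLDF (the fused
module output), and DRFE (the compressed embedding) — and quantifies
class separation with the silhouette score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import silhouette_score as _sk_silhouette

from . import autodiff as ad
from .io_encoding import batch_encode
from .model import M6AClassifier

EMBEDDING_STAGES = ("MP", "MKC", "GLDF", "DRFE")
_STAGE_TAPS = {"MKC": "mkc", "GLDF": "o_mkff", "DRFE": "x_drfe"}


@dataclass
class SaliencyResult:
    """Per-position saliency plus extracted high-contribution windows."""

    record_id: str
    per_position: np.ndarray  # length = original sequence length
    windows: list[tuple[int, int, float]] = None  # (start, end, score), desc. score
    subsequences: list[str] = None


def input_saliency(model: M6AClassifier, record, aggregation: str = "l2") -> SaliencyResult:
    """Gradient of the predicted probability w.r.t. the embedding vectors.

    ``aggregation`` collapses the embedding dimension per position:
    ``l2`` (default) or ``abs_sum``.
    """
    if aggregation not in ("l2", "abs_sum"):
        raise ValueError("aggregation must be 'l2' or 'abs_sum'")
    config = model.config
    batch = batch_encode([record], config.L_max, truncate=config.truncate,
                         padding_side=config.padding_side,
                         ambiguous_policy=config.ambiguous_policy)
    taps: dict = {}
    prob = model(batch.codes, taps=taps)
    emb = taps["embedding"]  # (1, embed_dim, L_max)
    model.zero_grad()
    prob.backward(np.ones(1, dtype=prob.dtype))
    grad = emb.grad if emb.grad is not None else np.zeros_like(emb.data)
    model.zero_grad()
    if aggregation == "l2":
        per_pos = np.sqrt((grad[0] ** 2).sum(axis=0))
    else:
        per_pos = np.abs(grad[0]).sum(axis=0)
    n = int(batch.lengths[0])
    # padding is a prefix under left padding, a suffix under right padding
    scores = per_pos[config.L_max - n:] if config.padding_side == "left" else per_pos[:n]
    return SaliencyResult(record_id=record.id, per_position=scores.astype(np.float64))


def extract_windows(per_position: np.ndarray, window: int, top_k: int,
                    ) -> list[tuple[int, int, float]]:
    """Top-k non-overlapping fixed-width windows by summed saliency.

    Windows slide with stride 1; selection is greedy by descending score
    with ties broken leftmost.
    """
    scores = np.asarray(per_position, dtype=np.float64)
    length = scores.size
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if window < 1 or window > length:
        raise ValueError(f"window must lie in [1, {length}]")
    cums = np.concatenate([[0.0], np.cumsum(scores)])
    window_scores = cums[window:] - cums[:-window]  # start = 0..length-window
    order = sorted(range(window_scores.size), key=lambda s: (-window_scores[s], s))
    chosen: list[tuple[int, int, float]] = []
    taken = np.zeros(length, dtype=bool)
    for start in order:
        if len(chosen) == top_k:
            break
        if taken[start : start + window].any():
            continue
        taken[start : start + window] = True
        chosen.append((start, start + window, float(window_scores[start])))
    return chosen


def saliency_windows(model: M6AClassifier, records, window: int = 10,
                     top_k: int = 3, aggregation: str = "l2") -> list[SaliencyResult]:
    """Saliency + window extraction + subsequence slicing for many records."""
    results = []
    for rec in records:
        res = input_saliency(model, rec, aggregation=aggregation)
        w = min(window, res.per_position.size)
        res.windows = extract_windows(res.per_position, w, top_k)
        res.subsequences = [rec.sequence[s:e] for s, e, _ in res.windows]
        results.append(res)
    return results


def export_subsequences(records, saliency_results, path) -> int:
    """Write one FASTA entry per extracted window; returns the entry count."""
    by_id = {rec.id: rec for rec in records}
    n = 0
    with open(path, "w") as fh:
        for res in saliency_results:
            seq = by_id[res.record_id].sequence
            for start, end, score in res.windows or ():
                fh.write(f">{res.record_id}:{start}-{end} score={score:.6g}\n")
                fh.write(seq[start:end] + "\n")
                n += 1
    return n


def export_windows_bed(saliency_results, path) -> None:
    with open(path, "w") as fh:
        for res in saliency_results:
            for start, end, score in res.windows or ():
                fh.write(f"{res.record_id}\t{start}\t{end}\tsaliency\t{score:.6g}\n")


def export_embeddings(model: M6AClassifier, records, stage: str,
                      batch_size: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Flattened per-record feature vectors at a named stage + labels."""
    if stage not in EMBEDDING_STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {EMBEDDING_STAGES}")
    config = model.config
    batch = batch_encode(records, config.L_max, truncate=config.truncate,
                         padding_side=config.padding_side,
                         ambiguous_policy=config.ambiguous_policy)
    labels = batch.labels if batch.labels is not None else np.full(len(batch), -1)
    if stage == "MP":
        return batch.codes.astype(np.float64), labels
    chunks = []
    with ad.no_grad():
        for start in range(0, len(batch), batch_size):
            taps: dict = {}
            model(batch.codes[start : start + batch_size], taps=taps)
            t = taps[_STAGE_TAPS[stage]]
            chunks.append(t.data.reshape(t.shape[0], -1).astype(np.float64))
    return np.concatenate(chunks, axis=0), labels


def write_embeddings_tsv(ids, matrix, path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(ids, matrix):
            fh.write(rid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def silhouette_score(embeddings: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette over samples (Euclidean distance)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette score requires at least two classes")
    return float(_sk_silhouette(np.asarray(embeddings), labels, metric="euclidean"))


def motif_overlap_enrichment(saliency_results, records, n_permutations: int = 1000,
                             seed: int = 0) -> dict:
    """Permutation test: do top-1 windows overlap planted motifs?

    Compares the mean overlap (in bases) of each record's top-scoring
    window with its ground-truth motif intervals against a null built by
    placing the same-width window uniformly at random in the same
    sequence.  Returns the observed mean, the null mean, and a one-sided
    p-value.
    """
    by_id = {rec.id: rec for rec in records}
    rng = np.random.default_rng(seed)
    observed, null_draws = [], []
    for res in saliency_results:
        rec = by_id[res.record_id]
        if not rec.motif_intervals or not res.windows:
            continue
        start, end, _ = res.windows[0]
        observed.append(_overlap(start, end, rec.motif_intervals))
        width = end - start
        span = len(rec.sequence) - width
        starts = rng.integers(0, span + 1, size=n_permutations) if span > 0 else np.zeros(n_permutations, dtype=int)
        null_draws.append([
            _overlap(s, s + width, rec.motif_intervals) for s in starts
        ])
    if not observed:
        raise ValueError("no records with ground-truth motif intervals")
    observed_mean = float(np.mean(observed))
    null_matrix = np.asarray(null_draws)  # (records, permutations)
    null_means = null_matrix.mean(axis=0)
    p = float((np.sum(null_means >= observed_mean) + 1) / (n_permutations + 1))
    return {"observed_mean_overlap": observed_mean,
            "null_mean_overlap": float(null_means.mean()),
            "p_value": p, "n_records": len(observed)}


def _overlap(start: int, end: int, intervals) -> int:
    """Largest base overlap between [start, end) and any interval."""
    best = 0
    for s, e in intervals:
        best = max(best, min(end, e) - max(start, s))
    return max(best, 0)
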