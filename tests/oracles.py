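"""Independent brute-force reference implementations used only by tests.

Everything here is written as explicit Python loops (or direct textbook
formulas) so it shares no code path with the package's vectorized
implementations.
"""

from __future__ import annotations

import math

import numpy as np


def conv1d_loops(x, w, b=None, pad=0):
    """Explicit-loop stride-1 1-D convolution. x: (B,Ci,L); w: (Co,Ci,K)."""
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    B, Ci, L = x.shape
    Co, _, K = w.shape
    xp = np.zeros((B, Ci, L + 2 * pad))
    xp[:, :, pad : pad + L] = x
    Lout = L + 2 * pad - K + 1
    out = np.zeros((B, Co, Lout))
    for bi in range(B):
        for co in range(Co):
            for pos in range(Lout):
                acc = 0.0
                for ci in range(Ci):
                    for k in range(K):
                        acc += xp[bi, ci, pos + k] * w[co, ci, k]
                out[bi, co, pos] = acc + (b[co] if b is not None else 0.0)
    return out


def maxpool1d_loops(x, kernel, stride=1, pad=0):
    x = np.asarray(x, dtype=np.float64)
    B, C, L = x.shape
    xp = np.full((B, C, L + 2 * pad), -np.inf)
    xp[:, :, pad : pad + L] = x
    Lout = (L + 2 * pad - kernel) // stride + 1
    out = np.zeros((B, C, Lout))
    for bi in range(B):
        for c in range(C):
            for pos in range(Lout):
                out[bi, c, pos] = max(xp[bi, c, pos * stride : pos * stride + kernel])
    return out


def relu_loops(x):
    return np.maximum(np.asarray(x, dtype=np.float64), 0.0)


def global_attention_loops(mk, w, b):
    """Mean over positions, 1-channel cross-channel conv, sigmoid, broadcast."""
    mk = np.asarray(mk, dtype=np.float64)
    B, C, L = mk.shape
    K = w.shape[-1]
    pad = K // 2
    weight = np.zeros((B, C))
    profile = mk.mean(axis=2)  # (B, C)
    for bi in range(B):
        padded = np.zeros(C + 2 * pad)
        padded[pad : pad + C] = profile[bi]
        for c in range(C):
            acc = b[0] if b is not None else 0.0
            for k in range(K):
                acc += padded[c + k] * w.reshape(-1)[k]
            weight[bi, c] = 1.0 / (1.0 + math.exp(-acc))
    fea = mk * weight[:, :, None]
    return weight, fea


def local_attention_loops(mk, w_sq, b_sq, w_ex, b_ex, axis=2):
    """Squeeze conv -> excitation conv -> softmax -> elementwise weight."""
    squeezed = conv1d_loops(mk, w_sq, b_sq, pad=w_sq.shape[-1] // 2)
    logits = conv1d_loops(squeezed, w_ex, b_ex, pad=w_ex.shape[-1] // 2)
    shifted = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    weight = e / e.sum(axis=axis, keepdims=True)
    return weight, np.asarray(mk, dtype=np.float64) * weight


def dense_sigmoid_loops(x, w, b):
    """Flattened dense layer + sigmoid, one sample at a time."""
    x = np.asarray(x, dtype=np.float64)
    out = np.zeros(x.shape[0])
    for i in range(x.shape[0]):
        acc = b[0]
        for j in range(x.shape[1]):
            acc += x[i, j] * w[j, 0]
        out[i] = 1.0 / (1.0 + math.exp(-acc))
    return out


def auc_pairwise(y, scores):
    """Wilcoxon rank statistic: P(score_pos > score_neg) + 0.5 ties."""
    y = np.asarray(y)
    scores = np.asarray(scores)
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def mcc_confusion(y, calls):
    """MCC from the 2x2 confusion matrix; 0 on a zero denominator."""
    y = np.asarray(y)
    calls = np.asarray(calls)
    tp = int(np.sum((y == 1) & (calls == 1)))
    tn = int(np.sum((y == 0) & (calls == 0)))
    fp = int(np.sum((y == 0) & (calls == 1)))
    fn = int(np.sum((y == 1) & (calls == 0)))
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def silhouette_loops(X, labels):
    """Mean silhouette with explicit pairwise Euclidean distances."""
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    n = X.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            dist[i, j] = math.sqrt(((X[i] - X[j]) ** 2).sum())
    scores = []
    for i in range(n):
        same = [j for j in range(n) if j != i and labels[j] == labels[i]]
        a = sum(dist[i, j] for j in same) / len(same)
        b = min(
            sum(dist[i, j] for j in np.nonzero(labels == other)[0]) / np.sum(labels == other)
            for other in np.unique(labels) if other != labels[i]
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def windows_bruteforce(scores, window, top_k):
    """Exhaustive greedy non-overlapping window selection, ties leftmost."""
    scores = np.asarray(scores, dtype=np.float64)
    candidates = [
        (float(scores[s : s + window].sum()), s) for s in range(len(scores) - window + 1)
    ]
    candidates.sort(key=lambda t: (-t[0], t[1]))
    chosen, used = [], set()
    for score, start in candidates:
        if len(chosen) == top_k:
            break
        span = set(range(start, start + window))
        if span & used:
            continue
        used |= span
        chosen.append((start, start + window, score))
    return chosen
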