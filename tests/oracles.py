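"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written as plain loops / exhaustive
enumeration, independent of the code paths under test.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np


def dihedral_oracle(p1, p2, p3, p4) -> float:
    """Signed dihedral via projections onto the plane perpendicular to the
    central bond: angle between the projected outer bonds, signed by the
    scalar triple product."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    b2u = b2 / np.linalg.norm(b2)
    u = -b1 - np.dot(-b1, b2u) * b2u  # component of p1<-p2 normal to axis
    w = b3 - np.dot(b3, b2u) * b2u
    cos_a = np.dot(u, w) / (np.linalg.norm(u) * np.linalg.norm(w))
    angle = math.degrees(math.acos(max(-1.0, min(1.0, cos_a))))
    if np.dot(np.cross(u, w), b2u) < 0:
        angle = -angle
    # map to [-180, 180)
    if angle >= 180.0 - 1e-12:
        angle -= 360.0
    return angle


def sw_bruteforce(a: str, b: str, sub, gap_open: float, gap_extend: float) -> float:
    """Optimal local alignment score by exhaustive enumeration.

    ``sub(x, y)`` gives the substitution score. A gap of length L costs
    gap_open + L * gap_extend. Enumerates every alignment of every pair of
    substrings; feasible only for very short sequences.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        # best score of an alignment ENDING at positions i of a / j of b,
        # with `state` the type of the last column (M, I = gap in b, D = gap in a)
        options = []
        if state == "M":
            s = sub(a[i], b[j])
            if i > 0 and j > 0:
                options.append(s + best(i - 1, j - 1, "M"))
                options.append(s + best(i - 1, j - 1, "I"))
                options.append(s + best(i - 1, j - 1, "D"))
            options.append(s)  # alignment starting here
        elif state == "I":  # a[i] aligned to a gap
            if i > 0:
                options.append(best(i - 1, j, "M") - gap_open - gap_extend)
                options.append(best(i - 1, j, "I") - gap_extend)
                options.append(best(i - 1, j, "D") - gap_open - gap_extend)
        else:  # D: b[j] aligned to a gap
            if j > 0:
                options.append(best(i, j - 1, "M") - gap_open - gap_extend)
                options.append(best(i, j - 1, "I") - gap_extend)
                options.append(best(i, j - 1, "D") - gap_open - gap_extend)
        return max(options) if options else -math.inf

    top = 0.0
    for i in range(len(a)):
        for j in range(len(b)):
            top = max(top, best(i, j, "M"))
    return top


def histogram_oracle(pairs: np.ndarray, n_bins: int) -> np.ndarray:
    """Per-pair loop binning with explicit edge arithmetic."""
    width = 360.0 / n_bins
    grid = np.zeros((n_bins, n_bins), dtype=int)
    for phi, psi in pairs:
        i = int((phi + 180.0) // width)
        j = int((psi + 180.0) // width)
        grid[min(i, n_bins - 1), min(j, n_bins - 1)] += 1
    return grid


def periodic_smooth_oracle(grid: np.ndarray, k: int) -> np.ndarray:
    """Uniform k x k moving average with wrap-around via explicit indices."""
    n = grid.shape[0]
    out = np.zeros_like(grid, dtype=float)
    r = k // 2
    for i in range(n):
        for j in range(n):
            acc = 0.0
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    acc += grid[(i + di) % n, (j + dj) % n]
            out[i, j] = acc / (k * k)
    return out


def f_aa_oracle(query: str, scores: dict, class_sets: dict) -> np.ndarray:
    """Two-loop max/sum implementation of the per-class similarity maxima."""
    maxima = []
    for x in range(1, 7):
        best = 0.0
        for k in class_sets[x]:
            if k == query:
                continue
            best = max(best, scores[(k, query)])
        maxima.append(best)
    total = sum(maxima)
    return np.array([m / total for m in maxima])


def similarity_features_oracle(
    query: str, scores: dict, class_sets: dict, n_bins: int = 10
) -> np.ndarray:
    """Loop-based rescaled per-class histogram blocks."""
    all_ids = sorted({k for s in class_sets.values() for k in s} - {query})
    global_max = max(scores[(k, query)] for k in all_ids)
    blocks = []
    for x in range(1, 7):
        members = sorted(set(class_sets[x]) - {query})
        counts = [0] * n_bins
        for k in members:
            r = scores[(k, query)] / global_max
            b = n_bins - 1 if r >= 1.0 else int(r * n_bins)
            counts[b] += 1
        total = sum(counts)
        blocks.extend(c / total for c in counts)
    return np.array(blocks)


def knn_proba_oracle(
    X_train: np.ndarray, y_train: np.ndarray, X_query: np.ndarray, k: int
) -> np.ndarray:
    """Inverse-distance-weighted kNN votes by explicit sort (k > 1)."""
    classes = sorted(set(y_train))
    out = np.zeros((len(X_query), len(classes)))
    for qi, q in enumerate(X_query):
        dists = [(float(np.linalg.norm(q - x)), i) for i, x in enumerate(X_train)]
        dists.sort()
        nearest = dists[:k]
        if any(d == 0.0 for d, _ in nearest):
            for d, i in nearest:
                if d == 0.0:
                    out[qi, classes.index(y_train[i])] += 1.0
        else:
            for d, i in nearest:
                out[qi, classes.index(y_train[i])] += 1.0 / d
        out[qi] /= out[qi].sum()
    return out


def multilabel_metrics_oracle(Y_true: np.ndarray, Y_pred: np.ndarray) -> dict:
    """Formula-by-formula loop implementation of all thirteen metrics."""
    n = len(Y_true)
    hamming = jacc = prec = rec = f1 = subset = 0.0
    for t, p in zip(Y_true, Y_pred):
        ts = {j for j in range(6) if t[j]}
        ps = {j for j in range(6) if p[j]}
        hamming += len(ts ^ ps) / 6
        jacc += len(ts & ps) / len(ts | ps) if ts | ps else 0.0
        prec += len(ts & ps) / len(ps) if ps else 0.0
        rec += len(ts & ps) / len(ts)
        f1 += 2 * len(ts & ps) / (len(ts) + len(ps))
        subset += 1.0 if ts == ps else 0.0
    hamming, jacc, prec, rec, f1, subset = (
        v / n for v in (hamming, jacc, prec, rec, f1, subset)
    )
    tp = [0] * 6
    fp = [0] * 6
    fn = [0] * 6
    for j in range(6):
        for t, p in zip(Y_true, Y_pred):
            if t[j] and p[j]:
                tp[j] += 1
            elif not t[j] and p[j]:
                fp[j] += 1
            elif t[j] and not p[j]:
                fn[j] += 1
    prec_j = [tp[j] / (tp[j] + fp[j]) if tp[j] + fp[j] else 0.0 for j in range(6)]
    rec_j = [tp[j] / (tp[j] + fn[j]) if tp[j] + fn[j] else 0.0 for j in range(6)]
    macro_p = sum(prec_j) / 6
    macro_r = sum(rec_j) / 6
    macro_f1 = (
        sum(
            2 * prec_j[j] * rec_j[j] / (prec_j[j] + rec_j[j])
            if prec_j[j] + rec_j[j]
            else 0.0
            for j in range(6)
        )
        / 6
    )
    stp, sfp, sfn = sum(tp), sum(fp), sum(fn)
    micro_p = stp / (stp + sfp) if stp + sfp else 0.0
    micro_r = stp / (stp + sfn) if stp + sfn else 0.0
    micro_f1 = (
        2 * micro_p * micro_r / (micro_p + micro_r) if micro_p + micro_r else 0.0
    )
    return {
        "hamming_loss": hamming,
        "one_minus_hamming": 1 - hamming,
        "accuracy": jacc,
        "precision": prec,
        "recall": rec,
        "f1": f1,
        "subset_accuracy": subset,
        "macro_precision": macro_p,
        "macro_recall": macro_r,
        "macro_f1": macro_f1,
        "micro_precision": micro_p,
        "micro_recall": micro_r,
        "micro_f1": micro_f1,
    }


def alpha_grid_oracle(P_si, P_aa, y, step: float) -> float:
    """Exhaustive loop over the alpha grid mirroring the published selection
    rule: accuracy first, mean margin second, largest alpha last."""
    n_steps = round(1.0 / step)
    best = None
    for g in range(n_steps + 1):
        alpha = g / n_steps
        fused = (1 - alpha) * P_si + alpha * P_aa
        correct = 0
        margin = 0.0
        for row, label in zip(fused, y):
            pred = int(np.argmax(row)) + 1
            if pred == label:
                correct += 1
            others = [row[c] for c in range(6) if c != label - 1]
            margin += row[label - 1] - max(others)
        acc = correct / len(y)
        key = (acc, margin / len(y), alpha)
        if best is None or key >= best:
            best = key
    return best[2]
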