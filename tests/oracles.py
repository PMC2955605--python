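"""Independent brute-force reference implementations used only by tests.

Every function here is written as a direct, loop-based transcription of
the method definitions, deliberately sharing no code with the package, so
agreement between the two routes is meaningful.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_c3net(I: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Loop transcription of the per-gene max-MI selection + symmetrization."""
    n = I.shape[0]
    A = np.zeros((n, n), dtype=int)
    for i in range(n):
        neigh = [j for j in range(n) if j != i and C[i, j] == 1]
        if not neigh:
            continue
        best = neigh[0]
        for j in neigh[1:]:
            if I[i, j] > I[i, best]:
                best = j
        A[i, best] = A[best, i] = 1
    return A


def brute_rn(I: np.ndarray, thr: float) -> np.ndarray:
    n = I.shape[0]
    A = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            if i != j and I[i, j] > thr:
                A[i, j] = 1
    return A


def brute_aracne(I: np.ndarray, thr: float, eps: float) -> np.ndarray:
    """RN followed by simultaneous DPI removal over all present triangles."""
    A = brute_rn(I, thr)
    doomed = set()
    n = I.shape[0]
    for i, j, k in itertools.combinations(range(n), 3):
        if A[i, j] and A[i, k] and A[j, k]:
            for (a, b), (c, d), (e, f) in (
                ((i, j), (i, k), (j, k)),
                ((i, k), (i, j), (j, k)),
                ((j, k), (i, j), (i, k)),
            ):
                if I[a, b] < (1 - eps) * min(I[c, d], I[e, f]):
                    doomed.add((a, b))
    out = A.copy()
    for a, b in doomed:
        out[a, b] = out[b, a] = 0
    return out


def brute_clr(I: np.ndarray) -> np.ndarray:
    n = I.shape[0]
    z = np.zeros((n, n))
    for i in range(n):
        row = [I[i, j] for j in range(n) if j != i]
        mu = sum(row) / len(row)
        sigma = math.sqrt(sum((v - mu) ** 2 for v in row) / len(row))
        for j in range(n):
            if j != i and sigma > 0:
                z[i, j] = max(0.0, (I[i, j] - mu) / sigma)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                w[i, j] = math.sqrt(z[i, j] ** 2 + z[j, i] ** 2)
    return w


def brute_mrnet(I: np.ndarray) -> np.ndarray:
    """Greedy forward MRMR selection per target, max-symmetrized scores."""
    n = I.shape[0]
    directed = np.zeros((n, n))
    for t in range(n):
        selected: list[int] = []
        candidates = [j for j in range(n) if j != t]
        while candidates:
            best_j, best_s = None, -np.inf
            for j in candidates:
                red = sum(I[j, k] for k in selected) / len(selected) if selected else 0.0
                s = I[j, t] - red
                if s > best_s:
                    best_j, best_s = j, s
            if best_s <= 0:
                break
            directed[best_j, t] = best_s
            selected.append(best_j)
            candidates.remove(best_j)
    return np.maximum(directed, directed.T)


def histogram_mi_bits(x: np.ndarray, y: np.ndarray, bins: int) -> float:
    """Plug-in hard-binned histogram MI in bits, equal-width bins on the
    min-max range of each variable (max sample in the last bin)."""
    def bin_of(v, lo, hi):
        if hi == lo:
            return bins // 2
        b = int((v - lo) / (hi - lo) * bins)
        return min(b, bins - 1)

    m = len(x)
    joint = np.zeros((bins, bins))
    for xi, yi in zip(x, y):
        joint[bin_of(xi, x.min(), x.max()), bin_of(yi, y.min(), y.max())] += 1
    joint /= m
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mi = 0.0
    for a in range(bins):
        for b in range(bins):
            if joint[a, b] > 0:
                mi += joint[a, b] * math.log2(joint[a, b] / (px[a] * py[b]))
    return mi


def brute_confusion(inferred: set, truth: set) -> tuple[int, int, int]:
    tp = len([e for e in inferred if e in truth])
    fp = len([e for e in inferred if e not in truth])
    fn = len([e for e in truth if e not in inferred])
    return tp, fp, fn


def fscore(tp: int, fp: int, fn: int) -> float:
    if tp == 0:
        return 0.0
    p = tp / (tp + fp)
    r = tp / (tp + fn)
    return 2 * p * r / (p + r)


def brute_optimal_cutoff(pair_scores: dict, truth: set) -> tuple[float, float]:
    """Exhaustive scan over all distinct positive scores (>= semantics)
    plus one above the max; returns (threshold, best F), densest
    maximizer.  Zero scores never form edges, so zero is not a cutoff."""
    candidates = sorted({s for s in pair_scores.values() if s > 0})
    top = (max(candidates) if candidates else 0.0) + 1.0
    best_thr, best_f, best_size = top, 0.0, 0
    for thr in candidates + [top]:
        inferred = {e for e, s in pair_scores.items() if s >= thr and s > 0}
        f = fscore(*brute_confusion(inferred, truth))
        if f > best_f or (f == best_f and len(inferred) > best_size):
            best_thr, best_f, best_size = thr, f, len(inferred)
    return best_thr, best_f
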