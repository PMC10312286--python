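"""Independent brute-force reference implementations used only by tests.

Everything here is written in the most literal form possible (explicit
loops over histogram cells, node triples, ordered pairs, label
permutations) so it shares no code path with the package.
"""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np


def bin_series(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width binning, maximum in the last bin (mirrors the contract,
    re-derived from the definition rather than shared code)."""
    x = np.asarray(x, dtype=float)
    lo, hi = float(min(x)), float(max(x))
    codes = []
    width = (hi - lo) / n_bins
    for v in x:
        c = int((v - lo) // width) if width > 0 else 0
        codes.append(min(c, n_bins - 1))
    return np.array(codes)


def nmi_bruteforce(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    """MI / sqrt(HxHy) by explicit summation over all joint histogram cells."""
    cx, cy = bin_series(x, n_bins), bin_series(y, n_bins)
    t = len(cx)
    joint = np.zeros((n_bins, n_bins))
    for a, b in zip(cx, cy):
        joint[a, b] += 1
    px = joint.sum(axis=1) / t
    py = joint.sum(axis=0) / t
    mi = 0.0
    for i in range(n_bins):
        for j in range(n_bins):
            p = joint[i, j] / t
            if p > 0:
                mi += p * math.log(p / (px[i] * py[j]))
    hx = -sum(p * math.log(p) for p in px if p > 0)
    hy = -sum(p * math.log(p) for p in py if p > 0)
    return mi / math.sqrt(hx * hy)


def mean_strength_loop(w: np.ndarray) -> float:
    n = w.shape[0]
    total, count = 0.0, 0
    for i in range(n):
        for j in range(i + 1, n):
            total += w[i, j]
            count += 1
    return total / count


def density_loop(w: np.ndarray) -> float:
    n = w.shape[0]
    edges = sum(1 for i in range(n) for j in range(i + 1, n) if w[i, j] != 0)
    return edges / (n * (n - 1) / 2)


def clustering_bruteforce(w: np.ndarray) -> np.ndarray:
    """Onnela clustering by explicit enumeration of ordered neighbor pairs."""
    n = w.shape[0]
    wmax = w.max()
    c = np.zeros(n)
    if wmax == 0:
        return c
    for i in range(n):
        k = sum(1 for j in range(n) if w[i, j] > 0)
        if k < 2:
            continue
        s = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    s += (w[i, j] / wmax * w[i, h] / wmax * w[j, h] / wmax) ** (1 / 3)
        c[i] = s / (k * (k - 1))
    return c


def efficiency_floyd_warshall(w: np.ndarray) -> float:
    """Global efficiency via an explicit Floyd-Warshall all-pairs solve."""
    n = w.shape[0]
    d = np.full((n, n), math.inf)
    for i in range(n):
        d[i, i] = 0.0
        for j in range(n):
            if w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and math.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def modularity_double_loop(w: np.ndarray, labels: np.ndarray) -> float:
    n = w.shape[0]
    w2 = w.sum()
    s = w.sum(axis=1)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += w[i, j] - s[i] * s[j] / w2
    return q / w2


def participation_loop(w: np.ndarray, labels: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    p = np.zeros(n)
    for i in range(n):
        s_i = w[i].sum()
        if s_i == 0:
            continue
        acc = 0.0
        for m in set(labels.tolist()):
            s_im = sum(w[i, j] for j in range(n) if labels[j] == m)
            acc += (s_im / s_i) ** 2
        p[i] = 1.0 - acc
    return p


def chi2_loop(table: np.ndarray) -> float:
    """Pearson chi-squared by the explicit sum of (O - E)^2 / E."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    chi2 = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / total
            chi2 += (table[i, j] - e) ** 2 / e
    return chi2


def set_partitions(n: int):
    """All partitions of {0..n-1} as restricted-growth label tuples."""

    def rec(i, max_label, cur):
        if i == n:
            yield tuple(cur)
            return
        for lab in range(max_label + 1):
            cur.append(lab)
            yield from rec(i + 1, max(max_label, lab + 1), cur)
            cur.pop()

    yield from rec(0, 0, [])


def best_label_permutation_overlap(l1: np.ndarray, l2: np.ndarray) -> int:
    """Maximum total contingency overlap over all label permutations of l2."""
    m1 = sorted(set(l1.tolist()))
    m2 = sorted(set(l2.tolist()))
    size = max(len(m1), len(m2))
    best = -1
    for perm in permutations(range(size), len(m2)):
        overlap = 0
        for a_idx, a in enumerate(m1):
            for b_idx, b in enumerate(m2):
                if perm[b_idx] == a_idx:
                    overlap += int(np.sum((l1 == a) & (l2 == b)))
        best = max(best, overlap)
    return best


def vi_from_contingency(l1: np.ndarray, l2: np.ndarray) -> float:
    """Variation of information by direct entropy arithmetic (in nats)."""
    n = len(l1)
    h1 = 0.0
    for a in set(l1.tolist()):
        p = np.sum(l1 == a) / n
        h1 -= p * math.log(p)
    h2 = 0.0
    for b in set(l2.tolist()):
        p = np.sum(l2 == b) / n
        h2 -= p * math.log(p)
    mi = 0.0
    for a in set(l1.tolist()):
        for b in set(l2.tolist()):
            p = np.sum((l1 == a) & (l2 == b)) / n
            if p > 0:
                pa, pb = np.sum(l1 == a) / n, np.sum(l2 == b) / n
                mi += p * math.log(p / (pa * pb))
    return h1 + h2 - 2 * mi


def random_weighted_graph(
    rng: np.random.Generator, n: int, p_edge: float = 0.5
) -> np.ndarray:
    """Symmetric nonnegative weight matrix with zero diagonal; guaranteed
    to contain at least one edge."""
    while True:
        mask = rng.random((n, n)) < p_edge
        w = np.triu(rng.random((n, n)) * mask, 1)
        if w.any():
            return w + w.T
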