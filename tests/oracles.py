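"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the implementation paths (and the libraries)
used by cstkit itself wherever feasible.
"""

import itertools

import numpy as np
import scipy.stats


def brute_upgma_heights(d: np.ndarray) -> list[float]:
    """UPGMA merge heights by recomputing unweighted pairwise-leaf means
    from scratch at every step."""
    n = d.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            dist = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or dist < best[0]:
                best = (dist, a, b)
        dist, a, b = best
        heights.append(dist)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return heights


def brute_silhouette(d: np.ndarray, labels: np.ndarray) -> float:
    """Double-loop mean silhouette with the singleton/degenerate-0 conventions."""
    n = len(labels)
    scores = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            scores.append(0.0)
            continue
        a = sum(d[i, j] for j in own) / len(own)
        b = min(
            sum(d[i, j] for j in range(n) if labels[j] == c)
            / sum(1 for j in range(n) if labels[j] == c)
            for c in set(labels)
            if c != labels[i]
        )
        scores.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(scores))


def brute_bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    tot = float(np.sum(x + y))
    if tot == 0:
        return 0.0
    return float(np.sum(np.abs(x - y)) / tot)


def brute_tukey_significant_pairs(arrays: list[np.ndarray], alpha: float) -> set[tuple[int, int]]:
    """Tukey-Kramer significant pairs from the q statistic and the
    studentized-range critical value."""
    k = len(arrays)
    ns = [len(a) for a in arrays]
    big_n = sum(ns)
    means = [a.mean() for a in arrays]
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrays) / (big_n - k)
    crit = scipy.stats.studentized_range.ppf(1 - alpha, k, big_n - k)
    out = set()
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(msw / 2 * (1 / ns[i] + 1 / ns[j]))
        q = abs(means[i] - means[j]) / se
        if q > crit:
            out.add((i, j))
    return out


def brute_pcoa_eigvals(d: np.ndarray) -> np.ndarray:
    """Classical-scaling eigenvalues via explicit Gower centering."""
    n = d.shape[0]
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    b = a - row - col + a.mean()
    return np.sort(np.linalg.eigvalsh(b))[::-1]
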