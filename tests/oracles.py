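"""Independent reference implementations used only to check the package.

Each oracle is deliberately naive (numerical integration, bisection,
quadratic brute force, O(n^3) agglomeration, exhaustive enumeration) and
shares no code path with the implementation it verifies.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.integrate import quad


def t_pdf(x: float, df: float) -> float:
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    return c * (1 + x * x / df) ** (-(df + 1) / 2)


def t_sf(t: float, df: float) -> float:
    """Upper tail of the t distribution by numerical integration."""
    return quad(lambda x: t_pdf(x, df), t, math.inf)[0]


def two_sided_t_p(t: float, df: float) -> float:
    return 2.0 * t_sf(abs(t), df)


def norm_sf(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def norm_upper_quantile(alpha: float) -> float:
    """Bisection on the complementary error function."""
    lo, hi = -12.0, 12.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if norm_sf(mid) > alpha:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def bh_brute_force(pvals) -> np.ndarray:
    """Quadratic-time step-up definition: q(i) = min over p(j) >= p(i) of
    min(1, m*p(j)/rank(j))."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        candidates = [
            min(1.0, m * p[j] / ranks[j]) for j in range(m) if p[j] >= p[i]
        ]
        q[i] = min(candidates)
    return q


def naive_average_linkage(d: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """O(n^3) agglomerative average linkage; returns merges as
    (cluster_a, cluster_b, height) with lowest-index tie-breaking."""
    n = d.shape[0]
    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            h = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or h < best[2] - 1e-15:
                best = (a, b, h)
        a, b, h = best
        merged = clusters[a] | clusters[b]
        merges.append((clusters[a], clusters[b], h))
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
    return merges


def enumerate_subset_proximity_p(points: np.ndarray, member_idx, metric="diameter"):
    """Exhaustive empirical p over all k-subsets, recomputing distances
    directly from coordinates (no shared pairwise matrix)."""
    k = len(member_idx)
    n = len(points)

    def prox(idx):
        vals = [
            float(np.linalg.norm(points[i] - points[j]))
            for i, j in itertools.combinations(idx, 2)
        ]
        return max(vals) if metric == "diameter" else sum(vals) / len(vals)

    observed = prox(member_idx)
    count = sum(
        1
        for combo in itertools.combinations(range(n), k)
        if prox(combo) <= observed + 1e-12
    )
    return count / math.comb(n, k), observed


def adjusted_rand_index(labels_a, labels_b) -> float:
    """ARI from the contingency table (direct formula)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    classes_a, ia = np.unique(a, return_inverse=True)
    classes_b, ib = np.unique(b, return_inverse=True)
    table = np.zeros((classes_a.size, classes_b.size), dtype=int)
    for x, y in zip(ia, ib):
        table[x, y] += 1
    comb = lambda x: x * (x - 1) / 2.0
    sum_ij = comb(table).sum()
    sum_a = comb(table.sum(axis=1)).sum()
    sum_b = comb(table.sum(axis=0)).sum()
    total = comb(len(a))
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)
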