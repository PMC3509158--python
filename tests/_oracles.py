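"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: UPGMA by
explicit pairwise-average agglomeration, OLS by normal equations, ANOVA by
raw sums of squares.
"""

from __future__ import annotations

import numpy as np


def brute_force_fd(X: np.ndarray) -> float:
    """Summed dendrogram branch length by explicit UPGMA agglomeration.

    Average linkage over all leaf pairs, node height = merge distance,
    leaves at height 0, ties broken by smallest cluster ids.
    """
    n = len(X)
    if n <= 1:
        return 0.0
    D = {
        (i, j): float(np.linalg.norm(X[i] - X[j]))
        for i in range(n)
        for j in range(i + 1, n)
    }
    clusters = {i: [i] for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    nxt = n
    total = 0.0

    def cdist(a: int, b: int) -> float:
        s = sum(
            D[(min(i, j), max(i, j))] for i in clusters[a] for j in clusters[b]
        )
        return s / (len(clusters[a]) * len(clusters[b]))

    while len(clusters) > 1:
        a, b = min(
            ((p, q) for p in clusters for q in clusters if p < q),
            key=lambda pq: (cdist(*pq), pq),
        )
        h = cdist(a, b)
        total += (h - heights[a]) + (h - heights[b])
        clusters[nxt] = clusters.pop(a) + clusters.pop(b)
        heights[nxt] = h
        nxt += 1
    return total


def ols_normal_equations(y: np.ndarray, X: np.ndarray):
    """(coefficients incl. intercept first) via the normal equations."""
    design = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(design.T @ design, design.T @ y)


def anova_sums_of_squares(values: np.ndarray, groups: np.ndarray) -> float:
    """One-way F statistic from raw between/within sums of squares."""
    grand = values.mean()
    levels = np.unique(groups)
    ssb = sum(
        (values[groups == g]).size * (values[groups == g].mean() - grand) ** 2
        for g in levels
    )
    ssw = sum(
        ((values[groups == g] - values[groups == g].mean()) ** 2).sum()
        for g in levels
    )
    dfb = levels.size - 1
    dfw = values.size - levels.size
    return (ssb / dfb) / (ssw / dfw)
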