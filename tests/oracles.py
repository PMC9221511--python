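"""Independent reference implementations used only to check the package.

Each oracle recomputes a statistic from first principles along a different
code path than the library: sum-of-squares ANOVA, brute-force BH step-up,
combinatorial hypergeometric tails, and an O(n^3) average-linkage
agglomeration.
"""

from math import comb

import numpy as np
from scipy import stats


def anova_oracle(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects F and p via the explicit sum-of-squares formula."""
    pooled = np.concatenate(groups)
    n, k = pooled.size, len(groups)
    grand = pooled.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return f, float(stats.f.sf(f, k - 1, n - k))


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Literal BH step-up: q_(i) = min_{j>=i} min(1, p_(j) * m / j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(
            min(1.0, sorted_p[j] * m / (j + 1)) for j in range(i, m)
        )
    out = np.empty(m)
    out[order] = q_sorted
    return out


def hypergeom_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by direct combinatorial summation."""
    total = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)) / total


def average_linkage_oracle(dist: np.ndarray) -> list[tuple[frozenset, float]]:
    """Brute-force average-linkage agglomeration.

    Returns the merged leaf set and merge height of every internal node.
    Ties broken by the lowest pair of current cluster indices.
    """
    n = dist.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        ids = sorted(clusters)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        merged = clusters.pop(a) + clusters.pop(b)
        clusters[next_id] = merged
        merges.append((frozenset(merged), d))
        next_id += 1
    return merges


def linkage_to_merges(linkage: np.ndarray) -> list[tuple[frozenset, float]]:
    """Leaf set and height of every internal node of a scipy linkage matrix."""
    n = linkage.shape[0] + 1
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for row_idx, (a, b, height, _) in enumerate(linkage):
        merged = members[int(a)] | members[int(b)]
        members[n + row_idx] = merged
        merges.append((merged, float(height)))
    return merges
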