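"""Independent reference implementations used to check the package.

These deliberately avoid the production code paths: identity comes from a
full dynamic-programming edit-distance table (not edlib), clustering from
a literal first-fit scan over the oracle identities, and the Mantel
p-value from exhaustive permutation enumeration.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def infix_edit_distance(query: str, target: str) -> int:
    """Exact semi-global edit distance: ``query`` aligned anywhere within
    ``target`` with free terminal gaps on the target.  Full DP table,
    row-vectorized (unit costs allow the prefix-min trick for the
    horizontal transition)."""
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    m = len(t)
    idx = np.arange(m + 1)
    prev = np.zeros(m + 1, dtype=np.int64)  # free start gap in target
    for i in range(1, len(q) + 1):
        sub = prev[:-1] + (q[i - 1] != t)
        up = prev[1:] + 1
        b = np.empty(m + 1, dtype=np.int64)
        b[0] = i
        b[1:] = np.minimum(sub, up)
        # horizontal gaps: cur[j] = min_k<=j (b[k] + (j - k))
        prev = np.minimum.accumulate(b - idx) + idx
    return int(prev.min())


def identity_oracle(a: str, b: str) -> float:
    """1 - d/len(shorter) with d the infix edit distance of the shorter
    sequence within the longer (min over both orders when equal length)."""
    if len(a) > len(b):
        a, b = b, a
    d = infix_edit_distance(a, b)
    if len(a) == len(b):
        d = min(d, infix_edit_distance(b, a))
    return 1.0 - d / len(a)


def greedy_cluster_oracle(entries: list[tuple[str, int]], threshold: float):
    """Literal first-fit scan over precomputed oracle identities.

    ``entries`` are (sequence, size) pairs already sorted size-desc then
    sequence-asc.  Returns a list of member-index lists, one per cluster
    in founding order.
    """
    clusters: list[list[int]] = []
    centroids: list[str] = []
    for i, (seq, _size) in enumerate(entries):
        for c, cent in enumerate(centroids):
            if identity_oracle(seq, cent) >= threshold:
                clusters[c].append(i)
                break
        else:
            centroids.append(seq)
            clusters.append([i])
    return clusters


def mantel_exhaustive(m1: np.ndarray, m2: np.ndarray) -> tuple[float, float]:
    """Mantel r and exhaustive-permutation p over all n! joint row/column
    permutations of the second matrix (ties counted with the same 1e-12
    slack the implementation uses)."""
    n = m1.shape[0]
    iu = np.triu_indices(n, k=1)
    from scipy.stats import pearsonr

    r = pearsonr(m1[iu], m2[iu]).statistic
    count = 0
    total = 0
    for perm in permutations(range(n)):
        p = np.array(perm)
        rp = pearsonr(m1[iu], m2[np.ix_(p, p)][iu]).statistic
        total += 1
        if rp >= r - 1e-12:
            count += 1
    return float(r), count / total
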