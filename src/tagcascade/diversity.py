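"""Alpha and beta diversity on consensus feature tables, plus the Mantel
permutation test used to compare methods.

Observed features counts strictly-positive abundances (any positive
consensus mean reflects presence in at least one rarefaction replicate).
Bray-Curtis is computed from its closed form, which accepts the
fractional consensus abundances.  UniFrac (weighted non-normalized and
unweighted) is delegated to scikit-bio on a supplied tree.  The Mantel
test is implemented here with an explicit seeded generator and the
``(1 + #{r' >= r}) / (1 + n_perm)`` permutation p-value.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.diversity.beta import unweighted_unifrac, weighted_unifrac

from .seq_io import FeatureTable

logger = logging.getLogger(__name__)


def observed_features(table: FeatureTable) -> pd.Series:
    """Per-sample count of features with abundance strictly > 0."""
    return pd.Series(
        (table.counts > 0).sum(axis=0), index=table.sample_ids, name="observed_features"
    )


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity: d(x, y) = 1 - 2 sum(min) / (sum x + sum y).

    A pair of all-zero samples has distance 0 (with a warning).
    """
    n = len(table.sample_ids)
    if n < 2:
        raise ValueError("bray_curtis needs >= 2 samples")
    mat = np.zeros((n, n))
    X = table.counts
    for i, j in combinations(range(n), 2):
        x, y = X[:, i], X[:, j]
        denom = x.sum() + y.sum()
        if denom == 0:
            logger.warning(
                "samples %r and %r are both empty; distance set to 0",
                table.sample_ids[i], table.sample_ids[j],
            )
            d = 0.0
        else:
            d = 1.0 - 2.0 * np.minimum(x, y).sum() / denom
        mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=table.sample_ids)


def unifrac(
    table: FeatureTable,
    tree: TreeNode,
    weighted: bool = False,
    normalized: bool = False,
    strict: bool = True,
) -> DistanceMatrix:
    """Pairwise UniFrac over the table's samples on a supplied tree.

    Unweighted: fraction of observed branch length unique to one of the
    two communities.  Weighted (default non-normalized): sum over branches
    of length x |pA - pB| with pX the fraction of sample X descending
    through the branch.  In strict mode a nonzero feature missing from the
    tree is an error naming it; in lenient mode it is dropped with a
    warning.
    """
    tips = {t.name for t in tree.tips()}
    present = (table.counts.sum(axis=1) > 0)
    missing = [
        f for f, p in zip(table.feature_ids, present) if p and f not in tips
    ]
    if missing:
        if strict:
            raise ValueError(f"features absent from tree: {missing}")
        logger.warning("dropping features absent from tree: %s", missing)
    keep = [f for f in table.feature_ids if f in tips]
    sub = table.select_features(keep)
    n = len(sub.sample_ids)
    if n < 2:
        raise ValueError("unifrac needs >= 2 samples")
    mat = np.zeros((n, n))
    taxa = list(sub.feature_ids)
    for i, j in combinations(range(n), 2):
        u, v = sub.counts[:, i], sub.counts[:, j]
        if weighted:
            d = weighted_unifrac(u, v, taxa=taxa, tree=tree, normalized=normalized)
        else:
            d = unweighted_unifrac(u, v, taxa=taxa, tree=tree)
        mat[i, j] = mat[j, i] = float(d)
    return DistanceMatrix(mat, ids=sub.sample_ids)


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Mantel r (Pearson over upper triangles) with a seeded permutation p.

    Rows+columns of the second matrix are permuted jointly;
    p = (1 + #{permutations with r' >= r}) / (1 + n_perm).  Requires the
    same sample set on both matrices and at least 3 samples.
    """
    if set(d1.ids) != set(d2.ids):
        raise ValueError("distance matrices must share their sample set")
    n = len(d1.ids)
    if n < 3:
        raise ValueError("mantel needs >= 3 samples")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    m2 = d2.filter(d1.ids).data  # align sample order
    m1 = d1.data
    iu = np.triu_indices(n, k=1)

    def corr(a, b):
        return float(np.corrcoef(a, b)[0, 1])

    r = corr(m1[iu], m2[iu])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    from math import factorial

    if factorial(n) <= n_perm:
        # small sample sets: enumerate every permutation exactly
        from itertools import permutations

        rs = [
            corr(m1[iu], m2[np.ix_(perm, perm)][iu])
            for perm in permutations(range(n))
        ]
        p = sum(rp >= r - 1e-12 for rp in rs) / factorial(n)
        return r, p
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rp = corr(m1[iu], m2[np.ix_(perm, perm)][iu])
        if rp >= r - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return r, p
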