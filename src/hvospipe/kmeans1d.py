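"""Exact one-dimensional k-means by dynamic programming.

For scalar data the k-means optimum is a partition of the *sorted* values
into k contiguous blocks, so the globally optimal clustering can be found
by dynamic programming over block boundaries in O(k n^2) with O(1)
within-block costs from prefix sums.  Deterministic: no initialization,
no seed sensitivity.  Used to cluster per-pixel SNR values during ROI
selection.
"""

from __future__ import annotations

import numpy as np

__all__ = ["kmeans_1d"]


def _block_cost(prefix: np.ndarray, prefix2: np.ndarray, i: int, j: int) -> float:
    """Within-cluster sum of squares of sorted values [i, j)."""
    n = j - i
    s = prefix[j] - prefix[i]
    s2 = prefix2[j] - prefix2[i]
    return s2 - s * s / n


def kmeans_1d(values: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Globally optimal k-means partition of scalar data.

    Parameters
    ----------
    values
        1-D array of scalars.
    k
        Number of clusters, 1 <= k <= len(values).

    Returns
    -------
    labels
        Cluster index per input value, in the original order; clusters are
        numbered in increasing order of their centers.
    centers
        Cluster means, ascending.
    cost
        Total within-cluster sum of squares at the optimum.
    """
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    if n == 0:
        raise ValueError("empty input")
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")

    order = np.argsort(values, kind="stable")
    x = values[order]
    prefix = np.concatenate([[0.0], np.cumsum(x)])
    prefix2 = np.concatenate([[0.0], np.cumsum(x * x)])

    # dp[j][m] = optimal cost of clustering x[:m] into j clusters
    dp = np.full((k + 1, n + 1), np.inf)
    split = np.zeros((k + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for j in range(1, k + 1):
        # at least j points needed for j nonempty clusters
        for m in range(j, n + 1):
            best, arg = np.inf, j - 1
            for i in range(j - 1, m):
                if dp[j - 1, i] == np.inf:
                    continue
                c = dp[j - 1, i] + _block_cost(prefix, prefix2, i, m)
                if c < best - 1e-15:
                    best, arg = c, i
            dp[j, m] = best
            split[j, m] = arg

    # backtrack block boundaries
    bounds = [n]
    m = n
    for j in range(k, 0, -1):
        m = split[j, m]
        bounds.append(m)
    bounds = bounds[::-1]  # length k+1, ascending

    labels_sorted = np.empty(n, dtype=int)
    centers = np.empty(k)
    for j in range(k):
        lo, hi = bounds[j], bounds[j + 1]
        labels_sorted[lo:hi] = j
        centers[j] = x[lo:hi].mean()

    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels, centers, float(dp[k, n])
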