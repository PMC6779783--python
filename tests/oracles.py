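"""Independent brute-force oracles used by the test suite.

These deliberately recompute everything from first principles (no shared
code with the implementation paths they check).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps

EPS = 1e-12


def brute_average_linkage(ids, values, cutoff):
    """Naive average-linkage agglomeration.

    Recomputes every inter-cluster mean distance from the base gene-pair
    distance matrix at every step (no Lance-Williams update).  Distances
    within EPS are tied; ties merge the pair whose smallest member id is
    lexicographically least (then the partner's).  Returns frozenset of
    frozensets partition.
    """
    idx = {g: i for i, g in enumerate(ids)}
    dist = 1.0 - np.asarray(values, dtype=float)
    threshold = 1.0 - cutoff
    clusters = [[g] for g in ids]
    while len(clusters) > 1:
        candidates = []
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                pairs = [
                    dist[idx[x], idx[y]] for x in clusters[a] for y in clusters[b]
                ]
                d = math.fsum(pairs) / len(pairs)
                if d <= threshold + EPS:
                    candidates.append((d, a, b))
        if not candidates:
            break
        dmin = min(c[0] for c in candidates)
        tied = [c for c in candidates if c[0] <= dmin + EPS]

        def tie_key(c):
            _, a, b = c
            lo_a, lo_b = min(clusters[a]), min(clusters[b])
            return (min(lo_a, lo_b), max(lo_a, lo_b))

        _, a, b = min(tied, key=tie_key)
        merged = sorted(clusters[a] + clusters[b])
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return frozenset(frozenset(c) for c in clusters)


def partial_corr_by_residual_ranks(x, y, z):
    """Partial Spearman correlation via rank-residual regression: rank all
    three vectors, regress x-ranks and y-ranks on z-ranks by least squares,
    and Pearson-correlate the residuals."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rz = sps.rankdata(z)
    A = np.column_stack([np.ones_like(rz), rz])
    res_x = rx - A @ np.linalg.lstsq(A, rx, rcond=None)[0]
    res_y = ry - A @ np.linalg.lstsq(A, ry, rcond=None)[0]
    return float(
        (res_x @ res_y) / np.sqrt((res_x @ res_x) * (res_y @ res_y))
    )


def spearman_by_rank_pearson(x, y):
    """Spearman rho as Pearson on average ranks."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def smith_waterman_best_length(a, b, match=1, mismatch=-1, gap=-1):
    """Exhaustive O(n*m) local alignment; returns the aligned length
    (columns) of the best-scoring local alignment."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    L = np.zeros((n + 1, m + 1), dtype=int)
    best, best_len = 0.0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = H[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            up = H[i - 1, j] + gap
            left = H[i, j - 1] + gap
            h = max(0.0, diag, up, left)
            H[i, j] = h
            if h == 0:
                L[i, j] = 0
            elif h == diag:
                L[i, j] = L[i - 1, j - 1] + 1
            elif h == up:
                L[i, j] = L[i - 1, j] + 1
            else:
                L[i, j] = L[i, j - 1] + 1
            if h > best:
                best, best_len = h, L[i, j]
    return best_len


def random_identity_matrix(rng, n, low=0.85, decimals=2):
    """Random symmetric identity matrix with deliberate exact ties."""
    vals = rng.uniform(low, 1.0, size=(n, n)).round(decimals)
    vals = np.triu(vals, 1)
    vals = vals + vals.T
    np.fill_diagonal(vals, 1.0)
    return vals
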