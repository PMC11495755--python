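"""Independent brute-force oracles (O(n^2), no spatial indexing).

These deliberately avoid the package's KD-tree / nearest-neighbour code
paths: everything is computed from full pairwise-distance matrices so that
the fast implementations can be checked entry-for-entry against them.
"""
from __future__ import annotations

import numpy as np


def _dist_matrix(xy: np.ndarray) -> np.ndarray:
    diff = xy[:, None, :] - xy[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def brute_neighborhood(xy, labels, clusters, radius):
    """All-pairs directed neighborhood matrix: mean count of cluster-j cells
    within ``radius`` of each cluster-i cell (self excluded)."""
    xy = np.asarray(xy, dtype=float)
    labels = np.asarray(labels, dtype=object)
    K = len(clusters)
    D = _dist_matrix(xy)
    np.fill_diagonal(D, np.inf)  # a cell is never its own neighbour
    within = D <= radius
    N = np.full((K, K), np.nan)
    counts = np.zeros(K, dtype=int)
    for i, ci in enumerate(clusters):
        rows = labels == ci
        counts[i] = rows.sum()
        if counts[i] == 0:
            continue
        for j, cj in enumerate(clusters):
            cols = labels == cj
            N[i, j] = within[np.ix_(rows, cols)].sum() / counts[i]
    return N, counts


def brute_distance_summary(xy, labels, clusters):
    """All-pairs directed mean nearest-neighbour distance matrix."""
    xy = np.asarray(xy, dtype=float)
    labels = np.asarray(labels, dtype=object)
    K = len(clusters)
    D = _dist_matrix(xy)
    np.fill_diagonal(D, np.inf)
    out = np.full((K, K), np.nan)
    for i, ci in enumerate(clusters):
        rows = np.flatnonzero(labels == ci)
        if len(rows) == 0:
            continue
        for j, cj in enumerate(clusters):
            cols = np.flatnonzero(labels == cj)
            if len(cols) == 0:
                continue
            if ci == cj and len(rows) < 2:
                continue
            sub = D[np.ix_(rows, cols)]
            out[i, j] = sub.min(axis=1).mean()
    return out


def brute_band_counts(xy, labels, reference, query, band_width, max_dist):
    """Band occupancy of query cells by nearest-reference distance."""
    xy = np.asarray(xy, dtype=float)
    labels = np.asarray(labels, dtype=object)
    ref_set = {reference} if isinstance(reference, str) else set(reference)
    D = _dist_matrix(xy)
    np.fill_diagonal(D, np.inf)
    ref_cols = np.flatnonzero(np.isin(labels, list(ref_set)))
    q_rows = np.flatnonzero(labels == query)
    n_bands = int(round(max_dist / band_width))
    counts = np.zeros(n_bands + 1, dtype=int)  # last bin = beyond max
    for r in q_rows:
        d = D[r, ref_cols].min() if len(ref_cols) else np.inf
        if np.isfinite(d) and d < max_dist:
            counts[int(d // band_width)] += 1
        else:
            counts[-1] += 1
    return counts


def brute_knn_density_cluster(X, k, order=None):
    """Full-distance-matrix implementation of density-ascent clustering with
    basin consolidation, mirroring the documented two-stage rule."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    if order is None:
        order = np.arange(n)
    D = _dist_matrix(X)
    np.fill_diagonal(D, np.inf)
    neigh = np.argsort(D, axis=1, kind="stable")[:, :k]
    mean_d = np.take_along_axis(D, neigh, axis=1).mean(axis=1)
    with np.errstate(divide="ignore"):
        dens = np.where(mean_d > 0, 1.0 / mean_d, np.inf)

    def key_gt(a, b):
        return dens[a] > dens[b] or (dens[a] == dens[b] and order[a] < order[b])

    parent = np.full(n, -1, dtype=int)
    for i in range(n):
        best = -1
        for j in neigh[i]:
            if key_gt(j, i) and (best == -1 or key_gt(j, best)):
                best = j
        parent[i] = best

    def root_of(i):
        while parent[i] != -1:
            i = parent[i]
        return i

    roots = np.array([root_of(i) for i in range(n)])
    # consolidation: repeatedly unify roots joined by a kNN edge
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in neigh[i]:
                ri, rj = roots[i], roots[j]
                if ri != rj:
                    lo, hi = (ri, rj) if order[ri] < order[rj] else (rj, ri)
                    roots[roots == hi] = lo
                    changed = True
    labels = np.zeros(n, dtype=int)
    first = {}
    for i in np.argsort(order, kind="stable"):
        first.setdefault(roots[i], len(first))
    for i in range(n):
        labels[i] = first[roots[i]]
    return labels


def brute_pseudo_f(X, labels):
    """Pseudo-F from raw definitions: squared Euclidean distances, group
    sums-of-squares by direct enumeration."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object)
    n = len(X)
    D2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    groups = sorted(set(labels))
    ss_t = sum(D2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ss_w += sum(
            D2[a, b] for ii, a in enumerate(idx) for b in idx[ii + 1:]
        ) / len(idx)
    ss_a = ss_t - ss_w
    return (ss_a / (len(groups) - 1)) / (ss_w / (n - len(groups)))
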