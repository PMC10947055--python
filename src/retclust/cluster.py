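"""Topographic hierarchical clustering of deviation grids with d' refinement.

Three stages reproduce the cluster-map procedure:

1. agglomerative merge tree under *within-groups average linkage* with
   squared Euclidean distance -- each step merges the pair of clusters whose
   union has the smallest mean pairwise squared distance over *all* pairs
   inside the union (not just cross-pairs, which is what distinguishes this
   linkage from ordinary average linkage);
2. a Gaussian-likelihood BIC (cluster-specific means, pooled variance,
   p = k + 1 parameters) selects the starting cluster count k0 from the tree;
3. cluster pairs whose separability d' = |x1 - x2| / sqrt(0.5 (s1^2 + s2^2))
   falls below the criterion (default 1) are merged smallest-d'-first until
   every surviving pair is separated by at least the criterion.

Features default to the subcohort mean deviation per grid cell (a scalar per
location); a per-participant-vector mode is available by passing an (n, d)
feature matrix.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .types import ClusterSolution, ClusterStats, DeviationGrid


def _pair_cost(n_a, s1_a, s2_a, n_b, s1_b, s2_b) -> float:
    """Mean pairwise squared Euclidean distance within the merged cluster."""
    m = n_a + n_b
    s1 = s1_a + s1_b
    s2 = s2_a + s2_b
    sum_pairs = m * s2 - float(np.dot(s1, s1))
    return sum_pairs / (m * (m - 1) / 2.0)


try:  # numba accelerates the O(n^2) merge loop on 4096-cell grids
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap


@njit(cache=False)
def _merge_tree_core(X, s2, D):  # pragma: no cover - exercised via the wrapper
    n, d = X.shape
    cnt = np.ones(n, dtype=np.int64)
    s1 = X.copy()
    INF = np.inf
    active = np.ones(n, dtype=np.bool_)
    row_min = np.full(n, INF)
    row_arg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        best = INF
        arg = 0
        for j in range(i + 1, n):
            if D[i, j] < best:
                best = D[i, j]
                arg = j
        row_min[i] = best
        row_arg[i] = arg
    out_i = np.empty(n - 1, dtype=np.int64)
    out_j = np.empty(n - 1, dtype=np.int64)
    out_c = np.empty(n - 1)
    for step in range(n - 1):
        i = 0
        best = INF
        for r in range(n):
            if active[r] and row_min[r] < best:
                best = row_min[r]
                i = r
        j = row_arg[i]
        out_i[step] = i
        out_j[step] = j
        out_c[step] = best
        cnt[i] += cnt[j]
        for c in range(d):
            s1[i, c] += s1[j, c]
        s2[i] += s2[j]
        active[j] = False
        row_min[j] = INF
        for r in range(n):
            D[r, j] = INF
            D[j, r] = INF
        # refresh costs of the merged slot against every active partner
        for r in range(n):
            if r == i or not active[r]:
                continue
            m = cnt[i] + cnt[r]
            sp = 0.0
            for c in range(d):
                s = s1[i, c] + s1[r, c]
                sp += s * s
            sum_pairs = m * (s2[i] + s2[r]) - sp
            cost = sum_pairs / (m * (m - 1) / 2.0)
            if cost < 0.0:
                cost = 0.0
            if r < i:
                D[r, i] = cost
                if cost < row_min[r]:
                    row_min[r] = cost
                    row_arg[r] = i
            else:
                D[i, r] = cost
        # refresh the merged row's cached minimum
        best = INF
        arg = 0
        for r in range(i + 1, n):
            if D[i, r] < best:
                best = D[i, r]
                arg = r
        row_min[i] = best
        row_arg[i] = arg
        # rows whose cached minimum pointed at i or j must be rescanned
        for r in range(n):
            if not active[r] or r == i:
                continue
            if row_arg[r] == i or row_arg[r] == j:
                best = INF
                arg = 0
                for q in range(r + 1, n):
                    if D[r, q] < best:
                        best = D[r, q]
                        arg = q
                row_min[r] = best
                row_arg[r] = arg
    return out_i, out_j, out_c


def hierarchical_merge_tree(features: np.ndarray) -> list[tuple[int, int, float]]:
    """Full agglomerative merge sequence under within-groups linkage.

    ``features`` is (n,) or (n, d).  Returns n - 1 merges ``(i, j, cost)``
    over cluster slots, where the merged cluster keeps the lower slot index
    ``i`` and slot ``j`` dies.  Ties break on the smallest (i, j).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least 2 points to cluster")
    if HAVE_NUMBA and n >= 256:
        Xc = np.ascontiguousarray(X)
        s2 = np.einsum("ij,ij->i", Xc, Xc)
        sq = s2[:, None] + s2[None, :] - 2.0 * (Xc @ Xc.T)
        np.maximum(sq, 0.0, out=sq)
        for r in range(n):  # lower triangle (incl. diagonal) is unused
            sq[r, : r + 1] = np.inf
        out_i, out_j, out_c = _merge_tree_core(Xc, s2.copy(), sq)
        return [(int(a), int(b), float(c)) for a, b, c in zip(out_i, out_j, out_c)]
    cnt = np.ones(n, dtype=np.int64)
    s1 = X.copy()
    s2 = np.einsum("ij,ij->i", X, X)
    active = np.ones(n, dtype=bool)
    # D[i, j] (i < j) = within-cluster mean squared distance of slots i U j;
    # for singletons this is the plain squared Euclidean distance
    sq = s2[:, None] + s2[None, :] - 2.0 * (X @ X.T)
    D = np.triu(sq, k=1)
    D[np.tril_indices(n)] = np.inf
    np.maximum(D, 0.0, out=D)
    D[np.tril_indices(n)] = np.inf

    row_min = D.min(axis=1)
    row_arg = D.argmin(axis=1)
    merges: list[tuple[int, int, float]] = []
    for _ in range(n - 1):
        i = int(np.argmin(row_min))
        j = int(row_arg[i])
        cost = float(row_min[i])
        merges.append((i, j, cost))
        # merge slot j into slot i
        cnt[i] += cnt[j]
        s1[i] += s1[j]
        s2[i] += s2[j]
        active[j] = False
        row_min[j] = np.inf
        D[j, :] = np.inf
        D[:, j] = np.inf
        others = np.flatnonzero(active)
        others = others[others != i]
        if others.size:
            m = cnt[i] + cnt[others]
            s1_new = s1[i][None, :] + s1[others]
            s2_new = s2[i] + s2[others]
            sum_pairs = m * s2_new - np.einsum("ij,ij->i", s1_new, s1_new)
            costs = sum_pairs / (m * (m - 1) / 2.0)
            np.maximum(costs, 0.0, out=costs)
            lo = others[others < i]
            hi = others[others > i]
            D[lo, i] = costs[others < i]
            D[i, hi] = costs[others > i]
            row_min[i] = D[i].min()
            row_arg[i] = int(D[i].argmin())
        else:
            row_min[i] = np.inf
        # rows whose cached minimum involved i or j, or that gained a better
        # candidate in column i, must be refreshed
        stale = np.flatnonzero(active & ((row_arg == i) | (row_arg == j)))
        stale = stale[stale != i]
        if stale.size:
            block = D[stale]
            row_min[stale] = block.min(axis=1)
            row_arg[stale] = block.argmin(axis=1)
        lo = others[others < i] if others.size else np.array([], dtype=int)
        if lo.size:
            better = D[lo, i] < row_min[lo]
            row_min[lo[better]] = D[lo[better], i]
            row_arg[lo[better]] = i
    return merges


def cut_tree_labels(merges: Sequence[tuple[int, int, float]], n: int, k: int) -> np.ndarray:
    """Labels (0..k-1) after applying the first n - k merges.

    Labels are assigned in order of each cluster's smallest member index.
    """
    if not 1 <= k <= n:
        raise ValueError("k must lie in 1..n")
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return int(a)

    for i, j, _ in merges[: n - k]:
        parent[find(j)] = find(i)
    roots = np.array([find(a) for a in range(n)])
    _, labels = np.unique(roots, return_inverse=True)
    return labels


def gaussian_bic(features: np.ndarray, labels: np.ndarray) -> float:
    """BIC of a Gaussian model with cluster means and pooled variance.

    p = k + 1 free parameters per feature dimension grouping (k means plus
    one pooled variance, times d for vector features).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    k = len(np.unique(labels))
    ssw = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        ssw += float(((sub - sub.mean(axis=0)) ** 2).sum())
    sigma2 = max(ssw / (n * d), 1e-12)
    loglik = -0.5 * n * d * (math.log(2 * math.pi * sigma2) + 1.0)
    p = k * d + 1
    return -2.0 * loglik + p * math.log(n)


def select_initial_k_bic(
    features: np.ndarray,
    merges: Sequence[tuple[int, int, float]],
    k_max: int = 10,
    change_ratio: float = 0.04,
) -> int:
    """Starting cluster count from likelihood-BIC over the tree cuts.

    On continuous data the raw BIC keeps improving with every extra mean, so
    a two-stage rule (the classic auto-clustering reading) is used:

    1. a coarse upper bound: the smallest k for which moving to k + 1
       clusters worsens the BIC or improves it by less than ``change_ratio``
       of the first (1 -> 2) improvement, capped at ``k_max``;
    2. refinement by merge distance: among k = 2..coarse, the jump ratio
       R(k) = (cost of the merge taking k -> k-1 clusters) / (cost of the
       merge taking k+1 -> k).  If the largest jump clearly dominates the
       second largest (by > 1.15x) its k wins, otherwise the larger of the
       two candidate ks.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    kmax_eff = min(k_max, n)
    bics = [gaussian_bic(X, cut_tree_labels(merges, n, k))
            for k in range(1, kmax_eff + 1)]
    if len(bics) == 1:
        return 1
    d_first = bics[1] - bics[0]
    if d_first >= 0:
        return 1
    coarse = kmax_eff
    for k in range(2, kmax_eff):
        d = bics[k] - bics[k - 1]  # change when moving from k to k+1 clusters
        if d >= 0 or abs(d) < change_ratio * abs(d_first):
            coarse = k
            break
    if coarse <= 2:
        return coarse
    # stage 2: merges[j] is the j-th merge, leaving n - 1 - j clusters;
    # the merge taking k -> k-1 clusters is merges[n - k]
    def jump(k: int) -> float:
        num = merges[n - k][2]
        den = merges[n - k - 1][2]
        if den == 0.0:
            return math.inf if num > 0 else 1.0
        return num / den
    ratios = {k: jump(k) for k in range(2, coarse + 1)}
    ordered = sorted(ratios, key=ratios.get, reverse=True)
    k1, k2 = ordered[0], ordered[1] if len(ordered) > 1 else ordered[0]
    if ratios[k2] == 0 or ratios[k1] > 1.15 * ratios[k2]:
        return k1
    return max(k1, k2)


def cluster_stats(values: np.ndarray) -> ClusterStats:
    """Mean, (population) SD and size of a cluster's scalar values."""
    v = np.asarray(values, dtype=float)
    return ClusterStats(mean=float(v.mean()), sd=float(v.std()), n=int(v.size))


def dprime(a: ClusterStats, b: ClusterStats) -> float:
    """Separability index d' = |x_a - x_b| / sqrt(0.5 (sd_a^2 + sd_b^2)).

    Degenerate case of two zero-variance clusters: 0 for equal means,
    +inf for distinct means.
    """
    denom = math.sqrt(0.5 * (a.sd**2 + b.sd**2))
    num = abs(a.mean - b.mean)
    if denom == 0.0:
        return 0.0 if num == 0.0 else math.inf
    return num / denom


def _dprime_matrix(stats: list[ClusterStats]) -> np.ndarray:
    k = len(stats)
    M = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            M[i, j] = M[j, i] = dprime(stats[i], stats[j])
    return M


def refine_by_dprime(
    cell_values: np.ndarray,
    labels: np.ndarray,
    criterion: float = 1.0,
) -> tuple[np.ndarray, list[ClusterStats], np.ndarray]:
    """Merge the smallest-d' cluster pair while it falls below the criterion.

    ``cell_values`` are the scalar per-location values that define cluster
    means and SDs (subcohort mean deviations, um); ``labels`` is the starting
    assignment.  Returns relabelled assignments (0..k-1 by descending cluster
    mean), the cluster stats and the final pairwise d' matrix, which
    satisfies min d' >= criterion (or k = 1).
    """
    v = np.asarray(cell_values, dtype=float)
    labels = np.asarray(labels).copy()
    while True:
        uniq = np.unique(labels)
        stats = [cluster_stats(v[labels == lab]) for lab in uniq]
        if len(uniq) == 1:
            break
        M = _dprime_matrix(stats)
        iu = np.triu_indices(len(uniq), k=1)
        flat = M[iu]
        pos = int(np.argmin(flat))
        if flat[pos] >= criterion:
            break
        a, b = iu[0][pos], iu[1][pos]
        labels[labels == uniq[b]] = uniq[a]
    # ordinal relabel: 0 = most positive mean
    uniq = np.unique(labels)
    stats = [cluster_stats(v[labels == lab]) for lab in uniq]
    order = np.argsort([-s.mean for s in stats], kind="stable")
    remap = {uniq[o]: rank for rank, o in enumerate(order)}
    new_labels = np.array([remap[lab] for lab in labels])
    stats = [stats[o] for o in order]
    M = _dprime_matrix(stats)
    if len(stats) > 1:
        assert M[np.triu_indices(len(stats), k=1)].min() >= criterion
    return new_labels, stats, M


def cluster_grid(
    grid_values: np.ndarray,
    grid_valid: np.ndarray,
    k_max: int = 10,
    criterion: float = 1.0,
    feature_matrix: np.ndarray | None = None,
) -> ClusterSolution:
    """Cluster the valid cells of a 64 x 64 (subcohort mean) deviation grid.

    ``feature_matrix`` optionally supplies an (n_valid, d) per-participant
    feature vector per cell (vector mode); cluster statistics and d'
    refinement always use the scalar subcohort mean per cell, which is what
    the reported cluster means +- SD (um) describe.
    """
    values = np.asarray(grid_values, dtype=float)
    valid = np.asarray(grid_valid, dtype=bool)
    cell_values = values[valid]
    if cell_values.size < 2:
        raise ValueError("need at least 2 valid cells")
    features = cell_values if feature_matrix is None else np.asarray(feature_matrix)
    merges = hierarchical_merge_tree(features)
    k0 = select_initial_k_bic(features, merges, k_max=k_max)
    labels0 = cut_tree_labels(merges, len(cell_values), k0)
    labels, stats, M = refine_by_dprime(cell_values, labels0, criterion=criterion)
    label_map = np.zeros(values.shape, dtype=int)
    label_map[valid] = labels + 1
    return ClusterSolution(labels=label_map, clusters=stats, dprime_matrix=M, k0=k0)


def participant_feature_matrix(
    grids: list[DeviationGrid], valid: np.ndarray
) -> np.ndarray:
    """(n_cells, n_participants) matrix of deviations at the valid cells.

    Rows follow the row-major order of the valid cells (matching
    ``grid_values[valid]``).  A participant's missing value at a cell is
    imputed with the cell's mean over contributing participants.
    """
    valid = np.asarray(valid, dtype=bool)
    stack = np.stack(
        [np.where(g.valid, g.values, np.nan) for g in grids]
    )  # (p, 64, 64)
    mat = stack[:, valid].T  # (cells, participants)
    cell_mean = np.nanmean(mat, axis=1)
    nan_rows, nan_cols = np.nonzero(np.isnan(mat))
    mat[nan_rows, nan_cols] = cell_mean[nan_rows]
    return mat


def subcohort_mean_grid(
    grids: list[DeviationGrid], min_frac: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Mean deviation per cell across a subcohort, cell-wise over contributors.

    A cell is valid when at least ``min_frac`` of the participants contribute
    a valid value there.
    """
    if not grids:
        raise ValueError("empty subcohort")
    stack = np.stack([g.values for g in grids])
    vstack = np.stack([g.valid for g in grids])
    counts = vstack.sum(axis=0)
    total = np.where(vstack, stack, 0.0).sum(axis=0)
    valid = counts >= max(1, math.ceil(min_frac * len(grids)))
    mean = np.where(valid, total / np.maximum(counts, 1), 0.0)
    return mean, valid
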