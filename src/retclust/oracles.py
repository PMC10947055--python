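"""Brute-force reference implementations used only for cross-checking.

Each function here recomputes a statistic by direct enumeration or from
first principles, deliberately sharing no code with the production modules,
so tests and the acceptance checks can compare the two routes.
"""

from __future__ import annotations

import math

import numpy as np


def within_groups_merge_sequence(points: np.ndarray) -> list[tuple[int, int, float]]:
    """O(n^3) recomputation of the within-groups-linkage merge sequence.

    At every step, for every active cluster pair, the mean pairwise squared
    Euclidean distance over all point pairs inside the union is recomputed by
    explicit double loops; the minimal (cost, i, j) pair merges, the union
    keeping slot i.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    clusters: dict[int, list[int]] = {i: [i] for i in range(len(X))}
    merges = []
    while len(clusters) > 1:
        best = None
        keys = sorted(clusters)
        for ai, a in enumerate(keys):
            for b in keys[ai + 1:]:
                members = clusters[a] + clusters[b]
                total = 0.0
                npairs = 0
                for u in range(len(members)):
                    for v in range(u + 1, len(members)):
                        diff = X[members[u]] - X[members[v]]
                        total += float(diff @ diff)
                        npairs += 1
                cost = total / npairs
                if best is None or (cost, a, b) < best:
                    best = (cost, a, b)
        cost, a, b = best
        merges.append((a, b, cost))
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return merges


def cohen_kappa(a: np.ndarray, b: np.ndarray) -> float | None:
    """Cohen's kappa for two binary labelings from explicit p_o and p_e."""
    a = np.asarray(a, dtype=bool).ravel()
    b = np.asarray(b, dtype=bool).ravel()
    if len(set(a.tolist())) < 2 or len(set(b.tolist())) < 2:
        return None  # single-category labeling: chance correction degenerates
    po = float(np.mean(a == b))
    pe = 0.0
    for category in (True, False):
        pe += float(np.mean(a == category)) * float(np.mean(b == category))
    return (po - pe) / (1.0 - pe)


def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    xs = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and xs[j + 1] == xs[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman r as Pearson correlation of explicit mid-ranks."""
    rx = _midranks(np.asarray(x, dtype=float))
    ry = _midranks(np.asarray(y, dtype=float))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def gaussian_bic_direct(values: np.ndarray, labels: np.ndarray) -> float:
    """Direct evaluation of the pooled-variance Gaussian BIC for scalars."""
    v = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    n = v.size
    resid = np.concatenate(
        [v[labels == lab] - v[labels == lab].mean() for lab in np.unique(labels)]
    )
    sigma2 = max(float(np.mean(resid**2)), 1e-12)
    loglik = sum(
        -0.5 * (math.log(2 * math.pi * sigma2) + (r**2) / sigma2) for r in resid
    )
    k = len(np.unique(labels))
    return -2.0 * loglik + (k + 1) * math.log(n)


def dprime_direct(x1: float, s1: float, x2: float, s2: float) -> float:
    """Direct evaluation of the separability index."""
    denom = math.sqrt(0.5 * (s1 * s1 + s2 * s2))
    if denom == 0.0:
        return 0.0 if x1 == x2 else math.inf
    return abs(x1 - x2) / denom
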