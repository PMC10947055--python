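"""Defective-cluster classification and between-layer spatial agreement.

A cluster is *defective* when its mean deviation is negative (thinner than
the matched normative data) AND falls below the macula-wide mean deviation;
both conditions are required.  Binarised 64 x 64 maps from two layers are
compared over their commonly valid cells with percentage agreement and
Cohen's kappa (chance agreement from the marginals), with a large-sample
normal approximation for the kappa p-value.  kappa is undefined (N/A) when
chance agreement is 1, i.e. when a map is single-category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

from .types import ClusterSolution


@dataclass
class AgreementResult:
    layer_pair: tuple[str, str]
    contingency: tuple[int, int, int, int]  # (both, A-only, B-only, neither)
    percent_agreement: float
    kappa: Optional[float]
    p_value: Optional[float]

    @property
    def n(self) -> int:
        return sum(self.contingency)


def classify_defective_clusters(
    solution: ClusterSolution, grid_mean: float
) -> list[bool]:
    """Per-cluster defective flags (ordered as ``solution.clusters``).

    ``grid_mean`` is the mean deviation over all valid cells of the
    subcohort-mean grid the solution was built on.
    """
    return [c.mean < 0 and c.mean < grid_mean for c in solution.clusters]


def defective_mask(
    solution: ClusterSolution, grid_values: np.ndarray, grid_valid: np.ndarray
) -> np.ndarray:
    """Binary 64 x 64 map of cells belonging to defective clusters."""
    grid_mean = float(np.asarray(grid_values)[np.asarray(grid_valid, bool)].mean())
    flags = classify_defective_clusters(solution, grid_mean)
    mask = np.zeros(solution.labels.shape, dtype=bool)
    for label_idx, flag in enumerate(flags):
        if flag:
            mask |= solution.labels == label_idx + 1
    return mask


def agreement_stats(
    map_a: np.ndarray,
    map_b: np.ndarray,
    valid: np.ndarray | None = None,
    layer_pair: tuple[str, str] = ("A", "B"),
) -> AgreementResult:
    """Percentage agreement and Cohen's kappa between two binary maps.

    ``valid`` restricts the comparison to commonly valid cells.  The kappa
    p-value tests kappa = 0 via the asymptotic standard error under the
    null (Fleiss), two-sided.
    """
    a_map = np.asarray(map_a, dtype=bool).ravel()
    b_map = np.asarray(map_b, dtype=bool).ravel()
    if a_map.shape != b_map.shape:
        raise ValueError("maps must share a shape")
    mask = np.ones(a_map.shape, bool) if valid is None else np.asarray(valid, bool).ravel()
    a_map, b_map = a_map[mask], b_map[mask]
    n = a_map.size
    if n == 0:
        raise ValueError("no commonly valid cells")
    both = int(np.sum(a_map & b_map))
    a_only = int(np.sum(a_map & ~b_map))
    b_only = int(np.sum(~a_map & b_map))
    neither = int(np.sum(~a_map & ~b_map))
    po = (both + neither) / n
    percent = 100.0 * po
    pa1 = (both + a_only) / n  # marginal: A defective
    pb1 = (both + b_only) / n
    pe = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    # kappa is undefined (reported N/A) when a map is single-category: the
    # chance-corrected scale degenerates
    if pa1 in (0.0, 1.0) or pb1 in (0.0, 1.0):
        return AgreementResult(layer_pair, (both, a_only, b_only, neither),
                               percent, None, None)
    kappa = (po - pe) / (1 - pe)
    # Fleiss null SE for the 2x2 table
    marg = [(pa1, pb1), (1 - pa1, 1 - pb1)]
    s = sum(pi * qi * (pi + qi) for pi, qi in marg)
    var0 = (pe + pe**2 - s) / (n * (1 - pe) ** 2)
    if var0 <= 0:
        p_value = None
    else:
        z = kappa / math.sqrt(var0)
        p_value = float(2 * sps.norm.sf(abs(z)))
    return AgreementResult(layer_pair, (both, a_only, b_only, neither),
                           percent, float(kappa), p_value)
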