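"""Structure-function severity trends.

Per participant: the mean deviation difference within vs outside the
defective-GCIPL cells of that participant's stratum solution (for each
layer), and cross-layer Spearman correlations of deviations over the 64 x 64
grid.  Globally: Spearman correlations (r_g) of those per-participant
quantities against 10-2 MD and PSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import DeviationGrid

QUANTITIES = ("GCIPL_diff", "INL_diff", "ORC_diff",
              "r_GCIPL_INL", "r_GCIPL_ORC", "r_INL_ORC")


@dataclass
class SeverityCorrelation:
    quantity: str
    versus: str  # "MD" or "PSD"
    r_g: float
    p_value: float
    n: int


def within_outside_difference(grid: DeviationGrid, defective_mask: np.ndarray) -> float:
    """mean(deviation inside defective cells) - mean(outside), um.

    Negative values mean greater loss inside the defective region.  Requires
    at least one valid cell in each class; otherwise the participant
    contributes no value (raises ValueError; the caller excludes and logs).
    """
    mask = np.asarray(defective_mask, dtype=bool)
    inside = grid.valid & mask
    outside = grid.valid & ~mask
    if not inside.any() or not outside.any():
        raise ValueError("need valid cells both inside and outside the mask")
    return float(grid.values[inside].mean() - grid.values[outside].mean())


def spearman_r(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-rank ties; p via t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    if x.size < 5:
        raise ValueError("need at least 5 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant input")
    r, p = sps.spearmanr(x, y)
    return float(r), float(p)


def cross_layer_r(grid_a: DeviationGrid, grid_b: DeviationGrid) -> float:
    """Spearman r between two layers' deviations over commonly valid cells."""
    common = grid_a.valid & grid_b.valid
    if common.sum() < 5:
        raise ValueError("need at least 5 commonly valid cells")
    r, _ = spearman_r(grid_a.values[common], grid_b.values[common])
    return r


def global_severity_correlations(table: pd.DataFrame) -> list[SeverityCorrelation]:
    """r_g of each per-participant quantity against MD and PSD.

    ``table`` holds one row per participant with columns ``MD``, ``PSD`` and
    any subset of the six severity quantities; NaN rows are excluded per
    quantity.  Requires >= 10 defined participants per correlation.
    """
    out: list[SeverityCorrelation] = []
    for quantity in QUANTITIES:
        if quantity not in table.columns:
            continue
        for versus in ("MD", "PSD"):
            sub = table[[quantity, versus]].dropna()
            if len(sub) < 10:
                continue
            r, p = spearman_r(sub[quantity].to_numpy(), sub[versus].to_numpy())
            out.append(SeverityCorrelation(quantity=quantity, versus=versus,
                                           r_g=r, p_value=p, n=len(sub)))
    return out


def correlations_frame(corrs: list[SeverityCorrelation]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"quantity": c.quantity, "versus": c.versus, "r_g": c.r_g,
          "p_value": c.p_value, "n": c.n} for c in corrs]
    )
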