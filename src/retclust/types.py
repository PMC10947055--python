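"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import EXTENT_MM

LAYERS = ("GCIPL", "INL", "ORC")

#: probability-flag codes for the pattern-deviation probability map, ordered
#: by severity: none < p5 (p<5%) < p2 (p<2%) < p1 (p<1%) < p05 (p<0.5%)
FLAG_NONE, FLAG_P5, FLAG_P2, FLAG_P1, FLAG_P05 = 0, 1, 2, 3, 4


@dataclass
class ThicknessMap:
    """En-face per-pixel layer thickness (um) with a validity mask.

    ``fovea_xy`` is a continuous (col, row) coordinate.  ``tilt_deg`` is the
    disc-to-fovea tilt; standardised maps have tilt 0 and right-eye layout.
    """

    values: np.ndarray
    valid: np.ndarray
    layer: str
    fovea_xy: tuple[float, float]
    laterality: str = "OD"
    tilt_deg: float = 0.0
    extent_mm: float = EXTENT_MM

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must share a shape")
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be OD or OS, got {self.laterality!r}")
        fx, fy = self.fovea_xy
        nrow, ncol = self.values.shape
        if not (0 <= fx <= ncol - 1 and 0 <= fy <= nrow - 1):
            raise ValueError("fovea_xy must lie inside the raster")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class VFResult:
    """10-2 visual-field result: 68 points plus summary indices (dB).

    ``points`` columns: x, y (deg), td (total deviation), pd (pattern
    deviation) and flag (probability-flag code, see FLAG_*).
    """

    points: pd.DataFrame
    md: float
    psd: float

    def __post_init__(self) -> None:
        required = {"x", "y", "td", "pd", "flag"}
        if not required.issubset(self.points.columns):
            raise ValueError(f"points must have columns {sorted(required)}")
        if len(self.points) != 68:
            raise ValueError(f"expected 68 test points, got {len(self.points)}")


@dataclass
class ParticipantRecord:
    pid: str
    age: float
    sex: str  # 'M' or 'F'
    se: float  # spherical equivalent, dioptres
    eye: str = "OD"
    tilt_deg: float = 0.0
    maps: dict = field(default_factory=dict)  # layer -> ThicknessMap
    vf: Optional[VFResult] = None

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if self.eye not in ("OD", "OS"):
            raise ValueError("eye must be 'OD' or 'OS'")


@dataclass
class DeviationGrid:
    """64 x 64 grid of raw thickness deviations (um, glaucoma - normative)."""

    values: np.ndarray
    valid: np.ndarray
    layer: str
    participant_id: str = ""
    subgroup_size: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != (64, 64) or self.valid.shape != (64, 64):
            raise ValueError("deviation grids are exactly 64 x 64")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("valid cells must carry finite values")


@dataclass
class ClusterStats:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0 or self.n < 1:
            raise ValueError("cluster stats require sd >= 0 and n >= 1")


@dataclass
class ClusterSolution:
    """Finalised clustering of a 64 x 64 grid.

    ``labels`` carries 1-based cluster labels sorted by descending cluster
    mean (label 1 = most positive); 0 marks invalid cells.  ``clusters[i]``
    describes label i+1.  ``dprime_matrix`` is the pairwise d' matrix in the
    same order, ``k0`` the BIC-selected starting cluster count.
    """

    labels: np.ndarray
    clusters: list
    dprime_matrix: np.ndarray
    k0: int

    @property
    def k(self) -> int:
        return len(self.clusters)
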