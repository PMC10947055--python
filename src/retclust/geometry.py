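"""Scan geometry constants and coordinate helpers.

The macular cube spans 6.00 x 6.00 mm, acquired as 128 horizontal B-scans of
512 A-scans each (raw raster 128 rows x 512 columns).  All downstream analysis
runs on the standardised 512 x 512 raster, which is averaged over 8 x 8 pixel
blocks into a 64 x 64 grid of 93.75 x 93.75 um cells.

Coordinate conventions (right-eye format):
  * row 0 = superior retina, column 0 = temporal retina;
  * map coordinates are 0-based (col, row) with the fovea a continuous point;
  * retinal x_mm increases nasally, y_mm increases superiorly (y up);
  * visual-field coordinates are in degrees with y > 0 the superior field and
    x > 0 the temporal field (so VF (x, y) projects onto retina (x, -y)).
"""

from __future__ import annotations

import numpy as np

EXTENT_MM = 6.0
RAW_SHAPE = (128, 512)  # (B-scans, A-scans per B-scan)
STD_SHAPE = (512, 512)
BLOCK_PX = 8
GRID_SHAPE = (STD_SHAPE[0] // BLOCK_PX, STD_SHAPE[1] // BLOCK_PX)
CELL_UM = EXTENT_MM * 1000.0 / GRID_SHAPE[0]
assert CELL_UM == 93.75

#: lateral mm per degree of visual angle (configurable in the displacement step)
MM_PER_DEG = 0.288

#: axial sampling of the Cirrus cube: 2.0 mm over 1024 pixels
AXIAL_UM_PER_PX = 2000.0 / 1024.0


def map_center(shape: tuple[int, int]) -> tuple[float, float]:
    """Continuous (col, row) coordinate of the raster centre."""
    nrow, ncol = shape
    return ((ncol - 1) / 2.0, (nrow - 1) / 2.0)


def pixel_mm_grids(
    shape: tuple[int, int],
    fovea_xy: tuple[float, float],
    extent_mm: float = EXTENT_MM,
) -> tuple[np.ndarray, np.ndarray]:
    """Retinal (x_mm, y_mm) of every pixel centre relative to the fovea.

    x_mm increases with column (nasal), y_mm increases towards row 0
    (superior).  Pixels may be anisotropic on the raw raster.
    """
    nrow, ncol = shape
    px_w = extent_mm / ncol
    px_h = extent_mm / nrow
    fx, fy = fovea_xy
    cols = (np.arange(ncol) - fx) * px_w
    rows = (fy - np.arange(nrow)) * px_h
    x_mm, y_mm = np.meshgrid(cols, rows)
    return x_mm, y_mm


def lattice_10_2() -> np.ndarray:
    """The 68 test locations of the 10-2 visual-field grid.

    Points sit on the odd-degree lattice x, y in {+-1, ..., +-9} restricted to
    x^2 + y^2 < 90, which yields exactly 68 locations.  Returned as an (68, 2)
    int array sorted top-to-bottom, left-to-right (descending y, ascending x).
    """
    coords = [
        (x, y)
        for y in range(9, -10, -2)
        for x in range(-9, 10, 2)
        if x * x + y * y < 90
    ]
    out = np.array(coords, dtype=int)
    assert out.shape == (68, 2)
    return out
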