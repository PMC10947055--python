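"""Standardisation of raw thickness maps.

Fixed pipeline order: boundaries -> thickness -> resize (512 x 128 to
512 x 512) -> right-eye orientation -> rotation to zero disc-to-fovea tilt ->
(ORC only) photoreceptor/ganglion-cell displacement correction.  Every stage
propagates the validity mask so that no invalid source pixel ever feeds a
valid output pixel, and the valid-pixel count never increases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import AXIAL_UM_PER_PX, MM_PER_DEG, RAW_SHAPE, STD_SHAPE
from .types import ThicknessMap


@dataclass(frozen=True)
class DisplacementProfile:
    """Radial displacement (deg) as a function of eccentricity (deg).

    Samples must be strictly ascending in eccentricity; displacement is 0
    beyond the last sample.  ``per_meridian`` optionally maps a meridian key
    to its own displacement samples on the same eccentricity axis.
    """

    eccentricity_deg: tuple[float, ...]
    displacement_deg: tuple[float, ...]
    per_meridian: dict | None = None

    def __post_init__(self) -> None:
        ecc = np.asarray(self.eccentricity_deg, dtype=float)
        disp = np.asarray(self.displacement_deg, dtype=float)
        if ecc.size == 0:
            raise ValueError("displacement profile is empty")
        if ecc.size != disp.size:
            raise ValueError("eccentricity and displacement lengths differ")
        if np.any(ecc < 0) or np.any(np.diff(ecc) <= 0):
            raise ValueError("eccentricities must be non-negative, strictly ascending")

    def at(self, ecc_deg: np.ndarray) -> np.ndarray:
        return np.interp(ecc_deg, self.eccentricity_deg, self.displacement_deg,
                         left=self.displacement_deg[0], right=0.0)


def default_displacement_profile() -> DisplacementProfile:
    """Meridian-averaged ganglion-cell displacement profile.

    A piecewise-linear summary of the classical eccentricity-dependent
    displacement between central photoreceptors and their laterally displaced
    inner-retinal partners: rising steeply to a peak of ~1.5 deg near 2 deg
    eccentricity and decaying to zero by ~8 deg.
    """
    return DisplacementProfile(
        eccentricity_deg=(0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0),
        displacement_deg=(0.0, 0.7, 1.2, 1.45, 1.5, 1.1, 0.7, 0.4, 0.2, 0.08, 0.0),
    )


def thickness_from_boundaries(
    upper: np.ndarray,
    lower: np.ndarray,
    axial_scale: float = AXIAL_UM_PER_PX,
    layer: str = "GCIPL",
) -> ThicknessMap:
    """Thickness = (lower - upper) * axial_scale, per A-scan.

    ``upper``/``lower`` give the boundary row (axial pixel) per A-scan; NaN
    marks an erroneous segmentation, which invalidates that pixel.  A valid
    pixel with lower < upper is a data error.
    """
    upper = np.asarray(upper, dtype=float)
    lower = np.asarray(lower, dtype=float)
    if upper.shape != lower.shape:
        raise ValueError("boundary arrays must share a shape")
    valid = np.isfinite(upper) & np.isfinite(lower)
    bad = valid & (lower < upper)
    if np.any(bad):
        r, c = np.argwhere(bad)[0]
        raise ValueError(f"lower boundary above upper at pixel (row={r}, col={c})")
    values = np.where(valid, (lower - upper) * axial_scale, 0.0)
    fovea = ((upper.shape[1] - 1) / 2.0, (upper.shape[0] - 1) / 2.0)
    return ThicknessMap(values=values, valid=valid, layer=layer, fovea_xy=fovea)


def _spline_valid(valid: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """True where every source pixel in the cubic support window is valid.

    The cubic spline at coordinate s draws on source pixels within |s - j| < 2
    per axis; a conservative window of floor(s)-1 .. floor(s)+2 is required to
    be entirely valid (no extrapolation: out-of-field samples are invalid).
    """
    nrow, ncol = valid.shape
    rows, cols = coords
    out = np.ones(rows.shape, dtype=bool)
    in_field = (
        (rows >= -0.5) & (rows <= nrow - 0.5) & (cols >= -0.5) & (cols <= ncol - 0.5)
    )
    fr = np.floor(rows).astype(int)
    fc = np.floor(cols).astype(int)
    for dr in (-1, 0, 1, 2):
        rr = np.clip(fr + dr, 0, nrow - 1)
        for dc in (-1, 0, 1, 2):
            cc = np.clip(fc + dc, 0, ncol - 1)
            out &= valid[rr, cc]
    return out & in_field


def _resample(tmap_values: np.ndarray, valid: np.ndarray,
              coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bicubic resample of values at (row, col) coords with mask propagation."""
    values = ndimage.map_coordinates(tmap_values, coords, order=3, mode="nearest")
    new_valid = _spline_valid(valid, coords)
    values = np.where(new_valid, values, 0.0)
    return values, new_valid


def _cubic_weights(t: np.ndarray) -> np.ndarray:
    """Keys cubic-convolution weights (a = -0.5) for offsets -1..2 minus t."""
    a = -0.5
    offs = np.array([-1.0, 0.0, 1.0, 2.0])
    x = np.abs(offs[None, :] - t[:, None])
    w = np.where(
        x <= 1,
        (a + 2) * x**3 - (a + 3) * x**2 + 1,
        np.where(x < 2, a * x**3 - 5 * a * x**2 + 8 * a * x - 4 * a, 0.0),
    )
    return w


def resize_map(tmap: ThicknessMap) -> ThicknessMap:
    """Resize the raw 128 x 512 raster to 512 x 512 (bicubic on the slow axis).

    Output row r samples source row (r + 0.5) * 128/512 - 0.5 (pixel-centre
    aligned) by cubic convolution, which reproduces constant and linear
    profiles exactly away from the clamped edges; columns are untouched.
    Validity is propagated so no erroneous source pixel contributes.
    """
    if tmap.shape != RAW_SHAPE:
        raise ValueError(f"expected raw shape {RAW_SHAPE}, got {tmap.shape}")
    nrow_out, ncol = STD_SHAPE
    nrow_in = RAW_SHAPE[0]
    scale = nrow_in / nrow_out
    src_rows = (np.arange(nrow_out) + 0.5) * scale - 0.5
    base = np.floor(src_rows).astype(int)
    w = _cubic_weights(src_rows - base)  # (nrow_out, 4)
    values = np.zeros((nrow_out, ncol))
    invalid_touch = np.zeros((nrow_out, ncol), dtype=bool)
    src_invalid = ~tmap.valid
    for k in range(4):
        idx = np.clip(base + k - 1, 0, nrow_in - 1)
        values += w[:, k : k + 1] * tmap.values[idx]
        contributes = np.abs(w[:, k]) > 1e-12
        invalid_touch |= contributes[:, None] & src_invalid[idx]
    valid = ~invalid_touch
    values = np.where(valid, values, 0.0)
    fx, fy = tmap.fovea_xy
    fy_new = (fy + 0.5) / scale - 0.5
    return ThicknessMap(values=values, valid=valid, layer=tmap.layer,
                        fovea_xy=(fx, fy_new), laterality=tmap.laterality,
                        tilt_deg=tmap.tilt_deg, extent_mm=tmap.extent_mm)


def orient_right_eye(tmap: ThicknessMap) -> ThicknessMap:
    """Mirror left eyes about the vertical axis into right-eye format."""
    if tmap.laterality == "OD":
        return tmap
    ncol = tmap.shape[1]
    fx, fy = tmap.fovea_xy
    return ThicknessMap(values=tmap.values[:, ::-1].copy(),
                        valid=tmap.valid[:, ::-1].copy(), layer=tmap.layer,
                        fovea_xy=(ncol - 1 - fx, fy), laterality="OD",
                        tilt_deg=-tmap.tilt_deg, extent_mm=tmap.extent_mm)


def rotate_to_zero_tilt(tmap: ThicknessMap) -> ThicknessMap:
    """Rotate the map about the fovea so the disc-to-fovea tilt becomes 0.

    A feature at polar angle theta (y-up convention) about the fovea moves to
    theta - tilt.  Pixels leaving the field, or fed by any invalid source
    pixel, become invalid.
    """
    theta = np.radians(tmap.tilt_deg)
    nrow, ncol = tmap.shape
    fx, fy = tmap.fovea_xy
    cols, rows = np.meshgrid(np.arange(ncol, dtype=float), np.arange(nrow, dtype=float))
    # inverse map: source = R(+tilt) @ (target - fovea), in y-up coordinates
    dx = cols - fx
    dy = fy - rows
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    sx = cos_t * dx - sin_t * dy
    sy = sin_t * dx + cos_t * dy
    src_cols = fx + sx
    src_rows = fy - sy
    values, valid = _resample(tmap.values, tmap.valid, np.array([src_rows, src_cols]))
    return ThicknessMap(values=values, valid=valid, layer=tmap.layer,
                        fovea_xy=tmap.fovea_xy, laterality=tmap.laterality,
                        tilt_deg=0.0, extent_mm=tmap.extent_mm)


def apply_displacement_correction(
    tmap: ThicknessMap,
    profile: DisplacementProfile,
    mm_per_deg: float = MM_PER_DEG,
) -> ThicknessMap:
    """Remap outer-retina content onto its inner-retina partner locations.

    Outward convention: the value at a pixel of eccentricity e (deg) is
    resampled from eccentricity e + displacement(e) along the same ray, i.e.
    ORC samples are pulled centrifugally to align with the connecting INL and
    GCIPL components.  Requires a standardised (right-eye, zero-tilt) map.
    """
    if tmap.tilt_deg != 0.0:
        warnings.warn("displacement correction applied to a non-zero-tilt map")
    nrow, ncol = tmap.shape
    px_w = tmap.extent_mm / ncol
    px_h = tmap.extent_mm / nrow
    fx, fy = tmap.fovea_xy
    cols, rows = np.meshgrid(np.arange(ncol, dtype=float), np.arange(nrow, dtype=float))
    x_mm = (cols - fx) * px_w
    y_mm = (fy - rows) * px_h
    r_mm = np.hypot(x_mm, y_mm)
    ecc_deg = r_mm / mm_per_deg
    disp_mm = profile.at(ecc_deg) * mm_per_deg
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(r_mm > 0, (r_mm + disp_mm) / r_mm, 1.0)
    src_cols = fx + x_mm * scale / px_w
    src_rows = fy - y_mm * scale / px_h
    values, valid = _resample(tmap.values, tmap.valid, np.array([src_rows, src_cols]))
    return ThicknessMap(values=values, valid=valid, layer=tmap.layer,
                        fovea_xy=tmap.fovea_xy, laterality=tmap.laterality,
                        tilt_deg=tmap.tilt_deg, extent_mm=tmap.extent_mm)


def standardize_map(
    tmap: ThicknessMap,
    displacement: DisplacementProfile | None = None,
) -> ThicknessMap:
    """Run resize -> orient -> rotate (-> displace for the ORC) in order."""
    out = resize_map(tmap) if tmap.shape == RAW_SHAPE else tmap
    out = orient_right_eye(out)
    out = rotate_to_zero_tilt(out)
    if out.layer == "ORC":
        out = apply_displacement_correction(
            out, displacement if displacement is not None else default_displacement_profile()
        )
    return out
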