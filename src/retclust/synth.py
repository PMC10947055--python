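"""Synthetic cohorts of healthy and glaucomatous eyes with known ground truth.

The generator emulates the study conditions of the clinical analysis this
package re-implements: en-face GCIPL/INL/ORC thickness maps with
eccentricity-dependent healthy profiles, linear age/refraction/sex effects,
spatially correlated measurement noise and an interindividual random offset;
arcuate hemifield-specific GCIPL defects with attenuated colocalised INL
defects and unchanged (or slightly thickened) ORC; and matching 10-2
visual-field results with simplified MD/PSD indices.

Layer effect defaults mirror the fitted healthy-cohort regression
coefficients used as simulation ground truth (um/year, um/dioptre, um):

===== ========= ======== =========== =============
layer age_slope se_slope sex_offset  individual_sd
===== ========= ======== =========== =============
GCIPL   -0.112    0.513      0.0          4.35
INL     -0.039    0.258      0.0          1.45
ORC     -0.078    0.437     -1.953        6.20
===== ========= ======== =========== =============

``individual_sd`` (the SD of a per-eye constant thickness offset) is
calibrated so that OLS standard errors on n = 548 cohorts match the reported
ones.  Demographics are sampled with age-refraction and sex-refraction
coupling (older eyes more hyperopic, male eyes slightly more myopic), which
is what makes backward-elimination coefficient shifts realistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, zoom

from .geometry import (
    EXTENT_MM,
    MM_PER_DEG,
    RAW_SHAPE,
    STD_SHAPE,
    lattice_10_2,
    map_center,
    pixel_mm_grids,
)
from .types import (
    FLAG_NONE,
    FLAG_P05,
    FLAG_P1,
    FLAG_P2,
    FLAG_P5,
    LAYERS,
    ParticipantRecord,
    ThicknessMap,
    VFResult,
)

#: reference age (years) for the age effect; only differences matter downstream
REF_AGE = 50.0

#: piecewise-linear healthy baseline profiles, um vs eccentricity (mm).
#: GCIPL/INL: foveal pit, perifoveal peak near 1 mm, peripheral decline;
#: ORC: thickest at the fovea, declining outwards.
BASELINE_PROFILES: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "GCIPL": ((0.0, 0.3, 0.6, 1.2, 2.0, 3.0, 4.3), (15.0, 35.0, 70.0, 95.0, 75.0, 55.0, 45.0)),
    "INL": ((0.0, 0.3, 0.6, 1.2, 2.0, 3.0, 4.3), (8.0, 18.0, 30.0, 40.0, 36.0, 32.0, 30.0)),
    "ORC": ((0.0, 0.6, 1.2, 2.0, 3.0, 4.3), (210.0, 195.0, 180.0, 168.0, 160.0, 155.0)),
}

#: pattern-deviation probability-flag thresholds (dB); configurable
DEFAULT_FLAG_THRESHOLDS = {FLAG_P5: -3.0, FLAG_P2: -4.5, FLAG_P1: -6.0, FLAG_P05: -8.0}


@dataclass(frozen=True)
class DemographicsSpec:
    """Cohort demographic sampling model.

    Ages are truncated-normal within ``age_range``; spherical equivalent is
    built as ``se_age_slope * (age - age_mean) + se_male_shift * male + eps``
    truncated to ``se_range``, with eps scaled so the marginal SD is
    ``se_sd``.  Defaults follow the healthy reference cohort (n = 548,
    age 50.4 +- 16.9 y, 45% male, SE -0.55 +- 1.94 D, tilt 6.9 +- 3.4 deg).
    """

    n: int
    age_range: tuple[float, float] = (20.0, 86.0)
    sex_ratio: float = 0.45
    se_range: tuple[float, float] = (-6.0, 6.0)
    tilt_sd: float = 3.4
    seed: int = 0
    age_mean: float = 50.4
    age_sd: float = 16.9
    se_mean: float = -0.55
    se_sd: float = 1.94
    se_age_slope: float = 0.058  # D per year: older eyes more hyperopic
    se_male_shift: float = -0.6  # D: male eyes more myopic on average
    tilt_mean: float = 6.9

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be a non-empty interval")
        if self.se_range[0] > self.se_range[1]:
            raise ValueError("se_range must be a non-empty interval")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")


@dataclass(frozen=True)
class LayerEffectModel:
    """Generative model of one layer's thickness across the cohort."""

    layer: str
    baseline_profile: tuple[tuple[float, ...], tuple[float, ...]] = None  # type: ignore[assignment]
    age_slope: float = 0.0  # um / year
    se_slope: float = 0.0  # um / dioptre
    sex_offset: float = 0.0  # um, male - female
    noise_sd: float = 2.0  # um per pixel, after spatial smoothing
    spatial_correlation_length_um: float = 250.0
    individual_sd: float = 0.0  # um, per-eye constant offset
    ref_age: float = REF_AGE

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.baseline_profile is None:
            object.__setattr__(self, "baseline_profile", BASELINE_PROFILES[self.layer])
        ecc, thick = self.baseline_profile
        if len(ecc) != len(thick) or min(thick) < 0:
            raise ValueError("baseline_profile must be non-negative samples")
        if self.noise_sd < 0 or self.individual_sd < 0:
            raise ValueError("noise SDs must be >= 0")

    def baseline_at(self, ecc_mm: np.ndarray) -> np.ndarray:
        ecc, thick = self.baseline_profile
        return np.interp(ecc_mm, ecc, thick)


def default_layer_models() -> dict[str, LayerEffectModel]:
    """Ground-truth effect models for the three layers (see module docstring)."""
    return {
        "GCIPL": LayerEffectModel("GCIPL", age_slope=-0.112, se_slope=0.513,
                                  sex_offset=0.0, noise_sd=2.0, individual_sd=4.35),
        "INL": LayerEffectModel("INL", age_slope=-0.039, se_slope=0.258,
                                sex_offset=0.0, noise_sd=1.5, individual_sd=1.45),
        "ORC": LayerEffectModel("ORC", age_slope=-0.078, se_slope=0.437,
                                sex_offset=-1.953, noise_sd=2.5, individual_sd=6.20),
    }


@dataclass(frozen=True)
class DefectSpec:
    """Arcuate structural/functional defect with cross-layer coupling.

    The structural mask is an annular band (``inner_ecc_deg`` to
    ``outer_ecc_deg``) restricted to the named retinal hemifields, sweeping
    ``angular_extent_deg`` of polar angle from the nasal horizontal meridian.
    GCIPL thins by ``gcipl_depth``; the INL thins by ``inl_ratio`` of that;
    the ORC gains ``orc_delta`` (0 or small positive).  The visual-field
    projection mirrors the vertical axis (superior retina -> inferior field)
    and loses ``vf_depth`` dB, optionally deeper nasally (``nasal_taper``).
    """

    hemifields: frozenset = frozenset({"superior_retina"})
    inner_ecc_deg: float = 1.0
    outer_ecc_deg: float = 8.0
    angular_extent_deg: float = 180.0
    gcipl_depth: float = 10.0  # um
    inl_ratio: float = 0.3
    orc_delta: float = 0.0  # um thickening
    vf_depth: float = 8.0  # dB
    nasal_taper: float = 0.0  # relative depth increase at the nasal edge

    def __post_init__(self) -> None:
        object.__setattr__(self, "hemifields", frozenset(self.hemifields))
        bad = self.hemifields - {"superior_retina", "inferior_retina"}
        if bad:
            raise ValueError(f"unknown hemifields {sorted(bad)}")
        if self.gcipl_depth < 0:
            raise ValueError("gcipl_depth must be >= 0")
        if not 0.0 <= self.inl_ratio <= 1.0:
            raise ValueError("inl_ratio must lie in [0, 1]")

    def depth_for_layer(self, layer: str) -> float:
        """Signed thinning depth (um) applied inside the mask for a layer."""
        if layer == "GCIPL":
            return self.gcipl_depth
        if layer == "INL":
            return self.inl_ratio * self.gcipl_depth
        if layer == "ORC":
            return -self.orc_delta  # negative thinning = thickening
        raise ValueError(f"unknown layer {layer!r}")

    def weight(self, x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
        """Binary defect weight at retinal positions (x nasal, y up).

        ``nasal_taper`` only shapes the visual-field projection (see
        ``synth_vf``); the structural mask itself is uniform-depth.
        """
        ecc_deg = np.hypot(x_mm, y_mm) / MM_PER_DEG
        band = (ecc_deg >= self.inner_ecc_deg) & (ecc_deg <= self.outer_ecc_deg)
        az = np.degrees(np.arctan2(y_mm, x_mm))  # 0 = nasal horizontal
        hemi = np.zeros_like(band)
        if "superior_retina" in self.hemifields:
            hemi |= (az > 0) & (az <= self.angular_extent_deg)
        if "inferior_retina" in self.hemifields:
            hemi |= (az < 0) & (az >= -self.angular_extent_deg)
        return (band & hemi).astype(float)

    def retinal_mask(self, shape: tuple[int, int], fovea_xy=None,
                     extent_mm: float = EXTENT_MM) -> np.ndarray:
        """Boolean ground-truth mask of the structural defect on a raster."""
        if fovea_xy is None:
            fovea_xy = map_center(shape)
        x_mm, y_mm = pixel_mm_grids(shape, fovea_xy, extent_mm)
        return self.weight(x_mm, y_mm) > 0

    def grid_mask(self, grid_shape: tuple[int, int] = (64, 64)) -> np.ndarray:
        """Ground-truth mask on the analysis grid (cell in iff >=50% covered).

        Computed by block-averaging a 512 x 512 rasterisation of the mask,
        mirroring how grid cells aggregate pixels.
        """
        fine = self.retinal_mask(STD_SHAPE).astype(float)
        b0 = STD_SHAPE[0] // grid_shape[0]
        b1 = STD_SHAPE[1] // grid_shape[1]
        frac = fine.reshape(grid_shape[0], b0, grid_shape[1], b1).mean(axis=(1, 3))
        return frac >= 0.5


def _derived_seed(*parts: int) -> int:
    """Stable 32-bit child seed from a tuple of integers."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0])


def sample_demographics(spec: DemographicsSpec, pid_prefix: str = "P") -> list[ParticipantRecord]:
    """Sample ``spec.n`` participant records (no maps, no VF). Deterministic."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.age_range
    if lo == hi:
        ages = np.full(spec.n, float(lo))
    else:
        ages = np.empty(spec.n)
        filled = 0
        while filled < spec.n:
            draw = rng.normal(spec.age_mean, spec.age_sd, size=2 * (spec.n - filled))
            draw = draw[(draw >= lo) & (draw <= hi)][: spec.n - filled]
            ages[filled : filled + len(draw)] = draw
            filled += len(draw)
    male = rng.random(spec.n) < spec.sex_ratio
    explained = (spec.se_age_slope * spec.age_sd) ** 2 + (
        spec.se_male_shift**2 * spec.sex_ratio * (1 - spec.sex_ratio)
    )
    eps_sd = math.sqrt(max(spec.se_sd**2 - explained, 0.01))
    se_mu = (
        spec.se_mean
        + spec.se_age_slope * (ages - spec.age_mean)
        + spec.se_male_shift * male
    )
    se = se_mu + rng.normal(0.0, eps_sd, size=spec.n)
    np.clip(se, spec.se_range[0], spec.se_range[1], out=se)
    tilt = rng.normal(spec.tilt_mean, spec.tilt_sd, size=spec.n)
    eyes = np.where(rng.random(spec.n) < 0.5, "OD", "OS")
    return [
        ParticipantRecord(
            pid=f"{pid_prefix}{i:04d}",
            age=float(ages[i]),
            sex="M" if male[i] else "F",
            se=float(se[i]),
            eye=str(eyes[i]),
            tilt_deg=float(tilt[i]),
        )
        for i in range(spec.n)
    ]


def _correlated_noise(rng: np.random.Generator, shape: tuple[int, int],
                      corr_um: float, px_mm: tuple[float, float]) -> np.ndarray:
    """Unit-variance spatially correlated field (smoothed white noise).

    When the correlation length spans many pixels the field is generated on
    a coarser raster and bicubically upsampled, which is equivalent up to
    interpolation error well below the noise scale and keeps large rasters
    cheap.
    """
    sig_r = corr_um / 1000.0 / px_mm[0]
    sig_c = corr_um / 1000.0 / px_mm[1]
    if sig_r < 1e-6 and sig_c < 1e-6:
        return rng.standard_normal(shape)
    factor = max(1, int(min(sig_r, sig_c) // 3))
    sub_shape = (-(-shape[0] // factor), -(-shape[1] // factor))
    white = rng.standard_normal(sub_shape)
    smooth = gaussian_filter(
        white, sigma=(sig_r / factor, sig_c / factor), mode="reflect"
    )
    if factor > 1:
        # the coarse field is already smooth (sigma >= 3 px), so bilinear
        # upsampling is accurate and cheap
        smooth = zoom(smooth, factor, order=1, mode="nearest")[: shape[0], : shape[1]]
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def synth_thickness_map(
    record: ParticipantRecord,
    model: LayerEffectModel,
    defect: Optional[DefectSpec] = None,
    seed: int = 0,
    shape: tuple[int, int] = RAW_SHAPE,
    standardized: bool = False,
    dropout: float = 0.0,
) -> ThicknessMap:
    """Synthesize one eye's thickness map.

    Expected value per pixel: baseline(ecc) + age_slope*(age-ref_age) +
    se_slope*SE + sex_offset*[male] - depth*mask, plus a per-eye constant
    offset (SD ``individual_sd``) and spatially correlated noise.  By default
    the raw 128 x 512 raster is produced with the participant's laterality and
    tilt stamped on; ``standardized=True`` instead generates directly in
    right-eye, zero-tilt geometry (used for cohort-scale experiments).
    """
    rng = np.random.default_rng(seed)
    fovea = map_center(shape)
    px_mm = (EXTENT_MM / shape[0], EXTENT_MM / shape[1])
    x_mm, y_mm = pixel_mm_grids(shape, fovea)
    values = model.baseline_at(np.hypot(x_mm, y_mm))
    values = values + model.age_slope * (record.age - model.ref_age)
    values = values + model.se_slope * record.se
    if record.sex == "M":
        values = values + model.sex_offset
    if model.individual_sd > 0:
        values = values + rng.normal(0.0, model.individual_sd)
    if model.noise_sd > 0:
        values = values + model.noise_sd * _correlated_noise(
            rng, shape, model.spatial_correlation_length_um, px_mm
        )
    if defect is not None:
        values = values - defect.depth_for_layer(model.layer) * defect.weight(x_mm, y_mm)
    valid = np.ones(shape, dtype=bool)
    if dropout > 0:
        valid &= rng.random(shape) >= dropout
    if standardized:
        laterality, tilt = "OD", 0.0
    else:
        laterality, tilt = record.eye, record.tilt_deg
    return ThicknessMap(values=values, valid=valid, layer=model.layer,
                        fovea_xy=fovea, laterality=laterality, tilt_deg=tilt)


def synth_vf(
    defect: Optional[DefectSpec],
    noise_sd: float = 1.0,
    seed: int = 0,
    flag_thresholds: Optional[dict[int, float]] = None,
) -> VFResult:
    """Synthesize a 10-2 visual-field result.

    Pattern deviation is -vf_depth inside the field projection of the defect
    plus Gaussian noise; total deviation equals pattern deviation (no
    generalised depression is simulated).  MD is the unweighted mean of total
    deviations and PSD the sample SD of pattern deviations -- simplified
    versions of the proprietary perimeter indices.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    thresholds = dict(DEFAULT_FLAG_THRESHOLDS if flag_thresholds is None else flag_thresholds)
    rng = np.random.default_rng(seed)
    pts = lattice_10_2()
    x_deg = pts[:, 0].astype(float)
    y_deg = pts[:, 1].astype(float)
    if defect is not None and defect.vf_depth != 0:
        # field (x, y) projects onto retina (x, -y); the taper is applied in
        # field coordinates so the nasal field half (x < 0) is deeper
        base = defect.weight(x_deg * MM_PER_DEG, -y_deg * MM_PER_DEG) > 0
        w = base.astype(float)
        if defect.nasal_taper:
            nasal = -x_deg / np.maximum(np.hypot(x_deg, y_deg), 1e-9)
            w = w * (1.0 + defect.nasal_taper * nasal)
        pdval = -defect.vf_depth * w
    else:
        pdval = np.zeros(68)
    if noise_sd > 0:
        pdval = pdval + rng.normal(0.0, noise_sd, size=68)
    td = pdval.copy()
    flag = np.full(68, FLAG_NONE, dtype=int)
    for code in (FLAG_P5, FLAG_P2, FLAG_P1, FLAG_P05):
        flag[pdval <= thresholds[code]] = code
    df = pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1], "td": td, "pd": pdval, "flag": flag})
    md = float(td.mean())
    psd = float(np.std(pdval, ddof=1))
    return VFResult(points=df, md=md, psd=psd)


def synth_cohort(
    spec: DemographicsSpec,
    models: Optional[dict[str, LayerEffectModel]] = None,
    defect_for: Optional[Callable[[int, ParticipantRecord], Optional[DefectSpec]]] = None,
    vf_noise_sd: float = 1.0,
    with_vf: bool = False,
    shape: tuple[int, int] = RAW_SHAPE,
    standardized: bool = False,
    layers: Sequence[str] = LAYERS,
    pid_prefix: str = "P",
) -> list[ParticipantRecord]:
    """Sample demographics and attach per-layer maps (and optionally VFs).

    ``defect_for(i, record)`` returns the participant's DefectSpec (or None
    for a healthy eye).  All randomness derives from ``spec.seed``.
    """
    if models is None:
        models = default_layer_models()
    records = sample_demographics(spec, pid_prefix=pid_prefix)
    for i, rec in enumerate(records):
        defect = defect_for(i, rec) if defect_for is not None else None
        for j, layer in enumerate(layers):
            seed = _derived_seed(spec.seed, 1, i, j)
            rec.maps[layer] = synth_thickness_map(
                rec, models[layer], defect=defect, seed=seed,
                shape=shape, standardized=standardized,
            )
        if with_vf or defect is not None:
            rec.vf = synth_vf(defect, noise_sd=vf_noise_sd,
                              seed=_derived_seed(spec.seed, 2, i))
    return records


def cohort_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Tabular view of a cohort (id, age, sex, SE, eye, tilt)."""
    return pd.DataFrame(
        [
            {"pid": r.pid, "age": r.age, "sex": r.sex, "se": r.se,
             "eye": r.eye, "tilt_deg": r.tilt_deg}
            for r in records
        ]
    )
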