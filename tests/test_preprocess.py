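"""Standardisation chain: thickness extraction, resize, orientation,
rotation, displacement correction, and the mask-propagation invariants."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from retclust.preprocess import (
    DisplacementProfile,
    apply_displacement_correction,
    default_displacement_profile,
    orient_right_eye,
    resize_map,
    rotate_to_zero_tilt,
    standardize_map,
    thickness_from_boundaries,
)
from retclust.synth import LayerEffectModel, synth_thickness_map
from retclust.types import ParticipantRecord, ThicknessMap

RAW = (128, 512)
STD = (512, 512)


def _raw_map(values, valid=None, **kwargs):
    if valid is None:
        valid = np.ones(values.shape, dtype=bool)
    defaults = dict(layer="GCIPL", fovea_xy=(255.5, 63.5))
    defaults.update(kwargs)
    return ThicknessMap(values=values, valid=valid, **defaults)


class TestThicknessFromBoundaries:
    def test_coincident_boundaries_give_zero(self):
        b = np.full(RAW, 100.0)
        t = thickness_from_boundaries(b, b)
        assert np.all(t.values == 0) and t.valid.all()

    def test_axial_scaling(self):
        t = thickness_from_boundaries(np.full(RAW, 100.0), np.full(RAW, 150.0),
                                      axial_scale=1.95)
        assert np.all(t.values == pytest.approx(97.5))

    def test_erroneous_ascan_column_invalidated(self):
        upper = np.full(RAW, 100.0)
        lower = np.full(RAW, 150.0)
        upper[:, 37] = np.nan
        t = thickness_from_boundaries(upper, lower)
        assert not t.valid[:, 37].any()
        assert t.valid[:, 36].all() and t.valid[:, 38].all()

    def test_inverted_boundaries_name_the_pixel(self):
        upper = np.full(RAW, 100.0)
        lower = np.full(RAW, 150.0)
        lower[5, 7] = 90.0
        with pytest.raises(ValueError, match=r"row=5, col=7"):
            thickness_from_boundaries(upper, lower)


class TestResize:
    def test_constant_map_reproduced(self):
        out = resize_map(_raw_map(np.full(RAW, 7.0)))
        assert out.shape == STD
        assert np.abs(out.values - 7.0).max() < 1e-9

    def test_linear_ramp_reproduced_off_boundary(self):
        ramp = np.tile(np.arange(128.0)[:, None], (1, 512))
        out = resize_map(_raw_map(ramp))
        expected = np.clip((np.arange(512) + 0.5) * 128 / 512 - 0.5, 0, 127)
        err = np.abs(out.values[:, 0] - expected)
        assert err[8:-8].max() < 1e-6

    def test_invalid_source_pixel_never_contributes(self):
        valid = np.ones(RAW, bool)
        valid[60, 10] = False
        out = resize_map(_raw_map(np.zeros(RAW), valid))
        # all output rows drawing on source row 60 must be invalid in col 10
        assert (~out.valid[:, 10]).sum() >= 4 * 4  # 4x upsampling, 4-row support
        assert out.valid[:, 11].all()

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            resize_map(_raw_map(np.zeros(STD), fovea_xy=(255.5, 255.5)))


class TestOrientRightEye:
    def test_od_untouched(self):
        m = _raw_map(np.arange(128.0 * 512).reshape(RAW))
        assert orient_right_eye(m) is m

    def test_mirroring_is_involutive(self, rng):
        m = _raw_map(rng.normal(size=RAW), laterality="OS", tilt_deg=5.0)
        once = orient_right_eye(m)
        relabelled = ThicknessMap(values=once.values, valid=once.valid,
                                  layer="GCIPL", fovea_xy=once.fovea_xy,
                                  laterality="OS", tilt_deg=-once.tilt_deg)
        twice = orient_right_eye(relabelled)
        assert np.array_equal(twice.values, m.values)
        assert twice.fovea_xy == m.fovea_xy

    def test_marker_column_mirrors(self):
        vals = np.zeros(RAW)
        vals[64, 10] = 1.0
        out = orient_right_eye(_raw_map(vals, laterality="OS"))
        assert out.values[64, 501] == 1.0
        assert out.laterality == "OD"
        assert out.tilt_deg == 0.0


class TestRotation:
    def test_zero_tilt_is_identity(self, rng):
        vals = rng.normal(size=STD)
        m = ThicknessMap(values=vals, valid=np.ones(STD, bool), layer="GCIPL",
                         fovea_xy=(255.5, 255.5), tilt_deg=0.0)
        out = rotate_to_zero_tilt(m)
        assert np.abs(out.values[out.valid] - vals[out.valid]).max() < 1e-9

    def test_rotationally_symmetric_map_unchanged(self):
        cols, rows = np.meshgrid(np.arange(512.0), np.arange(512.0))
        r = np.hypot(cols - 255.5, rows - 255.5)
        vals = 80.0 * np.exp(-r / 300.0)
        m = ThicknessMap(values=vals, valid=np.ones(STD, bool), layer="GCIPL",
                         fovea_xy=(255.5, 255.5), tilt_deg=9.0)
        out = rotate_to_zero_tilt(m)
        # exclude the central kink of hypot, where spline error concentrates
        annulus = (r >= 16) & (r <= 240)
        assert np.abs(out.values[annulus] - vals[annulus]).max() < 1e-3
        assert out.tilt_deg == 0.0

    def test_landmark_moves_by_minus_tilt(self):
        vals = np.zeros(STD)
        r0, ang = 100.0, np.radians(45.0)
        row = int(round(255.5 - r0 * np.sin(ang)))
        col = int(round(255.5 + r0 * np.cos(ang)))
        vals[row, col] = 100.0
        vals = gaussian_filter(vals, 3)
        m = ThicknessMap(values=vals, valid=np.ones(STD, bool), layer="GCIPL",
                         fovea_xy=(255.5, 255.5), tilt_deg=7.0)
        out = rotate_to_zero_tilt(m)
        pk = np.unravel_index(np.argmax(out.values), STD)
        expected_ang = np.radians(45.0 - 7.0)
        exp_row = 255.5 - r0 * np.sin(expected_ang)
        exp_col = 255.5 + r0 * np.cos(expected_ang)
        assert np.hypot(pk[0] - exp_row, pk[1] - exp_col) <= 0.75


class TestDisplacement:
    def _field(self, values):
        return ThicknessMap(values=values, valid=np.ones(STD, bool), layer="ORC",
                            fovea_xy=(255.5, 255.5), tilt_deg=0.0)

    def test_zero_profile_is_identity(self, rng):
        vals = rng.normal(size=STD)
        prof = DisplacementProfile((0.0, 5.0), (0.0, 0.0))
        out = apply_displacement_correction(self._field(vals), prof)
        assert np.abs(out.values[out.valid] - vals[out.valid]).max() < 1e-9

    def test_constant_map_unchanged(self):
        out = apply_displacement_correction(self._field(np.full(STD, 42.0)),
                                            default_displacement_profile())
        assert np.abs(out.values[out.valid] - 42.0).max() < 1e-9

    def test_outward_remap_traces_the_profile(self):
        # radial eccentricity ramp (degrees): with a uniform 1 deg outward
        # displacement, a 2 deg pixel reads the source value at 3 deg
        cols, rows = np.meshgrid(np.arange(512.0), np.arange(512.0))
        px = 6.0 / 512
        ecc = np.hypot((cols - 255.5) * px, (rows - 255.5) * px) / 0.288
        prof = DisplacementProfile((0.0, 6.0, 7.0), (1.0, 1.0, 0.0))
        out = apply_displacement_correction(self._field(ecc.copy()), prof)
        col2deg = int(round(255.5 + 2 * 0.288 / px))
        sampled = out.values[256, col2deg]
        true_ecc = ecc[256, col2deg]
        assert sampled == pytest.approx(true_ecc + 1.0, abs=0.02)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            DisplacementProfile((), ())


class TestPipelineInvariants:
    def test_valid_count_never_increases(self, rng):
        valid = rng.random(RAW) > 0.02
        m = _raw_map(rng.normal(70, 5, size=RAW), valid,
                     laterality="OS", tilt_deg=6.0, layer="ORC")
        counts = [m.valid.sum() / m.valid.size]
        m = resize_map(m)
        counts.append(m.valid.sum() / m.valid.size)
        m = orient_right_eye(m)
        counts.append(m.valid.sum() / m.valid.size)
        m = rotate_to_zero_tilt(m)
        counts.append(m.valid.sum() / m.valid.size)
        m = apply_displacement_correction(m, default_displacement_profile())
        counts.append(m.valid.sum() / m.valid.size)
        assert all(b <= a + 1e-12 for a, b in zip(counts, counts[1:]))

    def test_mirrored_rotated_copies_standardise_identically(self):
        """An OS acquisition of the same eye, with opposite tilt, must
        standardise to the OD version within 0.5 um over the central 80%."""
        rec = ParticipantRecord("X", age=55, sex="F", se=-1.0)
        model = LayerEffectModel("GCIPL", noise_sd=2.0, individual_sd=0.0,
                                 spatial_correlation_length_um=500.0)
        base = synth_thickness_map(rec, model, seed=3)
        od = ThicknessMap(values=base.values, valid=base.valid, layer="GCIPL",
                          fovea_xy=base.fovea_xy, laterality="OD", tilt_deg=6.0)
        os_vals = base.values[:, ::-1].copy()
        os = ThicknessMap(values=os_vals, valid=base.valid.copy(), layer="GCIPL",
                          fovea_xy=(511 - base.fovea_xy[0], base.fovea_xy[1]),
                          laterality="OS", tilt_deg=-6.0)
        std_od = standardize_map(od)
        std_os = standardize_map(os)
        lo, hi = 51, 461  # central 80%
        sl = (slice(lo, hi), slice(lo, hi))
        both = std_od.valid[sl] & std_os.valid[sl]
        diff = np.abs(std_od.values[sl][both] - std_os.values[sl][both])
        assert diff.max() < 0.5
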