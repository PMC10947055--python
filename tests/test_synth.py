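"""Synthetic-cohort generator: determinism, effect structure, VF construction."""

import numpy as np
import pytest

from retclust.geometry import MM_PER_DEG, lattice_10_2
from retclust.synth import (
    DefectSpec,
    DemographicsSpec,
    LayerEffectModel,
    sample_demographics,
    synth_thickness_map,
    synth_vf,
)
from retclust.types import FLAG_NONE, ParticipantRecord


def _record_tuple(r):
    return (r.pid, r.age, r.sex, r.se, r.eye, r.tilt_deg)


class TestSampleDemographics:
    def test_deterministic_under_seed(self):
        spec = DemographicsSpec(n=3, seed=1)
        a = [_record_tuple(r) for r in sample_demographics(spec)]
        b = [_record_tuple(r) for r in sample_demographics(spec)]
        assert a == b

    def test_degenerate_age_interval(self):
        spec = DemographicsSpec(n=10, age_range=(50.0, 50.0), seed=2)
        assert all(r.age == 50.0 for r in sample_demographics(spec))

    def test_fields_within_ranges(self):
        spec = DemographicsSpec(n=200, age_range=(30, 60), se_range=(-3, 1), seed=5)
        recs = sample_demographics(spec)
        assert all(30 <= r.age <= 60 for r in recs)
        assert all(-3 <= r.se <= 1 for r in recs)

    def test_male_fraction_within_binomial_bounds(self):
        # 99% two-sided binomial bound for p=0.45, n=548:
        # p +- 2.576 * sqrt(p(1-p)/n) = 0.45 +- 0.0547
        spec = DemographicsSpec(n=548, sex_ratio=0.45, seed=7)
        frac = np.mean([r.sex == "M" for r in sample_demographics(spec)])
        half = 2.576 * np.sqrt(0.45 * 0.55 / 548)
        assert abs(frac - 0.45) <= half

    @pytest.mark.parametrize("bad", [
        dict(n=0), dict(age_range=(60, 30)), dict(sex_ratio=1.5),
        dict(se_range=(2, -2)),
    ])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(ValueError):
            DemographicsSpec(**{"n": 5, "seed": 0, **bad})


class TestSynthThicknessMap:
    def test_zero_effect_case_equals_baseline(self, ref_participant, clean_gcipl_model):
        tmap = synth_thickness_map(ref_participant, clean_gcipl_model, seed=0)
        ecc, thick = clean_gcipl_model.baseline_profile
        assert tmap.shape == (128, 512)
        # pixel centres sit off the exact fovea; compute the true eccentricity
        x_mm = (400 - 255.5) * 6.0 / 512
        y_mm = (63.5 - 63) * 6.0 / 128
        expected = np.interp(np.hypot(x_mm, y_mm), ecc, thick)
        assert tmap.values[63, 400] == pytest.approx(expected, abs=1e-9)
        assert tmap.valid.all()

    def test_defect_is_exactly_additive(self, ref_participant, clean_gcipl_model):
        defect = DefectSpec(hemifields={"superior_retina"}, gcipl_depth=10.0)
        base = synth_thickness_map(ref_participant, clean_gcipl_model, seed=0)
        hit = synth_thickness_map(ref_participant, clean_gcipl_model, defect=defect, seed=0)
        diff = base.values - hit.values
        mask = defect.retinal_mask(base.shape)
        assert np.all(diff[mask] == 10.0)
        assert np.all(diff[~mask] == 0.0)

    def test_age_slope_shifts_mean_map(self, clean_gcipl_model):
        young = ParticipantRecord("A", age=40, sex="F", se=0.0)
        old = ParticipantRecord("B", age=60, sex="F", se=0.0)
        m_young = synth_thickness_map(young, clean_gcipl_model, seed=0)
        m_old = synth_thickness_map(old, clean_gcipl_model, seed=0)
        # 20 years x 0.112 um/y
        assert np.mean(m_young.values - m_old.values) == pytest.approx(2.24, abs=1e-9)

    def test_depth_linearity_and_layer_coupling(self, ref_participant):
        models = {
            layer: LayerEffectModel(layer, noise_sd=0.0, individual_sd=0.0)
            for layer in ("GCIPL", "INL")
        }
        d1 = DefectSpec(hemifields={"inferior_retina"}, gcipl_depth=5.0, inl_ratio=0.3)
        d2 = DefectSpec(hemifields={"inferior_retina"}, gcipl_depth=10.0, inl_ratio=0.3)
        deficits = {}
        for layer, model in models.items():
            base = synth_thickness_map(ref_participant, model, seed=0)
            h1 = synth_thickness_map(ref_participant, model, defect=d1, seed=0)
            h2 = synth_thickness_map(ref_participant, model, defect=d2, seed=0)
            mask = d1.retinal_mask(base.shape)
            deficits[layer] = (
                np.mean(base.values[mask] - h1.values[mask]),
                np.mean(base.values[mask] - h2.values[mask]),
            )
        assert deficits["GCIPL"][1] == pytest.approx(2 * deficits["GCIPL"][0], rel=1e-12)
        assert deficits["INL"][0] == pytest.approx(0.3 * deficits["GCIPL"][0], rel=1e-12)
        assert deficits["INL"][1] == pytest.approx(0.3 * deficits["GCIPL"][1], rel=1e-12)

    def test_seed_repeatability(self, ref_participant):
        model = LayerEffectModel("GCIPL", noise_sd=2.0, individual_sd=4.0)
        a = synth_thickness_map(ref_participant, model, seed=42)
        b = synth_thickness_map(ref_participant, model, seed=42)
        assert np.array_equal(a.values, b.values)


class TestSynthVF:
    def test_clean_field(self):
        vf = synth_vf(None, noise_sd=0.0, seed=0)
        assert len(vf.points) == 68
        assert np.all(vf.points["pd"] == 0)
        assert vf.md == 0 and vf.psd == 0
        assert np.all(vf.points["flag"] == FLAG_NONE)

    def test_superior_field_defect_projection_and_md(self):
        # inferior retina projects to the superior field hemisphere
        defect = DefectSpec(hemifields={"inferior_retina"}, vf_depth=8.0)
        vf = synth_vf(defect, noise_sd=0.0, seed=0)
        pts = vf.points
        flagged = pts[pts["flag"] > 0]
        assert len(flagged) > 0
        assert np.all(flagged["y"] > 0)
        # flagged set is exactly the geometric projection of the defect
        proj = defect.weight(
            pts["x"].to_numpy() * MM_PER_DEG, -pts["y"].to_numpy() * MM_PER_DEG
        ) > 0
        assert np.array_equal(proj, (pts["flag"] > 0).to_numpy())
        assert vf.md == pytest.approx(-8.0 * proj.sum() / 68)

    def test_seed_repeatability(self):
        d = DefectSpec(hemifields={"superior_retina"}, vf_depth=6.0)
        a = synth_vf(d, noise_sd=1.5, seed=9)
        b = synth_vf(d, noise_sd=1.5, seed=9)
        assert a.points.equals(b.points) and a.md == b.md and a.psd == b.psd

    def test_lattice_is_the_68_point_10_2_grid(self):
        pts = lattice_10_2()
        assert pts.shape == (68, 2)
        assert np.all(np.abs(pts) <= 9)
        assert np.all(pts % 2 != 0)
        assert np.all((pts ** 2).sum(axis=1) < 90)
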