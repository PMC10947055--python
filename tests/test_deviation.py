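"""Matched subgroups, normative means, deviation maps and grid averaging."""

import numpy as np
import pytest

from retclust.deviation import (
    MatchSpec,
    compute_deviation_map,
    grid_average,
    normative_mean_map,
    participant_deviation_grid,
    select_matched_subgroup,
)
from retclust.geometry import CELL_UM, EXTENT_MM, GRID_SHAPE, STD_SHAPE
from retclust.synth import DefectSpec, LayerEffectModel, synth_thickness_map
from retclust.types import ParticipantRecord, ThicknessMap


def _std_map(values, valid=None):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(values.shape, bool)
    return ThicknessMap(values=values, valid=valid, layer="GCIPL",
                        fovea_xy=(255.5, 255.5))


def _p(pid, age, sex, se):
    return ParticipantRecord(pid=pid, age=age, sex=sex, se=se)


class TestMatching:
    def test_age_window_inclusive(self):
        g = _p("g", 64, "F", 0.0)
        assert select_matched_subgroup(g, [_p("h", 70, "F", 0.0)],
                                       MatchSpec(min_subgroup=1))

    def test_se_window_exclusive_beyond_two_dioptres(self):
        g = _p("g", 50, "F", -0.5)
        sub = select_matched_subgroup(g, [_p("h", 50, "F", -2.75)],
                                      MatchSpec(min_subgroup=0))
        assert sub == []

    def test_sex_rule_applies_when_requested(self):
        g = _p("g", 50, "F", 0.0)
        healthy = [_p("h", 50, "M", 0.0)]
        assert select_matched_subgroup(g, healthy, MatchSpec(min_subgroup=0,
                                                             match_sex=True)) == []
        assert select_matched_subgroup(g, healthy, MatchSpec(min_subgroup=0,
                                                             match_sex=False))

    def test_small_subgroup_warns(self):
        g = _p("g", 50, "F", 0.0)
        with pytest.warns(UserWarning, match="matched subgroup"):
            select_matched_subgroup(g, [_p("h", 50, "F", 0.0)], MatchSpec())


class TestNormativeMean:
    def test_identical_maps(self):
        maps = [_std_map(np.full(STD_SHAPE, 75.0)) for _ in range(4)]
        mean, counts = normative_mean_map(maps)
        assert np.all(mean == 75.0) and np.all(counts == 4)

    def test_pairwise_average(self):
        mean, counts = normative_mean_map(
            [_std_map(np.full(STD_SHAPE, 70.0)), _std_map(np.full(STD_SHAPE, 90.0))]
        )
        assert np.all(mean == 80.0) and np.all(counts == 2)

    def test_partially_invalid_pixel_uses_remaining_maps(self):
        v = np.ones(STD_SHAPE, bool)
        v[0, 0] = False
        maps = [_std_map(np.full(STD_SHAPE, 60.0), v),
                _std_map(np.full(STD_SHAPE, 90.0)),
                _std_map(np.full(STD_SHAPE, 90.0))]
        mean, counts = normative_mean_map(maps)
        assert counts[0, 0] == 2 and mean[0, 0] == 90.0
        assert counts[1, 1] == 3 and mean[1, 1] == 80.0


class TestDeviation:
    def test_sign_convention(self):
        g = _std_map(np.full(STD_SHAPE, 60.0))
        dev, valid = compute_deviation_map(g, np.full(STD_SHAPE, 75.0),
                                           np.full(STD_SHAPE, 3))
        assert np.all(dev == -15.0) and valid.all()

    def test_identical_maps_give_zero(self):
        g = _std_map(np.full(STD_SHAPE, 75.0))
        dev, _ = compute_deviation_map(g, np.full(STD_SHAPE, 75.0),
                                       np.full(STD_SHAPE, 2))
        assert np.all(dev == 0)

    def test_shape_mismatch_rejected(self):
        g = _std_map(np.zeros(STD_SHAPE))
        with pytest.raises(ValueError):
            compute_deviation_map(g, np.zeros((64, 64)), np.ones((64, 64)))


class TestGridAverage:
    def test_cell_geometry(self):
        assert EXTENT_MM * 1000 / GRID_SHAPE[0] == CELL_UM == 93.75

    def test_constant_map(self):
        grid = grid_average(np.full(STD_SHAPE, 5.0), np.ones(STD_SHAPE, bool))
        assert grid.values.shape == (64, 64)
        assert np.all(grid.values == 5.0) and grid.valid.all()

    def test_block_mean(self):
        dev = np.zeros(STD_SHAPE)
        dev[0:8, 0:8] = np.arange(64.0).reshape(8, 8)
        grid = grid_average(dev, np.ones(STD_SHAPE, bool))
        assert grid.values[0, 0] == 31.5

    def test_half_valid_threshold(self):
        valid = np.ones(STD_SHAPE, bool)
        valid[0:8, 0:8] = False
        valid[0:3, 0:8] = True  # 24 of 64 valid -> below 50%
        grid = grid_average(np.ones(STD_SHAPE), valid)
        assert not grid.valid[0, 0]
        valid[0:4, 0:8] = True  # exactly 32 -> at threshold
        grid = grid_average(np.ones(STD_SHAPE), valid)
        assert grid.valid[0, 0]

    def test_grid_mean_matches_pixel_mean_under_dropout(self, rng):
        dev = rng.normal(-2.0, 3.0, STD_SHAPE)
        valid = rng.random(STD_SHAPE) > 0.04
        grid = grid_average(dev, valid)
        assert abs(grid.values[grid.valid].mean() - dev[valid].mean()) < 0.5


class TestEndToEnd:
    def test_planted_defect_recovered_exactly_without_noise(self):
        """Noise-free glaucoma eye vs a demographically identical subgroup:
        the deviation grid is -10 inside the planted mask, 0 outside."""
        model = LayerEffectModel("GCIPL", age_slope=-0.112, se_slope=0.513,
                                 noise_sd=0.0, individual_sd=0.0)
        defect = DefectSpec(hemifields={"superior_retina"}, gcipl_depth=10.0)
        g = _p("G1", 55.0, "F", -1.0)
        healthy = [_p(f"H{i}", 55.0, "F", -1.0) for i in range(3)]
        for i, h in enumerate(healthy):
            h.maps["GCIPL"] = synth_thickness_map(h, model, seed=i,
                                                  shape=STD_SHAPE, standardized=True)
        g.maps["GCIPL"] = synth_thickness_map(g, model, defect=defect, seed=9,
                                              shape=STD_SHAPE, standardized=True)
        grid = participant_deviation_grid(g, healthy, "GCIPL")
        cell_mask = defect.grid_mask()
        interior = cell_mask & (np.abs(grid.values + 10.0) < 1e-9)
        outside_clean = ~cell_mask & (np.abs(grid.values) < 1e-9)
        # every cell is either exactly -10, exactly 0, or a partial edge cell
        partial = ~(interior | outside_clean)
        assert interior.sum() > 500
        assert (grid.values[partial] <= 0).all()
        assert partial.sum() < 0.1 * grid.values.size
        assert grid.subgroup_size == 3
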