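"""Per-participant deviation maps against demographics-matched normative means.

For each glaucomatous eye and layer, a matched subgroup of healthy eyes
(age within +-7.5 y, spherical equivalent within +-2.00 D, same sex when the
normative model requires it) supplies a per-pixel mean normative map; the raw
difference (glaucoma - normative, um) is averaged over 8 x 8 pixel blocks to
the 64 x 64 analysis grid.  Deviations stay in um -- never percent-of-normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import BLOCK_PX, GRID_SHAPE, STD_SHAPE
from .types import DeviationGrid, ParticipantRecord, ThicknessMap


@dataclass(frozen=True)
class MatchSpec:
    age_window: float = 7.5  # +- years
    se_window: float = 2.0  # +- dioptres
    match_sex: bool = False
    min_subgroup: int = 3

    def __post_init__(self) -> None:
        if self.age_window <= 0 or self.se_window <= 0:
            raise ValueError("matching windows must be positive")


def select_matched_subgroup(
    g: ParticipantRecord,
    healthy: list[ParticipantRecord],
    spec: MatchSpec = MatchSpec(),
) -> list[ParticipantRecord]:
    """Healthy participants inside the demographic windows of ``g``.

    The participant's own record (same pid) is excluded if present.  A
    subgroup smaller than ``min_subgroup`` triggers a warning; the caller
    records the subgroup size.
    """
    if not healthy:
        raise ValueError("healthy cohort is empty")
    out = []
    for h in healthy:
        if h.pid == g.pid:
            continue
        if abs(h.age - g.age) > spec.age_window:
            continue
        if abs(h.se - g.se) > spec.se_window:
            continue
        if spec.match_sex and h.sex != g.sex:
            continue
        out.append(h)
    if len(out) < spec.min_subgroup:
        warnings.warn(
            f"matched subgroup for {g.pid} has only {len(out)} members "
            f"(minimum {spec.min_subgroup})"
        )
    return out


def normative_mean_map(maps: list[ThicknessMap]) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mean over the subgroup maps, with contribution counts.

    A pixel contributes only where its map is valid; pixels with zero
    contributors have count 0 and an undefined (0) mean.
    """
    if not maps:
        raise ValueError("need at least one map")
    shape = maps[0].shape
    total = np.zeros(shape)
    counts = np.zeros(shape, dtype=int)
    for m in maps:
        if m.shape != shape:
            raise ValueError("subgroup maps must share a shape")
        total += np.where(m.valid, m.values, 0.0)
        counts += m.valid
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, total / np.maximum(counts, 1), 0.0)
    return mean, counts


def compute_deviation_map(
    g_map: ThicknessMap, norm_mean: np.ndarray, norm_counts: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Raw deviation (glaucoma - normative mean, um); negative = thinner.

    Invalid wherever the glaucoma pixel is invalid or no normative pixel
    contributed.
    """
    if g_map.shape != norm_mean.shape:
        raise ValueError("deviation requires matching shapes")
    valid = g_map.valid & (np.asarray(norm_counts) > 0)
    dev = np.where(valid, g_map.values - norm_mean, 0.0)
    return dev, valid


def grid_average(
    dev: np.ndarray,
    valid: np.ndarray,
    layer: str = "",
    participant_id: str = "",
    subgroup_size: int = 0,
    min_valid_frac: float = 0.5,
) -> DeviationGrid:
    """Average the 512 x 512 deviation map over 8 x 8 pixel blocks.

    Cell (i, j) is the mean of the valid pixels in block rows 8i..8i+7 and
    cols 8j..8j+7, and is valid iff at least ``min_valid_frac`` of its 64
    pixels are valid.
    """
    dev = np.asarray(dev, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    if dev.shape != STD_SHAPE:
        raise ValueError(f"expected {STD_SHAPE} deviation map, got {dev.shape}")
    gr, gc = GRID_SHAPE
    b = BLOCK_PX
    sums = np.where(valid, dev, 0.0).reshape(gr, b, gc, b).sum(axis=(1, 3))
    counts = valid.reshape(gr, b, gc, b).sum(axis=(1, 3))
    cell_valid = counts >= min_valid_frac * b * b
    values = np.where(cell_valid, sums / np.maximum(counts, 1), np.nan)
    values = np.where(cell_valid, values, 0.0)
    return DeviationGrid(values=values, valid=cell_valid, layer=layer,
                         participant_id=participant_id, subgroup_size=subgroup_size)


def participant_deviation_grid(
    g: ParticipantRecord,
    healthy: list[ParticipantRecord],
    layer: str,
    spec: MatchSpec = MatchSpec(),
) -> DeviationGrid:
    """Matched subgroup -> normative mean -> deviation -> 64 x 64 grid.

    With small healthy pools a participant at the demographic margins can
    match nobody.  In that case sex matching is relaxed first, then the
    age/SE windows are widened by 1.5x steps (each with a warning) until a
    comparison group exists -- the nearest-available-normals reading of the
    matching rule.
    """
    subgroup = select_matched_subgroup(g, healthy, spec)
    if not subgroup and spec.match_sex:
        warnings.warn(f"no sex-matched healthy eyes for {g.pid}; relaxing sex match")
        subgroup = select_matched_subgroup(
            g, healthy,
            MatchSpec(age_window=spec.age_window, se_window=spec.se_window,
                      match_sex=False, min_subgroup=spec.min_subgroup),
        )
    widen = 1.0
    while not subgroup and widen <= 4.0:
        widen *= 1.5
        warnings.warn(
            f"no matched healthy eyes for {g.pid}; widening windows x{widen:.2f}"
        )
        subgroup = select_matched_subgroup(
            g, healthy,
            MatchSpec(age_window=spec.age_window * widen,
                      se_window=spec.se_window * widen,
                      match_sex=False, min_subgroup=spec.min_subgroup),
        )
    if not subgroup:
        raise ValueError(f"no matched healthy participants for {g.pid}")
    mean, counts = normative_mean_map([h.maps[layer] for h in subgroup])
    dev, valid = compute_deviation_map(g.maps[layer], mean, counts)
    return grid_average(dev, valid, layer=layer, participant_id=g.pid,
                        subgroup_size=len(subgroup))
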