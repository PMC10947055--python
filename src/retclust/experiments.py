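"""Cohort-scale simulation studies.

These drivers tie the modules together into the three study designs the test
suite and the acceptance script exercise:

* :func:`regression_recovery_study` -- healthy cohorts (n = 548) generated
  with the ground-truth layer effects; OLS + backward elimination must
  recover the coefficients and the per-layer matching-covariate pattern
  (age/SE for GCIPL and INL; age/SE/sex for the ORC).
* :func:`planted_defect_recovery` -- subcohorts with a planted arcuate
  defect; visual-field typing, cluster topography (Dice against the planted
  mask) and between-layer agreement are scored against ground truth.
* :func:`severity_gradient_study` -- a glaucoma cohort spanning a defect
  depth gradient; global Spearman correlations of within/outside differences
  and cross-layer correlations against MD and PSD.

Maps for these experiments are synthesised directly in the standardised
right-eye, zero-tilt geometry (the preprocessing chain has its own tests),
and the regression study uses a reduced raster since only whole-scan means
enter the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .agreement import agreement_stats, defective_mask
from .cluster import cluster_grid, participant_feature_matrix, subcohort_mean_grid
from .deviation import MatchSpec, participant_deviation_grid
from .geometry import STD_SHAPE
from .normative import fit_layer_normative_model
from .severity import (
    correlations_frame,
    cross_layer_r,
    global_severity_correlations,
    spearman_r,
    within_outside_difference,
)
from .synth import (
    DefectSpec,
    DemographicsSpec,
    LayerEffectModel,
    default_layer_models,
    synth_cohort,
)
from .types import LAYERS
from .vf import classify_vf

logger = logging.getLogger(__name__)

#: matching requirements established by the normative analysis: sex matters
#: only for the ORC
MATCH_SEX = {"GCIPL": False, "INL": False, "ORC": True}

EXPECTED_FINAL_COVARIATES = {
    "GCIPL": frozenset({"age", "SE"}),
    "INL": frozenset({"age", "SE"}),
    "ORC": frozenset({"age", "SE", "sex"}),
}

TRUTH_KEYS = {"age": "age_slope", "SE": "se_slope", "sex": "sex_offset"}


def _seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0])


def regression_recovery_study(
    n_reps: int = 50,
    n: int = 548,
    seed: int = 0,
    shape: tuple[int, int] = (32, 128),
) -> dict:
    """Simulate healthy cohorts and score coefficient + pattern recovery.

    Returns per-(replicate, layer, coefficient) coverage of the ground truth
    by +-2 fitted standard errors, and the fraction of replicates whose
    backward elimination reproduces the expected matching pattern per layer.
    """
    models = default_layer_models()
    covered = []
    patterns = {layer: 0 for layer in LAYERS}
    estimates = {layer: [] for layer in LAYERS}
    for rep in range(n_reps):
        spec = DemographicsSpec(n=n, seed=_seed(seed, 10, rep))
        cohort = synth_cohort(spec, models=models, shape=shape, standardized=True)
        for layer in LAYERS:
            model, report = fit_layer_normative_model(cohort, layer)
            truth = models[layer]
            for cov, (est, se, _p) in model.terms.items():
                true_val = getattr(truth, TRUTH_KEYS[cov])
                covered.append(abs(est - true_val) <= 2.0 * se)
            estimates[layer].append({c: model.terms[c][0] for c in model.terms})
            if report.final_covariates == EXPECTED_FINAL_COVARIATES[layer]:
                patterns[layer] += 1
    return {
        "coverage": float(np.mean(covered)),
        "n_checks": len(covered),
        "pattern_rate": {layer: patterns[layer] / n_reps for layer in LAYERS},
        "mean_estimates": {
            layer: pd.DataFrame(estimates[layer]).mean().to_dict() for layer in LAYERS
        },
    }


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)


def _experiment_models(noise_sd: float) -> dict[str, LayerEffectModel]:
    return {
        layer: replace(model, noise_sd=noise_sd)
        for layer, model in default_layer_models().items()
    }


def _deviation_grids(glaucoma, healthy, layers=LAYERS):
    """Per-participant, per-layer deviation grids with layer-specific matching."""
    grids: dict[str, dict[str, object]] = {layer: {} for layer in layers}
    for g in glaucoma:
        for layer in layers:
            spec = MatchSpec(match_sex=MATCH_SEX[layer])
            grids[layer][g.pid] = participant_deviation_grid(g, healthy, layer, spec)
    return grids


@dataclass
class PlantedDefectResult:
    all_typed_s: bool
    dice_gcipl: float
    kappa_gcipl_inl: float | None
    kappa_gcipl_orc: float | None
    k_per_layer: dict = field(default_factory=dict)
    min_dprime: float = float("inf")


def planted_defect_recovery(
    n_reps: int = 50,
    n_glaucoma: int = 20,
    n_healthy: int = 80,
    gcipl_depth: float = 10.0,
    inl_ratio: float = 0.3,
    orc_delta: float = 0.0,
    noise_sd: float = 2.0,
    vf_depth: float = 8.0,
    vf_noise_sd: float = 1.0,
    seed: int = 0,
    k_max: int = 10,
) -> list[PlantedDefectResult]:
    """Planted superior-field (inferior-retina) arcuate defect recovery.

    Each replicate builds a fresh healthy pool and a glaucoma subcohort whose
    every eye carries the same arcuate defect, then runs visual-field typing,
    matched deviation mapping, clustering and between-layer agreement.
    """
    defect = DefectSpec(
        hemifields=frozenset({"inferior_retina"}),
        gcipl_depth=gcipl_depth,
        inl_ratio=inl_ratio,
        orc_delta=orc_delta,
        vf_depth=vf_depth,
    )
    models = _experiment_models(noise_sd)
    truth_mask = defect.grid_mask()
    results = []
    for rep in range(n_reps):
        healthy = synth_cohort(
            DemographicsSpec(n=n_healthy, seed=_seed(seed, 20, rep)),
            models=models, shape=STD_SHAPE, standardized=True, pid_prefix="H",
        )
        # glaucoma ages bounded away from the pool extremes so every eye
        # keeps a matched subgroup at this pool size
        glaucoma = synth_cohort(
            DemographicsSpec(n=n_glaucoma, age_range=(35.0, 70.0),
                             se_range=(-4.0, 2.5), seed=_seed(seed, 21, rep)),
            models=models, defect_for=lambda i, r: defect,
            vf_noise_sd=vf_noise_sd, shape=STD_SHAPE, standardized=True,
            pid_prefix="G",
        )
        all_s = all(classify_vf(g.vf).defect_type == "S" for g in glaucoma)
        grids = _deviation_grids(glaucoma, healthy)
        masks = {}
        solutions = {}
        mean_grids = {}
        for layer in LAYERS:
            layer_grids = list(grids[layer].values())
            mean, valid = subcohort_mean_grid(layer_grids)
            features = participant_feature_matrix(layer_grids, valid)
            solution = cluster_grid(mean, valid, k_max=k_max, feature_matrix=features)
            solutions[layer] = solution
            mean_grids[layer] = (mean, valid)
            masks[layer] = defective_mask(solution, mean, valid)
        gc_solution = solutions["GCIPL"]
        most_negative = gc_solution.labels == gc_solution.k  # ordinal: last label
        common = mean_grids["GCIPL"][1]
        kappa_inl = agreement_stats(
            masks["GCIPL"], masks["INL"],
            valid=common & mean_grids["INL"][1], layer_pair=("GCIPL", "INL"),
        ).kappa
        kappa_orc = agreement_stats(
            masks["GCIPL"], masks["ORC"],
            valid=common & mean_grids["ORC"][1], layer_pair=("GCIPL", "ORC"),
        ).kappa
        min_dp = min(
            (
                float(s.dprime_matrix[np.triu_indices(s.k, k=1)].min())
                for s in solutions.values()
                if s.k > 1
            ),
            default=float("inf"),
        )
        results.append(
            PlantedDefectResult(
                all_typed_s=all_s,
                dice_gcipl=dice(most_negative, truth_mask),
                kappa_gcipl_inl=kappa_inl,
                kappa_gcipl_orc=kappa_orc,
                k_per_layer={layer: solutions[layer].k for layer in LAYERS},
                min_dprime=min_dp,
            )
        )
    return results


def severity_gradient_study(
    n_glaucoma: int = 80,
    n_healthy: int = 100,
    depth_range: tuple[float, float] = (2.0, 14.0),
    vf_depth_scale: float = 1.8,
    inl_ratio: float = 0.3,
    noise_sd: float = 2.0,
    vf_noise_sd: float = 1.0,
    seed: int = 0,
    min_stratum: int = 3,
) -> dict:
    """Glaucoma cohort over a defect-depth gradient; severity correlations.

    Every eye carries an inferior-retina (superior-field) arcuate defect of
    depth drawn uniformly from ``depth_range``; field defect depth scales
    with structural depth, so MD worsens and PSD grows along the gradient.
    Returns the per-participant table, the global Spearman correlations and
    a permutation null band for correlations against MD.
    """
    rng = np.random.default_rng(_seed(seed, 30))
    depths = rng.uniform(*depth_range, size=n_glaucoma)
    models = _experiment_models(noise_sd)

    def defect_for(i, _record):
        return DefectSpec(
            hemifields=frozenset({"inferior_retina"}),
            gcipl_depth=float(depths[i]),
            inl_ratio=inl_ratio,
            orc_delta=0.0,
            vf_depth=vf_depth_scale * float(depths[i]),
        )

    healthy = synth_cohort(
        DemographicsSpec(n=n_healthy, seed=_seed(seed, 31)),
        models=models, shape=STD_SHAPE, standardized=True, pid_prefix="H",
    )
    glaucoma = synth_cohort(
        DemographicsSpec(n=n_glaucoma, age_range=(35.0, 70.0),
                         se_range=(-4.0, 2.5), seed=_seed(seed, 32)),
        models=models, defect_for=defect_for, vf_noise_sd=vf_noise_sd,
        shape=STD_SHAPE, standardized=True, pid_prefix="G",
    )
    classifications = {g.pid: classify_vf(g.vf) for g in glaucoma}
    grids = _deviation_grids(glaucoma, healthy)

    # stratum-level GCIPL defective masks
    strata: dict[tuple[str, str], list] = {}
    for g in glaucoma:
        c = classifications[g.pid]
        strata.setdefault((c.defect_type, c.md_bin), []).append(g.pid)
    stratum_masks: dict[tuple[str, str], np.ndarray] = {}
    for key, pids in strata.items():
        if len(pids) < min_stratum:
            logger.info("stratum %s too small (%d), skipped", key, len(pids))
            continue
        stratum_grids = [grids["GCIPL"][p] for p in pids]
        mean, valid = subcohort_mean_grid(stratum_grids)
        solution = cluster_grid(
            mean, valid, feature_matrix=participant_feature_matrix(stratum_grids, valid)
        )
        stratum_masks[key] = defective_mask(solution, mean, valid)

    rows = []
    excluded = 0
    for g in glaucoma:
        c = classifications[g.pid]
        row = {"pid": g.pid, "stratum": f"{c.defect_type}/{c.md_bin}",
               "MD": g.vf.md, "PSD": g.vf.psd, "true_depth": float(depths[
                   int(g.pid[1:])])}
        mask = stratum_masks.get((c.defect_type, c.md_bin))
        for layer in LAYERS:
            value = np.nan
            if mask is not None and mask.any():
                try:
                    value = within_outside_difference(grids[layer][g.pid], mask)
                except ValueError:
                    excluded += 1
            row[f"{layer}_diff"] = value
        for pair in (("GCIPL", "INL"), ("GCIPL", "ORC"), ("INL", "ORC")):
            try:
                row[f"r_{pair[0]}_{pair[1]}"] = cross_layer_r(
                    grids[pair[0]][g.pid], grids[pair[1]][g.pid]
                )
            except ValueError:
                row[f"r_{pair[0]}_{pair[1]}"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    corrs = global_severity_correlations(table)

    # permutation null band (99%) for |r_g| against MD, per quantity sample size
    null_rng = np.random.default_rng(_seed(seed, 33))
    md = table["MD"].to_numpy()
    orc = table["ORC_diff"].to_numpy()
    keep = np.isfinite(orc) & np.isfinite(md)
    null_bound = np.nan
    if keep.sum() >= 10:
        null_rs = []
        base = orc[keep]
        for _ in range(2000):
            perm = null_rng.permutation(base)
            null_rs.append(abs(spearman_r(perm, md[keep])[0]))
        null_bound = float(np.quantile(null_rs, 0.99))
    return {
        "table": table,
        "correlations": correlations_frame(corrs),
        "orc_null_bound_99": null_bound,
        "n_excluded_diffs": excluded,
    }
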