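"""End-to-end pipeline orchestration from a single YAML config.

Stage order: simulate (optional) -> preprocess -> classify-vf ->
fit-normative -> deviations -> cluster -> agreement -> severity.  Every
stage writes its outputs plus a JSON provenance record under the run
directory, and a rerun with identical config and seeds reproduces all
numeric outputs bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .agreement import agreement_stats, defective_mask
from .cluster import cluster_grid, participant_feature_matrix, subcohort_mean_grid
from .deviation import MatchSpec, participant_deviation_grid
from .normative import fit_layer_normative_model
from .preprocess import DisplacementProfile, default_displacement_profile, standardize_map
from .severity import correlations_frame, cross_layer_r, global_severity_correlations, within_outside_difference
from .synth import DefectSpec, DemographicsSpec, synth_cohort
from .types import LAYERS
from .vf import classify_vf

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 1,
    "simulate": {
        "n_healthy": 45,
        "n_glaucoma": 12,
        "depth_range": [4.0, 14.0],
        "vf_depth_scale": 1.8,
        "inl_ratio": 0.3,
        "vf_noise_sd": 1.0,
    },
    "match": {"age_window": 7.5, "se_window": 2.0, "min_subgroup": 3},
    "cluster": {"k_max": 10, "criterion": 1.0, "feature_mode": "participants"},
    "min_stratum": 3,
    "displacement_profile": None,  # path to CSV (ecc_deg, disp_deg); default built-in
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        path = Path(path_or_dict)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text())
    config = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (raw or {}).items():
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


def load_displacement(config: dict) -> DisplacementProfile:
    path = config.get("displacement_profile")
    if path is None:
        return default_displacement_profile()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"displacement profile not found: {path}")
    table = pd.read_csv(path)
    return DisplacementProfile(
        eccentricity_deg=tuple(table.iloc[:, 0]),
        displacement_deg=tuple(table.iloc[:, 1]),
    )


def _stage(run_dir: Path, name: str, config: dict) -> Path:
    out = run_dir / name
    out.mkdir(parents=True, exist_ok=True)
    rio.write_provenance(out / "provenance.json", name, config)
    return out


def run_pipeline(config, out_dir) -> Path:
    """Execute the full pipeline; returns the run directory."""
    config = load_config(config)
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    displacement = load_displacement(config)
    seed = int(config["seed"])
    t0 = time.time()

    # -- simulate ---------------------------------------------------------
    sim = config["simulate"]
    rng = np.random.default_rng(seed)
    depths = rng.uniform(*sim["depth_range"], size=sim["n_glaucoma"])

    def defect_for(i, _record):
        return DefectSpec(
            hemifields=frozenset({"inferior_retina"}),
            gcipl_depth=float(depths[i]),
            inl_ratio=sim["inl_ratio"],
            vf_depth=sim["vf_depth_scale"] * float(depths[i]),
        )

    healthy = synth_cohort(
        DemographicsSpec(n=sim["n_healthy"], seed=seed + 1), pid_prefix="H"
    )
    glaucoma = synth_cohort(
        DemographicsSpec(n=sim["n_glaucoma"], age_range=(35.0, 70.0),
                         se_range=(-4.0, 2.5), seed=seed + 2),
        defect_for=defect_for, vf_noise_sd=sim["vf_noise_sd"], pid_prefix="G",
    )
    stage_dir = _stage(run_dir, "simulate", config)
    rio.write_cohort(healthy, stage_dir / "healthy.csv")
    rio.write_cohort(glaucoma, stage_dir / "glaucoma.csv")
    logger.info("simulate: %d healthy, %d glaucoma (%.1fs)",
                len(healthy), len(glaucoma), time.time() - t0)

    # -- preprocess -------------------------------------------------------
    try:
        for rec in healthy + glaucoma:
            for layer in LAYERS:
                rec.maps[layer] = standardize_map(rec.maps[layer], displacement)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"stage preprocess failed on {rec.pid}: {exc}") from exc
    _stage(run_dir, "preprocess", config)

    # -- classify-vf ------------------------------------------------------
    stage_dir = _stage(run_dir, "classify_vf", config)
    classifications = {}
    rows = []
    for rec in glaucoma:
        c = classify_vf(rec.vf)
        classifications[rec.pid] = c
        rows.append({"pid": rec.pid, "defect_type": c.defect_type,
                     "md_bin": c.md_bin, "MD": rec.vf.md, "PSD": rec.vf.psd,
                     "cluster_sizes": ";".join(str(len(x)) for x in c.clusters)})
    strata_frame = pd.DataFrame(rows)
    strata_frame.to_csv(stage_dir / "strata.csv", index=False)

    # -- fit-normative ----------------------------------------------------
    stage_dir = _stage(run_dir, "fit_normative", config)
    match_sex = {}
    norm_rows = []
    for layer in LAYERS:
        model, report = fit_layer_normative_model(healthy, layer)
        match_sex[layer] = "sex" in report.final_covariates
        for cov, (est, se, p) in model.terms.items():
            norm_rows.append({"layer": layer, "covariate": cov, "estimate": est,
                              "se": se, "p": p,
                              "retained": cov in report.final_covariates})
    pd.DataFrame(norm_rows).to_csv(stage_dir / "normative_models.csv", index=False)

    # -- deviations -------------------------------------------------------
    stage_dir = _stage(run_dir, "deviations", config)
    match_conf = config["match"]
    grids = {layer: {} for layer in LAYERS}
    for rec in glaucoma:
        for layer in LAYERS:
            spec = MatchSpec(age_window=match_conf["age_window"],
                             se_window=match_conf["se_window"],
                             match_sex=match_sex[layer],
                             min_subgroup=match_conf["min_subgroup"])
            grid = participant_deviation_grid(rec, healthy, layer, spec)
            grids[layer][rec.pid] = grid
            np.savetxt(stage_dir / f"{rec.pid}_{layer}.tsv",
                       np.where(grid.valid, grid.values, np.nan),
                       fmt="%.5g", delimiter="\t")

    # -- cluster ----------------------------------------------------------
    stage_dir = _stage(run_dir, "cluster", config)
    strata = {}
    for rec in glaucoma:
        c = classifications[rec.pid]
        strata.setdefault((c.defect_type, c.md_bin), []).append(rec.pid)
    solutions = {}
    mean_grids = {}
    cluster_rows = []
    for key, pids in sorted(strata.items()):
        if len(pids) < config["min_stratum"]:
            continue
        for layer in LAYERS:
            stratum_grids = [grids[layer][p] for p in pids]
            mean, valid = subcohort_mean_grid(stratum_grids)
            features = None
            if config["cluster"].get("feature_mode", "participants") == "participants":
                features = participant_feature_matrix(stratum_grids, valid)
            solution = cluster_grid(mean, valid,
                                    k_max=config["cluster"]["k_max"],
                                    criterion=config["cluster"]["criterion"],
                                    feature_matrix=features)
            solutions[(key, layer)] = solution
            mean_grids[(key, layer)] = (mean, valid)
            np.savetxt(stage_dir / f"{key[0]}_{key[1]}_{layer}_labels.tsv",
                       solution.labels, fmt="%d", delimiter="\t")
            for idx, st in enumerate(solution.clusters):
                cluster_rows.append({
                    "stratum": f"{key[0]}/{key[1]}", "layer": layer,
                    "label": idx + 1, "mean": st.mean, "sd": st.sd, "n": st.n,
                    "k0": solution.k0, "k": solution.k,
                })
    pd.DataFrame(cluster_rows).to_csv(stage_dir / "clusters.csv", index=False)

    # -- agreement --------------------------------------------------------
    stage_dir = _stage(run_dir, "agreement", config)
    agreement_rows = []
    for key in sorted(strata):
        if (key, "GCIPL") not in solutions:
            continue
        masks = {}
        valids = {}
        for layer in LAYERS:
            mean, valid = mean_grids[(key, layer)]
            masks[layer] = defective_mask(solutions[(key, layer)], mean, valid)
            valids[layer] = valid
        for la, lb in (("GCIPL", "INL"), ("GCIPL", "ORC"), ("INL", "ORC")):
            res = agreement_stats(masks[la], masks[lb],
                                  valid=valids[la] & valids[lb], layer_pair=(la, lb))
            agreement_rows.append({
                "stratum": f"{key[0]}/{key[1]}", "pair": f"{la}-{lb}",
                "percent_agreement": res.percent_agreement,
                "kappa": res.kappa if res.kappa is not None else "N/A",
                "p_value": res.p_value if res.p_value is not None else "N/A",
            })
    agreement_frame = pd.DataFrame(agreement_rows)
    agreement_frame.to_csv(stage_dir / "agreement.csv", index=False)

    # -- severity ---------------------------------------------------------
    stage_dir = _stage(run_dir, "severity", config)
    severity_rows = []
    for rec in glaucoma:
        c = classifications[rec.pid]
        key = (c.defect_type, c.md_bin)
        row = {"pid": rec.pid, "stratum": f"{key[0]}/{key[1]}",
               "MD": rec.vf.md, "PSD": rec.vf.psd}
        gc_key = (key, "GCIPL")
        mask = None
        if gc_key in solutions:
            mean, valid = mean_grids[gc_key]
            mask = defective_mask(solutions[gc_key], mean, valid)
        for layer in LAYERS:
            value = np.nan
            if mask is not None and mask.any():
                try:
                    value = within_outside_difference(grids[layer][rec.pid], mask)
                except ValueError:
                    logger.info("no within/outside value for %s %s", rec.pid, layer)
            row[f"{layer}_diff"] = value
        for la, lb in (("GCIPL", "INL"), ("GCIPL", "ORC"), ("INL", "ORC")):
            try:
                row[f"r_{la}_{lb}"] = cross_layer_r(grids[la][rec.pid], grids[lb][rec.pid])
            except ValueError:
                row[f"r_{la}_{lb}"] = np.nan
        severity_rows.append(row)
    severity_frame = pd.DataFrame(severity_rows)
    severity_frame.to_csv(stage_dir / "per_participant.csv", index=False)
    corrs = global_severity_correlations(severity_frame)
    correlations_frame(corrs).to_csv(stage_dir / "global_correlations.csv", index=False)

    logger.info("pipeline complete in %.1fs", time.time() - t0)
    return run_dir
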