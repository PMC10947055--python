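"""Demographic drivers of healthy macular layer thickness.

Ordinary least squares of whole-scan mean layer thickness on age, spherical
equivalent (SE) and sex (female = 0, male = 1), followed by a single round of
backward elimination: the least significant main effect is removed and
reinstated only if any retained coefficient shifts by >= 10% -- the shift
being what flags a confounder worth matching on.  The surviving covariate
set is exactly what the deviation-map stage matches on per layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import ParticipantRecord, ThicknessMap

COVARIATES = ("age", "SE", "sex")


def mean_layer_thickness(tmap: ThicknessMap) -> float:
    """Arithmetic mean thickness (um) over valid pixels."""
    if not np.any(tmap.valid):
        raise ValueError("map has no valid pixels")
    return float(tmap.values[tmap.valid].mean())


@dataclass
class RegressionModel:
    """OLS fit of mean layer thickness on demographic main effects.

    ``terms`` maps covariate -> (estimate, SE of estimate, two-sided p).
    The design and response are retained so elimination can refit.
    """

    layer: str
    terms: dict
    intercept: float
    n: int
    _design: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]
    _response: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def covariates(self) -> tuple:
        return tuple(self.terms)


@dataclass
class EliminationReport:
    removed_covariate: str
    pct_changes: dict  # retained covariate -> |delta| / |pre| * 100
    reinstated: bool
    final_covariates: frozenset


def covariate_frame(records: list[ParticipantRecord], layer: str) -> pd.DataFrame:
    """Per-participant table of mean thickness and covariates for one layer."""
    rows = []
    for r in records:
        rows.append({
            "pid": r.pid,
            "mean_thickness": mean_layer_thickness(r.maps[layer]),
            "age": r.age,
            "SE": r.se,
            "sex": 1.0 if r.sex == "M" else 0.0,
        })
    return pd.DataFrame(rows)


def _ols(design: pd.DataFrame, response: np.ndarray):
    X = sm.add_constant(design, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear design matrix")
    return sm.OLS(response, X).fit()


def fit_multiple_linear_regression(
    means: np.ndarray | pd.Series,
    covariates: pd.DataFrame,
    layer: str = "",
) -> RegressionModel:
    """OLS of mean thickness on the columns of ``covariates``.

    ``covariates`` must carry numeric columns (sex already 0/1 coded); at
    least 10 participants are required.
    """
    y = np.asarray(means, dtype=float)
    design = covariates.astype(float).reset_index(drop=True)
    if len(y) < 10:
        raise ValueError("need at least 10 participants")
    if len(y) != len(design):
        raise ValueError("response and covariates length mismatch")
    res = _ols(design, y)
    terms = {
        c: (float(res.params[c]), float(res.bse[c]), float(res.pvalues[c]))
        for c in design.columns
    }
    return RegressionModel(layer=layer, terms=terms, intercept=float(res.params["const"]),
                           n=len(y), _design=design, _response=y)


def backward_stepwise_elimination(
    model: RegressionModel, threshold_pct: float = 10.0
) -> EliminationReport:
    """Single elimination round with the 10%-coefficient-shift rule.

    Removes the covariate with the largest p-value, refits, and compares each
    retained coefficient with its pre-removal value (absolute percent change
    against the pre-removal magnitude, intercept excluded).  If any change
    reaches ``threshold_pct`` the removed effect contributed materially and
    is reinstated (final model = all covariates); otherwise the final model
    is the reduced one.
    """
    if len(model.terms) < 2:
        raise ValueError("elimination needs at least 2 covariates")
    removed = max(model.terms, key=lambda c: model.terms[c][2])
    retained = [c for c in model.terms if c != removed]
    res = _ols(model._design[retained], model._response)
    pct_changes = {}
    for c in retained:
        pre = model.terms[c][0]
        post = float(res.params[c])
        if pre != 0:
            pct_changes[c] = abs(post - pre) / abs(pre) * 100.0
        else:
            pct_changes[c] = 0.0 if post == pre else np.inf
    reinstated = any(p >= threshold_pct for p in pct_changes.values())
    final = frozenset(model.terms) if reinstated else frozenset(retained)
    return EliminationReport(removed_covariate=removed, pct_changes=pct_changes,
                             reinstated=reinstated, final_covariates=final)


def required_matching_covariates(report: EliminationReport) -> frozenset:
    """The covariate set the deviation-map stage must match on."""
    return report.final_covariates


def fit_layer_normative_model(
    records: list[ParticipantRecord], layer: str, threshold_pct: float = 10.0
) -> tuple[RegressionModel, EliminationReport]:
    """Full per-layer procedure: OLS on age/SE/sex, then one elimination."""
    frame = covariate_frame(records, layer)
    model = fit_multiple_linear_regression(
        frame["mean_thickness"], frame[list(COVARIATES)], layer=layer
    )
    report = backward_stepwise_elimination(model, threshold_pct)
    return model, report
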