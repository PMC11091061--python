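"""End-to-end orchestration: instances -> phenotypes -> selection -> ladder.

Ties the modules together the way the colonization analysis runs on a real
dataset: aggregate instance records per slide, join the sample design
(plant, root region, replicate), standardize candidate structure
statistics, screen them with the Lasso, refine fixed effects by forward
selection and the random slope by LRT, fit the model ladder, and compute
region contrasts and phenotype rank comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .analysis_workflow import (
    SelectionResult,
    build_model_ladder,
    forward_select,
    lasso_screen,
    random_slope_search,
    rank_compare,
    region_contrasts,
)
from .mlm_engine import ModelSpec, fit_mixed_model, icc, r_squared, standardize_covariates
from .morphometrics import AMF_CLASSES, aggregate_slides, transform

__all__ = ["AnalysisResult", "make_design_table", "run_colonization_analysis"]


@dataclass
class AnalysisResult:
    """Everything the end-to-end analysis produces, table by table."""

    phenotypes: pd.DataFrame
    design: pd.DataFrame
    lasso: SelectionResult
    forward: SelectionResult
    final_spec: object
    ladder: pd.DataFrame
    fits: dict
    contrasts: pd.DataFrame
    pne_icc: float = float("nan")
    pne_r2_conditional: float = float("nan")
    rank_rho_pct_pne: float = float("nan")
    rank_p_pct_pne: float = float("nan")
    notes: list[str] = field(default_factory=list)


def make_design_table(
    phenotypes: pd.DataFrame,
    design: pd.DataFrame,
    response: str,
    covariates: Sequence[str],
) -> tuple[pd.DataFrame, list[str]]:
    """Join per-slide phenotypes with the sample design and scale covariates.

    ``design`` needs columns ``slide_id``, ``plant``, ``region`` (and
    optionally ``replicate``).  Covariate columns with missing values are
    dropped (a class absent from some slides has undefined average size);
    the survivors are z-scored once, shared by every model in the ladder.
    Returns the table and the scaled covariate column names.
    """
    merged = phenotypes.reset_index().merge(design, on="slide_id", how="inner", validate="1:1")
    if merged.empty:
        raise ValueError("no slides shared between phenotypes and design")
    usable = []
    for cov in covariates:
        if merged[cov].isna().any():
            warnings.warn(f"covariate {cov!r} has missing values; dropped from candidates")
            continue
        usable.append(cov)
    merged = standardize_covariates(merged, usable)
    return merged, [c + "_scaled" for c in usable]


def run_colonization_analysis(
    records: pd.DataFrame,
    design: pd.DataFrame,
    response: str = "total_pct_colonization",
    conf_threshold: float = 0.7,
    seed: int = 0,
    alpha: float = 0.05,
    folds: int = 10,
) -> AnalysisResult:
    """Run the full inference procedure on an instance-record table.

    Candidate predictors are the per-class counts and average sizes of the
    five AMF structure classes.  Selection: pooled Lasso screen (seeded
    k-fold CV, 1-SE rule), then mixed-model forward selection from the
    region-only model, then a random-slope search over the selected
    covariates.  The ladder, Tukey region contrasts for the structure
    statistics and phenotypes, the logit-PNE random-intercept model, and
    the percent-colonization vs PNE rank correlation complete the analysis.
    """
    phen = aggregate_slides(records, conf_threshold=conf_threshold)
    candidates = [f"count_{c}" for c in AMF_CLASSES] + [f"size_{c}" for c in AMF_CLASSES]
    data, scaled = make_design_table(phen, design, response, candidates)

    sel = lasso_screen(data[scaled], data[response], folds=folds, seed=seed)
    base = ModelSpec(response, ("region",), method="ml")
    fwd = forward_select(base, sel.selected or scaled, data, alpha=alpha)
    spec = fwd.final_spec
    spec = random_slope_search(spec, fwd.selected, data, alpha=alpha)

    covs = tuple(t for t in spec.fixed if t != "region")
    ladder, fits = build_model_ladder(data, response, covs, slope=spec.random_slope)

    structure_vars = [c for c in candidates if not data[c].isna().any()]
    pheno_vars = [response, "total_count_density", "pne"]
    contr = region_contrasts(data, structure_vars + pheno_vars, adjust="tukey")

    result = AnalysisResult(
        phenotypes=phen,
        design=data,
        lasso=sel,
        forward=fwd,
        final_spec=spec,
        ladder=ladder,
        fits=fits,
        contrasts=contr,
    )

    # logit-PNE random-intercept model with region as the fixed effect
    pne = data["pne"].clip(1e-6, 1 - 1e-6)
    pne_data = data.assign(pne_logit=transform(pne, "logit"))
    try:
        pne_fit = fit_mixed_model(pne_data, ModelSpec("pne_logit", ("region",)))
        result.pne_icc = icc(pne_fit.var_u0, pne_fit.var_resid)
        result.pne_r2_conditional = r_squared(pne_fit)[1]
    except (RuntimeError, ValueError) as exc:
        result.notes.append(f"PNE model failed: {exc}")

    per_plant = data.groupby("plant")[[response, "pne"]].mean().dropna()
    if len(per_plant) >= 4:
        rho, p = rank_compare(per_plant[response], per_plant["pne"])
        result.rank_rho_pct_pne, result.rank_p_pct_pne = rho, p
    return result
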