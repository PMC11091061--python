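"""Inference workflow: variable selection, the model ladder, region contrasts.

The procedure mirrors the colonization analysis: Lasso screening of
candidate structure statistics on the pooled standardized data, forward
selection of fixed effects by likelihood-ratio tests in the mixed model,
random-slope selection by LRT, assembly of the null-to-full model ladder
with variance-partition diagnostics, Tukey region contrasts, and Spearman
rank comparison of phenotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold

from .mlm_engine import (
    MixedModelFit,
    ModelSpec,
    fit_mixed_model,
    icc,
    information_criteria,
    likelihood_ratio_test,
    pcv,
    r_squared,
    standardize_covariates,
    vpc_at,
)

__all__ = [
    "SelectionResult",
    "lasso_coefficients",
    "lasso_screen",
    "forward_select",
    "random_slope_search",
    "build_model_ladder",
    "region_contrasts",
    "rank_compare",
]

CONTRASTS = (("MID", "TOP"), ("MID", "BOT"), ("TOP", "BOT"))


@dataclass
class SelectionResult:
    """Trace of a variable-selection step, reproducible from its seed."""

    candidates: tuple[str, ...]
    selected: tuple[str, ...]
    seed: int | None = None
    alphas: np.ndarray | None = None
    coef_path: pd.DataFrame | None = None
    alpha_min: float | None = None
    alpha_1se: float | None = None
    chosen_alpha: float | None = None
    cv_mean: np.ndarray | None = None
    cv_se: np.ndarray | None = None
    trace: list[dict] = field(default_factory=list)
    final_spec: ModelSpec | None = None


def lasso_coefficients(X: np.ndarray, y: np.ndarray, penalty: float) -> np.ndarray:
    """L1-penalized least-squares coefficients at one penalty.

    Uses scikit-learn's objective ``(1/2n)||y - Xb||^2 + penalty * ||b||_1``
    (no intercept penalty; responses and columns are expected centered /
    standardized).  ``penalty=0`` falls back to ordinary least squares.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if penalty == 0:
        coef, *_ = np.linalg.lstsq(np.column_stack([np.ones(len(X)), X]), y, rcond=None)
        return coef[1:]
    model = Lasso(alpha=penalty, fit_intercept=True, max_iter=50_000, tol=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model.coef_


def lasso_screen(
    X: pd.DataFrame,
    y: Sequence[float],
    folds: int = 10,
    seed: int = 0,
    n_alphas: int = 100,
    one_se: bool = True,
) -> SelectionResult:
    """Screen candidate predictors by cross-validated Lasso.

    The penalty grid comes from the full-data coordinate-descent path; the
    penalty is chosen by seeded k-fold cross-validation with the 1-SE rule
    (the largest penalty whose mean CV error is within one standard error
    of the minimum), and the selected set is the support of the full-data
    fit at that penalty.  Constant columns are dropped with a warning.
    """
    X = X.copy()
    y = np.asarray(y, dtype=float)
    if len(X) <= folds or folds < 2:
        raise ValueError("need n > folds >= 2")
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant columns: {constant}")
        X = X.drop(columns=constant)
    cols = tuple(X.columns)
    Xm = X.to_numpy(dtype=float)

    # lasso_path fits no intercept: center within each training fold
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        alphas, coefs, _ = lasso_path(Xm - Xm.mean(axis=0), y - y.mean(), n_alphas=n_alphas)
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        mse = np.empty((len(alphas), folds))
        for f, (tr, te) in enumerate(kf.split(Xm)):
            x_mean, y_mean = Xm[tr].mean(axis=0), y[tr].mean()
            _, coefs_f, _ = lasso_path(Xm[tr] - x_mean, y[tr] - y_mean, alphas=alphas)
            resid = (y[te] - y_mean)[:, None] - (Xm[te] - x_mean) @ coefs_f
            mse[:, f] = np.mean(resid**2, axis=0)
    cv_mean = mse.mean(axis=1)
    cv_se = mse.std(axis=1, ddof=1) / np.sqrt(folds)
    i_min = int(np.argmin(cv_mean))
    alpha_min = float(alphas[i_min])
    within = cv_mean <= cv_mean[i_min] + cv_se[i_min]
    alpha_1se = float(alphas[within].max())
    chosen = alpha_1se if one_se else alpha_min

    coef_chosen = lasso_coefficients(Xm, y, chosen)
    selected = tuple(c for c, b in zip(cols, coef_chosen) if b != 0.0)
    return SelectionResult(
        candidates=cols,
        selected=selected,
        seed=seed,
        alphas=alphas,
        coef_path=pd.DataFrame(coefs.T, index=alphas, columns=cols),
        alpha_min=alpha_min,
        alpha_1se=alpha_1se,
        chosen_alpha=float(chosen),
        cv_mean=cv_mean,
        cv_se=cv_se,
    )


def forward_select(
    base: ModelSpec,
    candidates: Sequence[str],
    data: pd.DataFrame,
    alpha: float = 0.05,
) -> SelectionResult:
    """Greedy forward selection of fixed effects by mixed-model LRT.

    At each step the candidate with the smallest likelihood-ratio p-value
    against the current model is added while p < ``alpha``.  Fits use ML
    (fixed effects differ between the compared models); the procedure is
    deterministic given the data.
    """
    remaining = [c for c in candidates if c not in base.fixed]
    current = base.with_method("ml")
    current_fit = fit_mixed_model(data, current)
    trace: list[dict] = []
    while remaining:
        best: tuple[float, str, MixedModelFit] | None = None
        for cand in remaining:
            cand_fit = fit_mixed_model(data, current.with_terms(cand))
            lrt = likelihood_ratio_test(current_fit, cand_fit)
            if best is None or lrt.pvalue < best[0]:
                best = (lrt.pvalue, cand, cand_fit)
        p_best, term, fit = best
        added = p_best < alpha
        trace.append({"term": term, "pvalue": p_best, "added": added})
        if not added:
            break
        current = current.with_terms(term)
        current_fit = fit
        remaining.remove(term)
    final = ModelSpec(base.response, current.fixed, base.random_slope, base.method)
    return SelectionResult(
        candidates=tuple(candidates),
        selected=tuple(t for t in current.fixed if t not in base.fixed),
        trace=trace,
        final_spec=final,
    )


def random_slope_search(
    spec: ModelSpec,
    slope_candidates: Sequence[str],
    data: pd.DataFrame,
    alpha: float = 0.05,
) -> ModelSpec:
    """Test a random slope on each candidate; keep the most significant one.

    Each candidate slope model is compared with the random-intercept model
    by ML likelihood-ratio test (2 df: slope variance plus intercept-slope
    covariance).  At most one slope is retained (the engine's constraint),
    the one with the smallest p-value below ``alpha``.  Non-convergent
    candidates are skipped with a warning.
    """
    base = spec.with_slope(None).with_method("ml")
    base_fit = fit_mixed_model(data, base)
    best: tuple[float, str] | None = None
    for cand in slope_candidates:
        try:
            cand_fit = fit_mixed_model(data, base.with_slope(cand))
            lrt = likelihood_ratio_test(base_fit, cand_fit)
        except (RuntimeError, ValueError) as exc:
            warnings.warn(f"random-slope candidate {cand!r} skipped: {exc}")
            continue
        if lrt.pvalue < alpha and (best is None or lrt.pvalue < best[0]):
            best = (lrt.pvalue, cand)
    return spec.with_slope(best[1]) if best else spec.with_slope(spec.random_slope)


def build_model_ladder(
    data: pd.DataFrame,
    response: str,
    covariates: Sequence[str] = (),
    slope: str | None = None,
    include_region: bool = True,
) -> tuple[pd.DataFrame, dict[str, dict[str, MixedModelFit]]]:
    """Fit the null-to-full model ladder and tabulate its diagnostics.

    The sequence is: null (random intercept only); + region; + each
    covariate cumulatively; + the random slope.  Each row reports REML
    fixed effects and variance components, PCV of both components against
    the null, ICC (or VPC at the mean of the slope covariate for slope
    models), marginal/conditional R^2, and ML-based AIC/BIC/deviance.
    ML deviance is checked to be non-increasing down the ladder.
    """
    specs: list[tuple[str, ModelSpec]] = []
    spec = ModelSpec(response)
    specs.append(("model_1_null", spec))
    k = 2
    if include_region:
        spec = spec.with_terms("region")
        specs.append((f"model_{k}_region", spec))
        k += 1
    for cov in covariates:
        spec = spec.with_terms(cov)
        specs.append((f"model_{k}_{cov}", spec))
        k += 1
    if slope is not None:
        specs.append((f"model_{k}_slope_{slope}", spec.with_slope(slope)))

    rows = []
    fits: dict[str, dict[str, MixedModelFit]] = {}
    null_reml: MixedModelFit | None = None
    prev_deviance = np.inf
    for name, s in specs:
        reml_fit = fit_mixed_model(data, s.with_method("reml"))
        ml_fit = fit_mixed_model(data, s.with_method("ml"))
        fits[name] = {"reml": reml_fit, "ml": ml_fit}
        if null_reml is None:
            null_reml = reml_fit
        aic, bic, deviance = information_criteria(ml_fit)
        if deviance > prev_deviance + 1e-6:
            warnings.warn(f"{name}: ML deviance increased along the ladder ({deviance:.4f})")
        prev_deviance = min(prev_deviance, deviance)
        is_null = name.endswith("null")
        marginal, conditional = r_squared(reml_fit)
        if reml_fit.has_random_slope:
            partition = float(vpc_at(reml_fit, reml_fit.slope_x_mean))
        else:
            partition = icc(reml_fit.var_u0, reml_fit.var_resid)
        row = {
            "model": name,
            "fixed": "+".join(s.fixed) if s.fixed else "(intercept)",
            "random_slope": s.random_slope or "",
            "var_plants": reml_fit.var_u0,
            "var_samples": reml_fit.var_resid,
            "var_slope": reml_fit.var_u1,
            "cov_intercept_slope": reml_fit.cov_u0u1,
            "var_fixed": reml_fit.var_fixed if not is_null else np.nan,
            "pcv_plants": np.nan if is_null else pcv(null_reml.var_u0, reml_fit.var_u0),
            "pcv_samples": np.nan if is_null else pcv(null_reml.var_resid, reml_fit.var_resid),
            "icc_or_vpc": partition,
            "r2_marginal": np.nan if is_null else marginal,
            "r2_conditional": conditional,
            "aic": aic,
            "bic": bic,
            "deviance": deviance,
            "converged": reml_fit.converged and ml_fit.converged,
        }
        for term, value in reml_fit.fe_params.items():
            row[f"beta[{term}]"] = value
        rows.append(row)
    return pd.DataFrame(rows).set_index("model"), fits


def region_contrasts(
    data: pd.DataFrame,
    variables: Sequence[str],
    adjust: Literal["tukey", "none"] = "tukey",
) -> pd.DataFrame:
    """Pairwise region contrasts (MID-TOP, MID-BOT, TOP-BOT) per variable.

    Computed on the pooled one-way region layout.  ``tukey`` refers the
    studentized statistic on the pooled within-region mean square to the
    studentized-range distribution; ``none`` gives plain pairwise
    pooled-variance t-tests.
    """
    if "region" not in data.columns:
        raise ValueError("data needs a 'region' column")
    rows = []
    for var in variables:
        sub = data[["region", var]].dropna()
        groups = {g: s[var].to_numpy(dtype=float) for g, s in sub.groupby("region")}
        for g, vals in groups.items():
            if len(vals) < 2:
                raise ValueError(f"region {g!r} has fewer than 2 observations for {var!r}")
        k = len(groups)
        n_total = sum(len(v) for v in groups.values())
        mse = sum((len(v) - 1) * np.var(v, ddof=1) for v in groups.values()) / (n_total - k)
        df_w = n_total - k
        for g1, g2 in CONTRASTS:
            if g1 not in groups or g2 not in groups:
                continue
            a, b = groups[g1], groups[g2]
            est = a.mean() - b.mean()
            if adjust == "tukey":
                se = np.sqrt(mse / 2.0 * (1.0 / len(a) + 1.0 / len(b)))
                q = abs(est) / se if se > 0 else 0.0
                p = float(stats.studentized_range.sf(q, k, df_w)) if se > 0 else 1.0
            else:
                sp2 = ((len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1)) / (
                    len(a) + len(b) - 2
                )
                se = np.sqrt(sp2 * (1.0 / len(a) + 1.0 / len(b)))
                t = est / se if se > 0 else 0.0
                p = float(2.0 * stats.t.sf(abs(t), len(a) + len(b) - 2)) if se > 0 else 1.0
            rows.append(
                {"variable": var, "contrast": f"{g1}-{g2}", "estimate": est, "pvalue": min(p, 1.0)}
            )
    return pd.DataFrame(rows)


def rank_compare(pheno_a: Sequence[float], pheno_b: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (midranks for ties) between paired values."""
    a = np.asarray(pheno_a, dtype=float)
    b = np.asarray(pheno_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be paired 1-d vectors")
    if len(a) < 4:
        raise ValueError("need at least 4 paired values")
    res = stats.spearmanr(a, b)
    return float(res.statistic), float(res.pvalue)
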