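"""Two-level Gaussian mixed linear models with variance-partition diagnostics.

The models are random-intercept (optionally plus one random slope) linear
mixed models for slide-level colonization phenotypes grouped by plant:

    y_ij = X_ij b + u_0i + u_1i * x_1ij + e_ij,
    (u_0i, u_1i) ~ N(0, S_u),  e_ij ~ N(0, s2_e),

with i indexing plants and j slides within plant.  Fitting is delegated to
``statsmodels`` ``MixedLM``; random-intercept-only fits are additionally
polished by a one-dimensional profiled-(RE)ML optimization over the
variance ratio so that on balanced one-way data the estimates agree with
the closed-form ANOVA estimators to high precision.

The diagnostics are the multilevel variance-partition quantities:

* ICC  = s2_u0 / (s2_u0 + s2_e)                       (intercept models)
* PCV  = (v_ref - v_new) / v_ref                       (vs a reference fit)
* VPC(x) = (s2_u0 + s2_u1 x^2 + 2 s_u01 x)
           / (s2_u0 + s2_u1 x^2 + 2 s_u01 x + s2_e)    (slope models)
* marginal / conditional R^2 on the fixed-effect and fixed+random
  variance shares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

__all__ = [
    "ModelSpec",
    "MixedModelFit",
    "LRTResult",
    "standardize_covariates",
    "fit_mixed_model",
    "icc",
    "pcv",
    "vpc_at",
    "r_squared",
    "information_criteria",
    "likelihood_ratio_test",
]

_REGION_LEVELS = ("TOP", "MID", "BOT")
_REGION_REFERENCE = "MID"  # intercept = MID mean; dummies for TOP and BOT


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one model in the ladder.

    ``fixed`` lists fixed-effect terms: the literal ``"region"`` expands to
    TOP/BOT dummies against the MID reference; any other entry names a
    covariate column (standardized columns by convention carry a
    ``_scaled`` suffix).  ``random_slope`` names the covariate whose
    coefficient varies by plant; it requires the (always-present) random
    intercept.  ``method`` selects REML or ML estimation.
    """

    response: str
    fixed: tuple[str, ...] = ()
    random_slope: str | None = None
    method: Literal["reml", "ml"] = "reml"

    def __post_init__(self) -> None:
        if self.method not in ("reml", "ml"):
            raise ValueError("method must be 'reml' or 'ml'")
        if self.random_slope is not None and self.random_slope == "region":
            raise ValueError("random slope must name a continuous covariate")

    def with_terms(self, *terms: str) -> "ModelSpec":
        return ModelSpec(self.response, self.fixed + tuple(terms), self.random_slope, self.method)

    def with_slope(self, covariate: str | None) -> "ModelSpec":
        return ModelSpec(self.response, self.fixed, covariate, self.method)

    def with_method(self, method: str) -> "ModelSpec":
        return ModelSpec(self.response, self.fixed, self.random_slope, method)  # type: ignore[arg-type]

    @property
    def formula(self) -> str:
        terms = ["1"]
        for t in self.fixed:
            if t == "region":
                terms.append(f"C(region, Treatment('{_REGION_REFERENCE}'))")
            else:
                terms.append(t)
        return f"{self.response} ~ " + " + ".join(terms)


@dataclass
class MixedModelFit:
    """Estimates and diagnostics from one mixed-model fit."""

    spec: ModelSpec
    fe_params: pd.Series
    fe_se: pd.Series
    var_u0: float
    var_u1: float
    cov_u0u1: float
    var_resid: float
    var_fixed: float
    loglike: float
    n_obs: int
    n_params: int
    converged: bool
    at_boundary: bool = False
    slope_x_mean: float = 0.0
    slope_x_sq_mean: float = 0.0
    notes: list[str] = field(default_factory=list)

    @property
    def has_random_slope(self) -> bool:
        return self.spec.random_slope is not None

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglike

    @property
    def var_random(self) -> float:
        """Observation-averaged random-effect variance (plant level)."""
        if not self.has_random_slope:
            return self.var_u0
        return (
            self.var_u0
            + self.var_u1 * self.slope_x_sq_mean
            + 2.0 * self.cov_u0u1 * self.slope_x_mean
        )


def standardize_covariates(
    data: pd.DataFrame, columns: Sequence[str], suffix: str = "_scaled"
) -> pd.DataFrame:
    """Z-score covariates once, on the analysis dataset, shared across models."""
    out = data.copy()
    for col in columns:
        x = out[col].astype(float)
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"covariate {col!r} is constant; cannot standardize")
        out[col + suffix] = (x - x.mean()) / sd
    return out


def _rename_fe(index: pd.Index) -> pd.Index:
    ugly = f"C(region, Treatment('{_REGION_REFERENCE}'))"
    return pd.Index([name.replace(f"{ugly}[T.", "region").rstrip("]") if ugly in name else name for name in index])


def _validate(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    for col in ("plant",) + tuple(t for t in spec.fixed) + (spec.response,):
        name = "region" if col == "region" else col
        if name not in data.columns:
            raise ValueError(f"design table lacks column {name!r}")
    if data[spec.response].isna().any():
        raise ValueError("missing values in the response are not allowed")
    if data["plant"].nunique() < 2:
        raise ValueError("at least 2 plants are required (singular grouping)")
    if (data.groupby("plant").size() < 2).any():
        warnings.warn("some plants have a single observation; variance components weakly identified")
    return data.reset_index(drop=True)


def _polish_random_intercept(model: MixedLM, psi_start: float):
    """1-D profiled-(RE)ML refinement over psi = s2_u0 / s2_e.

    Works on the model's own likelihood so the returned log-likelihood is on
    the same scale as statsmodels'.  Returns (fe, var_u0, var_resid, llf,
    at_boundary).
    """
    def negll(logpsi: float) -> float:
        p = MixedLMParams.from_components(cov_re=np.array([[math.exp(logpsi)]]))
        return -model.loglike(p, profile_fe=True)

    lo, hi = -35.0, 15.0
    start = math.log(max(psi_start, 1e-12))
    opt = None
    if psi_start > 1e-6:  # interior start: fast local refinement
        try:
            opt = minimize_scalar(
                negll, bracket=(start - 0.5, start, start + 0.5), method="brent",
                options={"xtol": 1e-11},
            )
            if not (lo <= opt.x <= hi):
                opt = None
        except (ValueError, RuntimeError):
            opt = None
    if opt is None:  # boundary or bracketing failure: global bounded search
        opt = minimize_scalar(negll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10})
    if lo <= start <= hi and negll(start) < opt.fun:  # never worse than the optimizer's answer
        opt.x, opt.fun = start, negll(start)
    psi = math.exp(opt.x)
    at_boundary = opt.x < lo + 1e-3
    vcomp = np.empty(0)
    fe = model.get_fe_params(np.array([[psi]]), vcomp)
    if isinstance(fe, tuple):
        fe = fe[0]
    fe = np.asarray(fe, dtype=float).ravel()
    scale = float(model.get_scale(fe, np.array([[psi]]), vcomp))
    return fe, psi * scale, scale, -float(opt.fun), at_boundary


def fit_mixed_model(data: pd.DataFrame, spec: ModelSpec) -> MixedModelFit:
    """Fit the two-level mixed model described by ``spec``.

    Maximizes the Gaussian (restricted) likelihood; variance estimates are
    constrained non-negative by the square-root parameterization, and fits
    hitting the zero-variance boundary are flagged rather than rejected.
    ``var_fixed`` is the empirical variance (ddof=1) of the fixed-effect
    linear predictor across observations.
    """
    data = _validate(data, spec)
    re_formula = f"~ {spec.random_slope}" if spec.random_slope else "~ 1"
    model = MixedLM.from_formula(spec.formula, data, groups=data["plant"], re_formula=re_formula)
    reml = spec.method == "reml"
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for opt_method in ("lbfgs", "bfgs", "cg", "powell"):
            try:
                res = model.fit(reml=reml, method=opt_method, maxiter=2000)
            except Exception:
                continue
            if res.converged:
                break
    if res is None:
        raise RuntimeError(f"all optimizers failed for {spec.formula}")

    notes: list[str] = []
    fe = np.asarray(res.fe_params, dtype=float)
    cov_re = np.asarray(res.cov_re, dtype=float)
    scale = float(res.scale)
    llf = float(res.llf)
    at_boundary = False

    if spec.random_slope is None:
        psi_start = max(cov_re[0, 0] / scale, 1e-12)
        fe, var_u0, scale, llf, at_boundary = _polish_random_intercept(model, psi_start)
        var_u1, cov_u0u1 = 0.0, 0.0
        if at_boundary:
            notes.append("between-plant variance at the zero boundary")
    else:
        var_u0 = max(float(cov_re[0, 0]), 0.0)
        var_u1 = max(float(cov_re[1, 1]), 0.0)
        cov_u0u1 = float(cov_re[0, 1])
        bound = math.sqrt(var_u0 * var_u1)
        if abs(cov_u0u1) > bound:  # numerical excess over PSD boundary
            cov_u0u1 = math.copysign(bound, cov_u0u1)
            notes.append("intercept-slope covariance clipped to the PSD boundary")

    exog = np.asarray(model.exog, dtype=float)
    linpred = exog @ fe
    var_fixed = float(np.var(linpred, ddof=1)) if len(linpred) > 1 else 0.0
    k_fe = exog.shape[1]
    n_params = k_fe + (2 if spec.random_slope is None else 4)

    fe_names = _rename_fe(pd.Index(model.exog_names))
    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        warnings.simplefilter("ignore")
        fe_se = pd.Series(np.asarray(res.bse_fe, dtype=float), index=fe_names)
    slope_x_mean = slope_x_sq_mean = 0.0
    if spec.random_slope is not None:
        x1 = data[spec.random_slope].to_numpy(dtype=float)
        slope_x_mean = float(np.mean(x1))
        slope_x_sq_mean = float(np.mean(x1**2))

    return MixedModelFit(
        spec=spec,
        fe_params=pd.Series(fe, index=fe_names),
        fe_se=fe_se,
        var_u0=var_u0,
        var_u1=var_u1,
        cov_u0u1=cov_u0u1,
        var_resid=scale,
        var_fixed=var_fixed,
        loglike=llf,
        n_obs=int(model.nobs),
        n_params=n_params,
        converged=bool(res.converged),
        at_boundary=at_boundary,
        slope_x_mean=slope_x_mean,
        slope_x_sq_mean=slope_x_sq_mean,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# variance-partition diagnostics


def icc(var_plant: float, var_sample: float) -> float:
    """Intraclass correlation: between-plant share of the total variance."""
    if var_plant < 0 or var_sample < 0:
        raise ValueError("variances must be non-negative")
    total = var_plant + var_sample
    if total == 0:
        warnings.warn("both variance components are zero: ICC undefined", stacklevel=2)
        return math.nan
    return var_plant / total


def pcv(var_ref: float, var_new: float) -> float:
    """Proportional change in a variance component relative to a reference.

    Positive values mean the new model absorbed that share of the reference
    component; negative values (variance increased) are legitimate.
    """
    if var_ref <= 0:
        warnings.warn("reference variance is zero: PCV undefined", stacklevel=2)
        return math.nan
    return (var_ref - var_new) / var_ref


def _vpc_components(fit_or_components):
    if isinstance(fit_or_components, MixedModelFit):
        f = fit_or_components
        return f.var_u0, f.var_u1, f.cov_u0u1, f.var_resid
    return fit_or_components


def vpc_at(fit: "MixedModelFit | tuple[float, float, float, float]", x) -> np.ndarray | float:
    """Variance partition coefficient at arbuscule count ``x``.

    For random-slope fits the plant-level variance is the quadratic
    ``s2_u0 + s2_u1 x^2 + 2 s_u01 x``; VPC is its share of the total.  With
    a zero slope variance and covariance this reduces to the ICC for all x.
    """
    var_u0, var_u1, cov_u0u1, var_resid = _vpc_components(fit)
    if var_u0 < 0 or var_u1 < 0 or var_resid < 0 or cov_u0u1**2 > var_u0 * var_u1 + 1e-12:
        raise ValueError("variance parameters violate positive semi-definiteness")
    x = np.asarray(x, dtype=float)
    plant_var = var_u0 + var_u1 * x**2 + 2.0 * cov_u0u1 * x
    out = plant_var / (plant_var + var_resid)
    return float(out) if out.ndim == 0 else out


def r_squared(fit: MixedModelFit) -> tuple[float, float]:
    """Marginal and conditional R^2 (fixed / fixed+random variance shares).

    For random-slope fits the plant-level variance entering the denominator
    is averaged over the observed slope covariate:
    ``s2_u0 + s2_u1 mean(x^2) + 2 s_u01 mean(x)``.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; R^2 undefined")
    denom = fit.var_fixed + fit.var_random + fit.var_resid
    if denom <= 0:
        warnings.warn("zero total variance: R^2 undefined", stacklevel=2)
        return math.nan, math.nan
    marginal = fit.var_fixed / denom
    conditional = (fit.var_fixed + fit.var_random) / denom
    return marginal, conditional


def information_criteria(fit: MixedModelFit) -> tuple[float, float, float]:
    """(AIC, BIC, deviance) with deviance = -2 log L and
    AIC = deviance + 2k, BIC = deviance + k ln(n)."""
    deviance = fit.deviance
    aic = deviance + 2.0 * fit.n_params
    bic = deviance + fit.n_params * math.log(fit.n_obs)
    return aic, bic, deviance


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    pvalue: float


def likelihood_ratio_test(nested: MixedModelFit, full: MixedModelFit) -> LRTResult:
    """Likelihood ratio test of a nested model against a fuller one.

    Both fits must be on identical data; when the fixed effects differ they
    must be ML fits (REML likelihoods are not comparable across fixed-effect
    structures).  The statistic is the deviance difference referred to a
    chi-square with df equal to the parameter-count difference.
    """
    if nested.n_obs != full.n_obs:
        raise ValueError("fits are not on the same data (n_obs differs)")
    df = full.n_params - nested.n_params
    if df <= 0:
        raise ValueError("'full' must have more parameters than 'nested'")
    fixed_differ = set(nested.fe_params.index) != set(full.fe_params.index)
    if fixed_differ and (nested.spec.method != "ml" or full.spec.method != "ml"):
        raise ValueError("models differing in fixed effects must both be fitted by ML")
    stat = nested.deviance - full.deviance
    if stat < -1e-6:
        raise ValueError(f"negative LRT statistic ({stat:.3g}): models not nested or fit failed")
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return LRTResult(stat, df, p)
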