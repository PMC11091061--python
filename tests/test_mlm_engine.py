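"""Mixed-model fitting, ICC/PCV/VPC and fit-quality diagnostics."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from mycostats.mlm_engine import (
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
from mycostats.synthetic_data import SimParams, simulate_mlm_dataset


def one_way_data(seed, n_plants=12, n_reps=9, var_u0=0.01, var_resid=0.005, mu=0.33):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, math.sqrt(var_u0), n_plants)
    y = mu + np.repeat(u, n_reps) + rng.normal(0, math.sqrt(var_resid), n_plants * n_reps)
    return pd.DataFrame({"plant": np.repeat(np.arange(n_plants), n_reps), "y": y})


def anova_estimates(df, n_reps):
    """Closed-form balanced one-way ANOVA variance-component oracle."""
    msb = n_reps * df.groupby("plant")["y"].mean().var(ddof=1)
    msw = df.groupby("plant")["y"].var(ddof=1).mean()
    return max(0.0, (msb - msw) / n_reps), msw


class TestFitting:
    @pytest.mark.parametrize("seed", range(5))
    def test_reml_equals_anova_oracle_on_balanced_design(self, seed):
        df = one_way_data(seed)
        su2, se2 = anova_estimates(df, 9)
        fit = fit_mixed_model(df, ModelSpec("y"))
        assert fit.var_u0 == pytest.approx(su2, rel=1e-6)
        assert fit.var_resid == pytest.approx(se2, rel=1e-6)

    def test_zero_plant_variance_degenerates_cleanly(self):
        # seed chosen so the between-plant mean square falls below the
        # within-plant one: the REML solution sits at the zero boundary
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"plant": np.repeat(np.arange(12), 9), "y": 0.4 + rng.normal(0, 0.08, 108)})
        assert anova_estimates(df, 9)[0] == 0.0
        fit = fit_mixed_model(df, ModelSpec("y"))
        assert fit.var_u0 < 1e-6
        assert fit.fe_params["Intercept"] == pytest.approx(df["y"].mean(), abs=1e-8)

    def test_region_reference_level_is_mid(self):
        design, _ = simulate_mlm_dataset(SimParams(seed=5))
        fit = fit_mixed_model(design, ModelSpec("y", ("region",)))
        assert set(fit.fe_params.index) == {"Intercept", "regionTOP", "regionBOT"}

    def test_singular_grouping_rejected(self):
        df = one_way_data(0).query("plant == 0")
        with pytest.raises(ValueError, match="2 plants"):
            fit_mixed_model(df, ModelSpec("y"))

    def test_missing_response_rejected(self):
        df = one_way_data(0)
        df.loc[3, "y"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_mixed_model(df, ModelSpec("y"))

    def test_random_slope_fit_recovers_strong_components(self):
        p = SimParams(n_plants=150, seed=21, var_u0=0.01, var_u1=0.005, var_resid=0.002)
        design, truth = simulate_mlm_dataset(p)
        spec = ModelSpec("y", ("region", "arb_count_scaled", "arb_size_scaled"),
                         random_slope="arb_count_scaled")
        fit = fit_mixed_model(design, spec)
        assert fit.var_u0 == pytest.approx(truth["var_u0"], rel=0.5)
        assert fit.var_u1 == pytest.approx(truth["var_u1"], rel=0.5)
        assert fit.n_params == 5 + 4

    def test_standardize_covariates(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        out = standardize_covariates(df, ["a"])
        assert out["a_scaled"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["a_scaled"].std(ddof=1) == pytest.approx(1.0)
        with pytest.raises(ValueError, match="constant"):
            standardize_covariates(pd.DataFrame({"a": [1.0, 1.0]}), ["a"])


class TestVariancePartition:
    def test_icc_from_published_percent_colonization_components(self):
        """Null-model plant/sample variances 0.0099/0.0054 give ICC ~0.647."""
        assert icc(0.0099, 0.0054) == pytest.approx(0.6472, rel=0.005)

    def test_icc_from_published_count_density_components(self):
        assert icc(20.689, 27.674) == pytest.approx(0.428, rel=0.005)

    def test_icc_trivials(self):
        assert icc(0.0, 5.0) == 0.0
        with pytest.warns(UserWarning):
            assert math.isnan(icc(0.0, 0.0))

    def test_pcv_from_published_count_density_ladder(self):
        assert pcv(20.689, 6.012) == pytest.approx(0.709, rel=0.005)
        assert pcv(27.674, 21.979) == pytest.approx(0.206, rel=0.005)

    def test_pcv_trivials(self):
        assert pcv(3.0, 3.0) == 0.0
        assert pcv(1.0, 1.5) == pytest.approx(-0.5)  # variance may increase
        with pytest.warns(UserWarning):
            assert math.isnan(pcv(0.0, 1.0))

    def test_vpc_reduces_to_icc_without_slope_variance(self):
        xs = np.linspace(-3, 3, 7)
        out = vpc_at((4.0, 0.0, 0.0, 12.0), xs)
        assert np.allclose(out, icc(4.0, 12.0))

    def test_vpc_printed_formula_values(self):
        assert vpc_at((4.0, 1.0, 0.0, 12.0), 2.0) == pytest.approx(8.0 / 20.0)
        assert vpc_at((4.0, 1.0, 0.0, 12.0), 0.0) == pytest.approx(4.0 / 16.0)

    def test_vpc_algebraic_identity_on_grid(self):
        var_u0, var_u1, cov, var_e = 0.0009, 0.0004, 0.0001, 0.0007
        xs = np.linspace(-4, 4, 41)
        v = vpc_at((var_u0, var_u1, cov, var_e), xs)
        num = var_u0 + var_u1 * xs**2 + 2 * cov * xs
        assert np.allclose(v * (num + var_e) - num, 0.0, atol=1e-15)
        assert ((v >= 0) & (v <= 1)).all()

    def test_vpc_rejects_invalid_covariance(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            vpc_at((1.0, 1.0, 2.0, 1.0), 0.0)

    def test_scale_invariance_of_partition_quantities(self):
        """Multiplying the response by c > 0 leaves ICC/PCV/VPC unchanged."""
        df = one_way_data(8)
        fit1 = fit_mixed_model(df, ModelSpec("y"))
        fit2 = fit_mixed_model(df.assign(y=df["y"] * 7.3), ModelSpec("y"))
        assert icc(fit2.var_u0, fit2.var_resid) == pytest.approx(
            icc(fit1.var_u0, fit1.var_resid), rel=1e-6
        )
        assert pcv(fit2.var_u0, fit2.var_u0 * 0.5) == pcv(fit1.var_u0, fit1.var_u0 * 0.5)


def _fit_stub(var_fixed, var_u0, var_resid, loglike=-1.0, n_obs=108, n_params=3):
    return MixedModelFit(
        spec=ModelSpec("y"),
        fe_params=pd.Series({"Intercept": 0.0}),
        fe_se=pd.Series({"Intercept": 1.0}),
        var_u0=var_u0,
        var_u1=0.0,
        cov_u0u1=0.0,
        var_resid=var_resid,
        var_fixed=var_fixed,
        loglike=loglike,
        n_obs=n_obs,
        n_params=n_params,
        converged=True,
    )


class TestFitQuality:
    def test_null_model_r2_equals_icc(self):
        df = one_way_data(12)
        fit = fit_mixed_model(df, ModelSpec("y"))
        marginal, conditional = r_squared(fit)
        assert marginal == pytest.approx(0.0, abs=1e-12)
        assert conditional == pytest.approx(icc(fit.var_u0, fit.var_resid), abs=1e-12)

    def test_r2_from_published_count_density_components(self):
        """Three-fixed-effect count-density model: R2m ~0.694, R2c ~0.841."""
        fit = _fit_stub(var_fixed=33.276, var_u0=7.049, var_resid=7.642)
        marginal, conditional = r_squared(fit)
        assert marginal == pytest.approx(0.694, rel=0.005)
        assert conditional == pytest.approx(0.841, rel=0.005)

    def test_r2_limits(self):
        fit = _fit_stub(var_fixed=1e12, var_u0=1.0, var_resid=1.0)
        marginal, conditional = r_squared(fit)
        assert marginal == pytest.approx(1.0, abs=1e-9)
        assert conditional == pytest.approx(1.0, abs=1e-9)

    def test_information_criteria_identities(self):
        fit = _fit_stub(0.0, 1.0, 1.0, loglike=-223.9263 / -2.0 * -1.0, n_obs=108, n_params=3)
        fit.loglike = 223.9263 / 2.0
        aic, bic, deviance = information_criteria(fit)
        assert deviance == pytest.approx(-223.9263)
        assert aic == pytest.approx(-217.9263)
        assert bic == pytest.approx(-223.9263 + 3 * math.log(108))
        assert aic - deviance == pytest.approx(2 * fit.n_params, abs=1e-12)


class TestLRT:
    def test_identical_models_give_zero_statistic(self):
        df = one_way_data(1)
        fit = fit_mixed_model(df, ModelSpec("y", method="ml"))
        res = likelihood_ratio_test(fit, _wider(fit))
        assert res.statistic == pytest.approx(0.0, abs=1e-6)
        assert res.pvalue == pytest.approx(1.0, abs=1e-4)

    def test_strong_effect_detected_in_seeded_reps(self):
        hits = 0
        for seed in range(20):
            p = SimParams(n_plants=12, seed=400 + seed,
                          betas=(("arb_count_scaled", 0.0937),),
                          slope_covariate=None, var_u1=0.0)
            design, _ = simulate_mlm_dataset(p)
            f0 = fit_mixed_model(design, ModelSpec("y", method="ml"))
            f1 = fit_mixed_model(design, ModelSpec("y", ("arb_count_scaled",), method="ml"))
            if likelihood_ratio_test(f0, f1).pvalue < 0.001:
                hits += 1
        assert hits >= 19

    def test_reml_fits_with_different_fixed_effects_rejected(self):
        design, _ = simulate_mlm_dataset(SimParams(seed=2))
        f0 = fit_mixed_model(design, ModelSpec("y"))
        f1 = fit_mixed_model(design, ModelSpec("y", ("arb_count_scaled",)))
        with pytest.raises(ValueError, match="ML"):
            likelihood_ratio_test(f0, f1)


def _wider(fit):
    """Same fit presented with one extra parameter (nesting of a model in itself)."""
    import copy

    wider = copy.deepcopy(fit)
    wider.n_params = fit.n_params + 1
    return wider
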