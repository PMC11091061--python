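"""Variable selection, the model ladder, region contrasts, rank comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mycostats.analysis_workflow import (
    build_model_ladder,
    forward_select,
    lasso_coefficients,
    lasso_screen,
    random_slope_search,
    rank_compare,
    region_contrasts,
)
from mycostats.mlm_engine import ModelSpec
from mycostats.synthetic_data import SimParams, simulate_mlm_dataset


class TestLasso:
    def test_zero_penalty_equals_ols(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 4))
        y = X @ [1.0, -0.5, 0.0, 0.2] + rng.normal(0, 0.1, 60)
        ols = np.linalg.lstsq(np.column_stack([np.ones(60), X]), y, rcond=None)[0][1:]
        assert np.allclose(lasso_coefficients(X, y, 0.0), ols)

    def test_huge_penalty_zeroes_everything(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((60, 4))
        y = X @ [1.0, -0.5, 0.0, 0.2]
        assert np.allclose(lasso_coefficients(X, y, 1e6), 0.0)

    def test_orthonormal_design_soft_thresholding(self):
        """With (1/n) X'X = I, each coefficient is soft-thresholded OLS."""
        rng = np.random.default_rng(2)
        n, k = 128, 4
        raw = rng.standard_normal((n, k))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        X = q * np.sqrt(n)  # columns now satisfy X'X = n I
        beta = np.array([2.0, -1.0, 0.3, 0.0])
        y = X @ beta
        b_ols = X.T @ y / n
        for penalty in (0.1, 0.5, 1.5):
            expected = np.sign(b_ols) * np.maximum(np.abs(b_ols) - penalty, 0.0)
            got = lasso_coefficients(X, y, penalty)
            assert np.allclose(got, expected, atol=1e-6)

    def test_screen_recovers_true_support(self):
        rng = np.random.default_rng(3)
        n = 120
        X = pd.DataFrame(rng.standard_normal((n, 6)), columns=[f"x{i}" for i in range(6)])
        y = 2.0 * X["x0"] - 1.5 * X["x3"] + rng.normal(0, 0.3, n)
        res = lasso_screen(X, y, folds=5, seed=0)
        assert set(res.selected) == {"x0", "x3"}
        assert res.alpha_1se >= res.alpha_min

    def test_screen_is_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.standard_normal((50, 3)), columns=list("abc"))
        y = X["a"] + rng.normal(0, 0.5, 50)
        r1 = lasso_screen(X, y, folds=5, seed=7)
        r2 = lasso_screen(X, y, folds=5, seed=7)
        assert r1.selected == r2.selected
        assert r1.chosen_alpha == r2.chosen_alpha
        assert np.array_equal(r1.cv_mean, r2.cv_mean)

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"a": rng.standard_normal(40), "flat": np.ones(40)})
        y = X["a"] + rng.normal(0, 0.2, 40)
        with pytest.warns(UserWarning, match="constant"):
            res = lasso_screen(X, y, folds=4, seed=0)
        assert "flat" not in res.candidates


class TestForwardSelection:
    def test_empty_candidates_returns_base(self):
        design, _ = simulate_mlm_dataset(SimParams(seed=0))
        base = ModelSpec("y", ("region",))
        res = forward_select(base, (), design)
        assert res.final_spec.fixed == base.fixed
        assert res.selected == ()

    def test_strong_effect_added_first(self):
        p = SimParams(n_plants=24, seed=6)
        design, _ = simulate_mlm_dataset(p)
        design["noise_cov"] = np.random.default_rng(6).standard_normal(len(design))
        res = forward_select(
            ModelSpec("y", ("region",)),
            ("noise_cov", "arb_count_scaled", "arb_size_scaled"),
            design,
        )
        assert res.trace[0]["term"] == "arb_count_scaled"
        assert "arb_count_scaled" in res.selected

    def test_null_candidates_usually_rejected(self):
        kept = 0
        for seed in range(20):
            p = SimParams(n_plants=12, seed=700 + seed, betas=(("arb_count_scaled", 0.0937),),
                          slope_covariate=None, var_u1=0.0)
            design, _ = simulate_mlm_dataset(p)
            design["x_null"] = np.random.default_rng(seed).standard_normal(len(design))
            res = forward_select(ModelSpec("y", ("region", "arb_count_scaled")), ("x_null",), design)
            kept += "x_null" in res.selected
        assert kept <= 3  # ~alpha = 0.05 per test


class TestRandomSlopeSearch:
    def test_true_slope_retained(self):
        p = SimParams(n_plants=48, seed=8, var_u1=0.004)
        design, _ = simulate_mlm_dataset(p)
        spec = ModelSpec("y", ("region", "arb_count_scaled", "arb_size_scaled"))
        out = random_slope_search(spec, ("arb_count_scaled", "arb_size_scaled"), design)
        assert out.random_slope == "arb_count_scaled"

    def test_no_slope_usually_retained_under_null(self):
        kept = 0
        for seed in range(10):
            p = SimParams(n_plants=12, seed=900 + seed, var_u1=0.0,
                          cov_u0u1=0.0, slope_covariate=None)
            design, _ = simulate_mlm_dataset(p)
            spec = ModelSpec("y", ("region", "arb_count_scaled", "arb_size_scaled"))
            out = random_slope_search(spec, ("arb_count_scaled",), design)
            kept += out.random_slope is not None
        assert kept <= 2

    def test_empty_candidates_leave_spec_unchanged(self):
        design, _ = simulate_mlm_dataset(SimParams(seed=1))
        spec = ModelSpec("y", ("region",))
        assert random_slope_search(spec, (), design) == spec


@pytest.fixture(scope="module")
def ladder():
    design, _ = simulate_mlm_dataset(SimParams(n_plants=24, seed=10))
    return build_model_ladder(
        design, "y", ("arb_count_scaled", "arb_size_scaled"), slope="arb_count_scaled"
    )


class TestModelLadder:
    def test_deviance_non_increasing(self, ladder):
        table, _ = ladder
        dev = table["deviance"].to_numpy()
        assert (np.diff(dev) <= 1e-6).all()

    def test_null_row_conventions(self, ladder):
        table, _ = ladder
        null = table.iloc[0]
        assert np.isnan(null["pcv_plants"]) and np.isnan(null["r2_marginal"])
        assert null["icc_or_vpc"] == pytest.approx(null["r2_conditional"], abs=1e-10)

    def test_pcv_positive_when_strong_fixed_effects_added(self, ladder):
        table, _ = ladder
        assert table["pcv_samples"].iloc[-1] > 0.5

    def test_no_fixed_effects_means_small_pcv(self):
        """PCV stays near zero when the added covariates have no effect."""
        pcvs = []
        for seed in range(10):
            p = SimParams(n_plants=96, seed=1100 + seed, betas=(("arb_count_scaled", 0.0),),
                          beta_region=(0.0, 0.0), slope_covariate=None, var_u1=0.0)
            design, _ = simulate_mlm_dataset(p)
            table, _ = build_model_ladder(design, "y", ("arb_count_scaled",))
            pcvs.append(abs(table["pcv_plants"].iloc[-1]))
        assert np.median(pcvs) < 0.1


class TestRegionContrasts:
    @staticmethod
    def _data(shift_top=0.0, seed=0, n=30):
        rng = np.random.default_rng(seed)
        regions = np.repeat(["TOP", "MID", "BOT"], n)
        y = rng.normal(0, 1, 3 * n)
        y[:n] += shift_top
        return pd.DataFrame({"region": regions, "v": y})

    def test_identical_groups_give_zero_estimates(self):
        df = pd.DataFrame({"region": ["TOP", "TOP", "MID", "MID", "BOT", "BOT"], "v": [1.0] * 6})
        table = region_contrasts(df, ["v"])
        assert (table["estimate"] == 0.0).all()
        assert set(table["contrast"]) == {"MID-TOP", "MID-BOT", "TOP-BOT"}

    def test_large_shift_is_significant(self):
        table = region_contrasts(self._data(shift_top=5.0), ["v"])
        top_bot = table.query("contrast == 'TOP-BOT'").iloc[0]
        assert top_bot["pvalue"] < 0.001
        assert top_bot["estimate"] > 4.0

    def test_unadjusted_matches_ttest_oracle(self):
        df = self._data(shift_top=0.7, seed=3)
        table = region_contrasts(df, ["v"], adjust="none")
        a = df.query("region == 'MID'")["v"]
        b = df.query("region == 'TOP'")["v"]
        oracle = stats.ttest_ind(a, b, equal_var=True)
        row = table.query("contrast == 'MID-TOP'").iloc[0]
        assert row["pvalue"] == pytest.approx(oracle.pvalue, rel=1e-10)
        assert row["estimate"] == pytest.approx(a.mean() - b.mean())

    def test_tukey_never_smaller_than_unadjusted(self):
        df = self._data(shift_top=0.8, seed=4)
        tukey = region_contrasts(df, ["v"], adjust="tukey").set_index("contrast")["pvalue"]
        plain = region_contrasts(df, ["v"], adjust="none").set_index("contrast")["pvalue"]
        assert (tukey >= plain - 1e-12).all()

    def test_small_region_rejected(self):
        df = pd.DataFrame({"region": ["TOP", "MID", "MID", "BOT", "BOT"], "v": [1, 2, 3, 4, 5.0]})
        with pytest.raises(ValueError, match="fewer than 2"):
            region_contrasts(df, ["v"])


class TestRankCompare:
    def test_identical_and_reversed_rankings(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert rank_compare(a, a)[0] == pytest.approx(1.0)
        assert rank_compare(a, a[::-1])[0] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(size=25), rng.normal(size=25)
        rho, _ = rank_compare(a, b)
        oracle = stats.pearsonr(stats.rankdata(a), stats.rankdata(b)).statistic
        assert rho == pytest.approx(oracle, abs=1e-10)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="4"):
            rank_compare([1, 2, 3], [3, 2, 1])
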