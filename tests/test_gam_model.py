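"""Penalized IRLS engine: closed forms, oracles, selection and inference."""

import numpy as np
import pandas as pd
import pytest

from antrisk.gam import (
    Categorical,
    Linear,
    LogisticGAM,
    Smooth1D,
    SmoothTensor2D,
    anova_compare,
)


def _invlogit(e):
    return 1.0 / (1.0 + np.exp(-e))


def _grouped(n11, n10, n01, n00):
    """Binary data: x=1 -> n11 successes / n10 failures; x=0 -> n01 / n00."""
    x = np.r_[np.ones(n11 + n10), np.zeros(n01 + n00)]
    y = np.r_[np.ones(n11), np.zeros(n10), np.ones(n01), np.zeros(n00)]
    return pd.DataFrame({"x": x}), y


class TestParametricClosedForms:
    def test_binary_column_coefficient_is_log_cross_product_odds_ratio(self):
        """Grouped 2x2 data (40,10;10,40): slope = log((40*40)/(10*10)) = log 16."""
        df, y = _grouped(40, 10, 10, 40)
        res = LogisticGAM(y, df, [Linear(["x"])]).fit()
        # the linear term is standardized internally; compare on the odds scale
        sd = df["x"].std(ddof=0)
        x1 = (1.0 - df["x"].mean()) / sd
        x0 = (0.0 - df["x"].mean()) / sd
        slope_raw = res.params[1] * (x1 - x0)
        assert slope_raw == pytest.approx(np.log(16.0), abs=1e-6)

    def test_intercept_only_recovers_logit_of_mean(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        res = LogisticGAM(y, pd.DataFrame(index=range(100)), []).fit()
        assert res.params[0] == pytest.approx(np.log(0.3 / 0.7), abs=1e-8)
        assert res.edf_total == pytest.approx(1.0)

    def test_matches_statsmodels_logistic_oracle(self, rng):
        """Unpenalized fit agrees with statsmodels GLM to 1e-6 (coefs + cov)."""
        import statsmodels.api as sm

        n = 1500
        df = pd.DataFrame(
            {"x1": rng.normal(size=n), "g": rng.choice(["a", "b", "c"], n)}
        )
        eta = 0.3 + 0.8 * df["x1"] + 0.5 * (df["g"] == "b")
        y = (rng.random(n) < _invlogit(eta)).astype(float)
        model = LogisticGAM(y, df, [Linear(["x1"]), Categorical("g", "a")])
        res = model.fit(tol=1e-12)
        sm_res = sm.GLM(y, model.X, family=sm.families.Binomial()).fit()
        assert np.abs(res.params - np.asarray(sm_res.params)).max() < 1e-6
        assert np.abs(res.cov_params - np.asarray(sm_res.cov_params())).max() < 1e-6
        assert res.aic == pytest.approx(sm_res.aic, abs=1e-6)

    def test_aic_identity(self, rng):
        df = pd.DataFrame({"x1": rng.normal(size=500)})
        y = (rng.random(500) < 0.5).astype(float)
        res = LogisticGAM(y, df, [Linear(["x1"])]).fit()
        assert res.aic == pytest.approx(res.deviance + 2 * res.edf_total)


class TestWaldTables:
    def test_null_coefficient_gives_or_one_z_zero_p_one(self):
        # perfectly balanced groups force the dummy coefficient to exactly 0
        df, y = _grouped(25, 25, 25, 25)
        df["g"] = np.where(df["x"] == 1, "b", "a")
        res = LogisticGAM(y, df[["g"]], [Categorical("g", "a")]).fit()
        row = res.or_table().set_index("param").loc["g[b]"]
        assert row["odds_ratio"] == pytest.approx(1.0, abs=1e-8)
        assert row["z"] == pytest.approx(0.0, abs=1e-6)
        assert row["p"] == pytest.approx(1.0, abs=1e-6)

    def test_delta_method_consistency(self, rng):
        """Reported SE(OR) = OR * SE(beta), so z = log(OR) / (SE/OR)."""
        df = pd.DataFrame({"g": rng.choice(["a", "b"], 800)})
        y = (rng.random(800) < np.where(df["g"] == "b", 0.7, 0.45)).astype(float)
        tab = LogisticGAM(y, df, [Categorical("g", "a")]).fit().or_table()
        r = tab.set_index("param").loc["g[b]"]
        assert r["se_or"] == pytest.approx(r["odds_ratio"] * r["se_beta"], rel=1e-12)
        assert r["z"] == pytest.approx(
            np.log(r["odds_ratio"]) / (r["se_or"] / r["odds_ratio"]), rel=1e-9
        )

    def test_delta_method_se_close_to_parametric_bootstrap(self, rng):
        """Delta-method SE of the OR within 10% of a bootstrap SE."""
        df = pd.DataFrame({"g": np.r_[["b"] * 300, ["a"] * 300]})
        y0 = (rng.random(600) < np.where(df["g"] == "b", 0.65, 0.45)).astype(float)
        model = LogisticGAM(y0, df, [Categorical("g", "a")])
        res = model.fit()
        r = res.or_table().set_index("param").loc["g[b]"]
        p_hat = res.fittedvalues
        ors = []
        for _ in range(800):
            yb = (rng.random(600) < p_hat).astype(float)
            rb = LogisticGAM(yb, df, [Categorical("g", "a")]).fit()
            ors.append(rb.or_table().set_index("param").loc["g[b]", "odds_ratio"])
        assert np.std(ors) == pytest.approx(r["se_or"], rel=0.10)


class TestPenaltyLimit:
    def _sim(self, rng, n=1500):
        df = pd.DataFrame(
            {
                "d": rng.uniform(0, 10, n),
                "u": rng.uniform(0, 1, n),
                "v": rng.uniform(0, 1, n),
            }
        )
        eta = 0.4 - 0.15 * df["d"] + 0.8 * df["u"] - 0.5 * df["v"]
        y = (rng.random(n) < _invlogit(eta)).astype(float)
        return df, y

    def test_infinite_penalty_collapses_to_parametric_glm(self, rng):
        """Very large λ drives the GAM's fit onto the nested linear GLM.

        λ = 1e10 keeps A = XᵀWX + λS numerically resolvable; still ~8 orders
        of magnitude above the unpenalized curvature, i.e. effectively ∞.
        """
        df, y = self._sim(rng)
        gam = LogisticGAM(
            y, df, [Smooth1D("d", k=8), SmoothTensor2D("u", "v", k_marginal=5)]
        ).fit(lam=1e10, tol=1e-12)
        glm = LogisticGAM(
            y, df, [Linear(["d"]), Linear(["u", "v"], product_pairs=[("u", "v")])]
        ).fit(tol=1e-12)
        assert np.abs(gam.fittedvalues - glm.fittedvalues).max() < 1e-6
        assert gam.deviance == pytest.approx(glm.deviance, abs=1e-6)
        # EDF shrinks to the penalty null-space dimension (centered basis):
        # 1 for the univariate smooth (linear), 3 for the tensor (x, y, xy)
        edf = gam.edf_by_term
        assert edf["f(d)"] == pytest.approx(1.0, abs=1e-3)
        assert edf["f(u,v)"] == pytest.approx(3.0, abs=1e-3)

    def test_constraint_reparameterization_preserves_fit(self, rng):
        """Centering the basis changes coefficients, not fitted values."""
        df, y = self._sim(rng, n=800)
        res_a = LogisticGAM(y, df, [Smooth1D("d", k=8)]).fit(lam=1.0)
        res_b = LogisticGAM(y, df, [Smooth1D("d", k=8)]).fit(lam=1.0)
        assert np.allclose(res_a.fittedvalues, res_b.fittedvalues, atol=1e-10)
        assert (res_a.fittedvalues > 0).all() and (res_a.fittedvalues < 1).all()


class TestGCVSelection:
    def _edf_of_smooth(self, eta_fn, rng, n=1500):
        df = pd.DataFrame({"d": rng.uniform(0, 10, n)})
        y = (rng.random(n) < _invlogit(eta_fn(df["d"].to_numpy()))).astype(float)
        res = LogisticGAM(y, df, [Smooth1D("d", k=10)]).fit(select="gcv")
        return res.edf_by_term["f(d)"], res

    def test_linear_truth_gives_small_edf(self):
        """On strictly linear logits, GCV keeps the smooth near-linear."""
        rng = np.random.default_rng(77)
        edfs = [self._edf_of_smooth(lambda d: 0.9 - 0.25 * d, rng)[0] for _ in range(20)]
        assert np.median(edfs) <= 2.5

    def test_sinusoidal_truth_detected(self):
        """On a sinusoidal logit at n=4000, GCV opens the smooth up (EDF >= 4)."""
        rng = np.random.default_rng(78)
        edfs = [
            self._edf_of_smooth(lambda d: 1.3 * np.sin(d), rng, n=4000)[0]
            for _ in range(20)
        ]
        assert np.median(edfs) >= 4.0

    def test_gcv_score_self_consistent(self, rng):
        """Reported GCV equals n*D/(n - EDF)^2 recomputed from the fit."""
        _, res = self._edf_of_smooth(lambda d: np.sin(d), rng)
        n = res.nobs
        assert res.gcv == pytest.approx(
            n * res.deviance / (n - res.edf_total) ** 2, rel=1e-12
        )


class TestSmoothTests:
    def test_chi2_nonnegative_and_type1_error_calibrated(self):
        """Flat truth: the smooth test rejects at ~alpha; chi2 is never negative."""
        rng = np.random.default_rng(5150)
        n, rejections = 1200, 0
        n_sims = 100
        for _ in range(n_sims):
            df = pd.DataFrame({"d": rng.uniform(0, 10, n)})
            y = (rng.random(n) < 0.55).astype(float)
            res = LogisticGAM(y, df, [Smooth1D("d", k=10)]).fit()
            st = res.smooth_tests().iloc[0]
            if np.isfinite(st["chi2"]):
                assert st["chi2"] >= 0
                rejections += st["p"] < 0.05
        assert 0.0 <= rejections / n_sims <= 0.12

    def test_power_against_strong_sinusoid(self):
        rng = np.random.default_rng(5151)
        hits = 0
        for _ in range(20):
            df = pd.DataFrame({"d": rng.uniform(0, 10, 2000)})
            y = (rng.random(2000) < _invlogit(1.5 * np.sin(df["d"]))).astype(float)
            res = LogisticGAM(y, df, [Smooth1D("d", k=10)]).fit()
            hits += res.smooth_tests().iloc[0]["p"] < 0.05
        assert hits >= 18


class TestAnova:
    def test_self_comparison_rejected(self, rng):
        df = pd.DataFrame({"x1": rng.normal(size=300)})
        y = (rng.random(300) < 0.5).astype(float)
        res = LogisticGAM(y, df, [Linear(["x1"])]).fit()
        with pytest.raises(ValueError, match="nested"):
            anova_compare(res, res)

    def test_mismatched_rows_rejected(self, rng):
        df1 = pd.DataFrame({"x1": rng.normal(size=300)})
        df2 = pd.DataFrame({"x1": rng.normal(size=200)})
        r1 = LogisticGAM((rng.random(300) < 0.5).astype(float), df1, [Linear(["x1"])]).fit()
        r2 = LogisticGAM((rng.random(200) < 0.5).astype(float), df2, [Linear(["x1"])]).fit()
        with pytest.raises(ValueError, match="identical rows"):
            anova_compare(r1, r2)

    def test_detects_nonlinear_improvement(self):
        """GLM vs GAM on nonlinear truth: deviance drop is significant."""
        rng = np.random.default_rng(99)
        significant = 0
        n_sims = 30
        for _ in range(n_sims):
            df = pd.DataFrame({"d": rng.uniform(0, 10, 1200)})
            y = (rng.random(1200) < _invlogit(1.2 * np.sin(df["d"]))).astype(float)
            glm = LogisticGAM(y, df, [Linear(["d"])]).fit()
            gam = LogisticGAM(y, df, [Smooth1D("d", k=10)]).fit()
            cmp_ = anova_compare(glm, gam)
            assert cmp_["ddeviance"] >= 0
            significant += cmp_["p_chi2"] < 0.01 and cmp_["p_F"] < 0.01
        assert significant >= int(0.9 * n_sims)


class TestPredict:
    def _fit(self, rng):
        n = 1000
        df = pd.DataFrame(
            {
                "landuse5": rng.choice(["natural", "agriculture"], n),
                "road_dist": rng.uniform(0, 300, n),
                "x": rng.uniform(0, 1000, n),
                "y_coord": rng.uniform(0, 1000, n),
            }
        )
        eta = 0.2 + 0.6 * (df["landuse5"] == "agriculture") - 0.004 * df["road_dist"]
        y = (rng.random(n) < _invlogit(eta)).astype(float)
        model = LogisticGAM(
            y,
            df,
            [
                Categorical("landuse5", "natural", component="landuse"),
                Smooth1D("road_dist", k=8, component="distance"),
                SmoothTensor2D("x", "y_coord", k_marginal=5, component="spatial"),
            ],
        )
        return df, model.fit(lam=1.0)

    def test_components_sum_to_linear_predictor(self, rng):
        df, res = self._fit(rng)
        comps = res.predict_components(df.iloc[:50])
        total = res.predict(df.iloc[:50], kind="link")
        parts = comps[["intercept", "landuse", "distance", "spatial"]].sum(axis=1)
        assert np.abs(parts - total).max() < 1e-10
        assert np.abs(comps["lp_total"] - total).max() < 1e-10

    def test_training_predictions_equal_fitted_values(self, rng):
        df, res = self._fit(rng)
        assert np.abs(res.predict(df) - res.fittedvalues).max() < 1e-10

    def test_unseen_level_rejected(self, rng):
        df, res = self._fit(rng)
        bad = df.iloc[:3].copy()
        bad["landuse5"] = "swamp"
        with pytest.raises(ValueError, match="unseen"):
            res.predict(bad)
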