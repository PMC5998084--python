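"""From-scratch nested mixed-model estimator: design construction,
likelihood exactness, closed-form and library oracles, LR tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grassnpp import (
    DesignMatrices,
    ModelSpec,
    VarianceComponents,
    build_design,
    fit_lmm,
    fixed_effects_at,
    loglik_at,
    lr_test,
    predict_trajectory,
)


def _toy_panel():
    return pd.DataFrame({
        "watershed_id": ["w1", "w1", "w2", "w2"],
        "county_id": ["c1", "c1", "c1", "c1"],
        "year": [1988.0, 1995.0, 1988.0, 2000.0],
        "npp": [100.0, 120.0, 90.0, 140.0],
    })


def _one_way(rng, k=6, m=4, sd_u=1.5, sd_e=0.8, mu=2.0):
    groups = np.repeat(np.arange(k), m)
    u = rng.normal(0, sd_u, k)
    y = mu + u[groups] + rng.normal(0, sd_e, k * m)
    return y, groups


class TestBuildDesign:
    def test_quadratic_time_vandermonde(self):
        dm = build_design(_toy_panel(), ModelSpec(fixed_terms=("1", "T", "T2")))
        T = np.array([0.0, 7.0, 0.0, 12.0])
        np.testing.assert_array_equal(dm.X, np.column_stack([np.ones(4), T, T**2]))
        assert dm.x_names == ["intercept", "T", "T2"]
        np.testing.assert_allclose(dm.y, np.log([100, 120, 90, 140]))

    def test_missing_row_dropped_and_counted(self, small_panel):
        panel, _, _ = small_panel
        panel = panel.head(10).copy()
        panel.loc[panel.index[3], "npp"] = np.nan
        dm = build_design(panel, ModelSpec(fixed_terms=("1", "T")))
        assert dm.n_obs == 9
        assert dm.n_dropped == 1

    def test_categorical_dummies_against_reference(self, covariate_panel):
        panel, _, _ = covariate_panel
        spec = ModelSpec(fixed_terms=("1", "C(grassland_type)"),
                         categorical_refs={"grassland_type": "ASAG"})
        dm = build_design(panel, spec)
        dummy_cols = [n for n in dm.x_names if n.startswith("grassland_type[")]
        assert len(dummy_cols) == panel["grassland_type"].nunique() - 1
        assert "grassland_type[ASAG]" not in dm.x_names
        idx = [dm.x_names.index(n) for n in dummy_cols]
        row_sums = dm.X[:, idx].sum(axis=1)
        # dummies sum to 1 - [is reference]: exactly one dummy fires off-reference
        assert np.all((row_sums == 0) | (row_sums == 1))
        frac_ref = (panel["grassland_type"] == "ASAG").mean()
        assert (row_sums == 0).mean() == pytest.approx(frac_ref)

    def test_unresolvable_term_named(self):
        with pytest.raises(KeyError, match="bogus"):
            build_design(_toy_panel(), ModelSpec(fixed_terms=("1", "bogus")))

    def test_nesting_violation_raises(self):
        panel = _toy_panel()
        panel.loc[1, "county_id"] = "c2"
        with pytest.raises(ValueError, match="nesting"):
            build_design(panel, ModelSpec(fixed_terms=("1",)))

    def test_t2_requires_t(self):
        with pytest.raises(ValueError, match="T2"):
            ModelSpec(fixed_terms=("1", "T2"))


class TestLoglikAt:
    def test_reduces_to_ols_gaussian_loglik(self, rng):
        n = 20
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta = np.array([1.0, 0.5])
        y = X @ beta + rng.normal(0, 0.6, n)
        dm = DesignMatrices.from_arrays(y, X, np.arange(n) % 4, np.zeros(n),
                                        random_watershed=("intercept",),
                                        random_county=())
        vc = VarianceComponents(sigma2=0.36, tau_watershed=[[0.0]], tau_county=None)
        ll = loglik_at(dm, vc, beta)
        r = y - X @ beta
        closed = float(np.sum(stats.norm.logpdf(r, scale=0.6)))
        assert ll == pytest.approx(closed, rel=1e-12)

    def test_matches_dense_multivariate_normal(self, rng):
        """5-observation toy against a brute-force dense MVN density."""
        y = rng.normal(size=5)
        X = np.ones((5, 1))
        ws = np.array([0, 0, 1, 2, 2])
        cty = np.array([0, 0, 0, 1, 1])
        t = np.array([0.0, 1.0, 0.0, 1.0, 2.0])
        dm = DesignMatrices.from_arrays(y, X, ws, cty, time=t,
                                        random_watershed=("intercept", "T"),
                                        random_county=("intercept",))
        tau_w = np.array([[0.9, 0.2], [0.2, 0.3]])
        tau_c = np.array([[0.7]])
        s2 = 0.4
        vc = VarianceComponents(s2, tau_w, tau_c)
        beta = np.array([0.3])
        # dense covariance assembled independently
        Zw = np.zeros((5, 6))
        for i, (w, ti) in enumerate(zip(ws, t)):
            Zw[i, 2 * w] = 1.0
            Zw[i, 2 * w + 1] = ti
        Zc = np.zeros((5, 2))
        for i, c in enumerate(cty):
            Zc[i, c] = 1.0
        V = s2 * np.eye(5) + Zw @ np.kron(np.eye(3), tau_w) @ Zw.T \
            + Zc @ np.kron(np.eye(2), tau_c) @ Zc.T
        dense = stats.multivariate_normal.logpdf(y, mean=(X @ beta), cov=V)
        # loglik_at consumes the design's sorted row order
        order = np.lexsort((ws, cty))
        assert np.array_equal(order, np.arange(5))  # already sorted
        assert loglik_at(dm, vc, beta) == pytest.approx(dense, rel=1e-12)

    def test_fitted_optimum_beats_perturbed_components(self, small_panel):
        panel, _, _ = small_panel
        dm = build_design(panel.assign(log_npp=np.log(panel["npp"])),
                          ModelSpec(fixed_terms=("1", "T", "T2")))
        fit = fit_lmm(dm, "ML")
        beta = np.array([fit.coefficients[n] for n in fit.x_names])
        ll_opt = loglik_at(dm, fit.vc, beta)
        assert ll_opt == pytest.approx(fit.loglik, rel=1e-8)
        for factor in (0.9, 1.1):
            vc_pert = VarianceComponents(
                fit.vc.sigma2 * factor,
                fit.vc.tau_watershed * factor,
                fit.vc.tau_county * factor)
            assert loglik_at(dm, vc_pert, beta) <= ll_opt + 1e-8


class TestFitClosedForms:
    def test_balanced_one_way_matches_anova_estimators(self, rng):
        """Balanced one-way layout: REML equals (MSW, (MSB-MSW)/m); ML
        equals (MSW, (SSB/k - MSW)/m)."""
        k, m = 6, 4
        y, groups = _one_way(rng, k, m)
        dm = DesignMatrices.from_arrays(y, np.ones((k * m, 1)), groups,
                                        np.zeros(k * m), x_names=["intercept"],
                                        random_county=())
        gm = np.array([y[groups == i].mean() for i in range(k)])
        ssw = sum(((y[groups == i] - gm[i]) ** 2).sum() for i in range(k))
        ssb = m * ((gm - y.mean()) ** 2).sum()
        msw = ssw / (k * (m - 1))
        msb = ssb / (k - 1)
        fr = fit_lmm(dm, "REML")
        assert fr.vc.sigma2 == pytest.approx(msw, rel=1e-6)
        assert fr.vc.tau_watershed[0, 0] == pytest.approx((msb - msw) / m, rel=1e-6)
        fm = fit_lmm(dm, "ML")
        assert fm.vc.sigma2 == pytest.approx(msw, rel=1e-6)
        assert fm.vc.tau_watershed[0, 0] == pytest.approx((ssb / k - msw) / m, rel=1e-6)
        assert fm.coefficients["intercept"] == pytest.approx(y.mean(), rel=1e-9)

    def test_identical_group_means_boundary(self):
        """No between-group signal: tau at 0, sigma2 = pooled ML variance."""
        y = np.tile([1.0, 2.0, 3.0], 5)  # every group mean identical
        groups = np.repeat(np.arange(5), 3)
        dm = DesignMatrices.from_arrays(y, np.ones((15, 1)), groups,
                                        np.zeros(15), random_county=())
        fit = fit_lmm(dm, "ML")
        assert fit.vc.tau_watershed[0, 0] == pytest.approx(0.0, abs=1e-6)
        assert fit.vc.sigma2 == pytest.approx(np.var(y), rel=1e-4)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_statsmodels_nested(self, seed):
        """Fixed effects and variance components agree with the
        independent MixedLM implementation on nested two-level data."""
        smf = pytest.importorskip("statsmodels.formula.api")
        rng = np.random.default_rng(seed)
        nc, nw, m = 7, 4, 5
        rows = []
        for c in range(nc):
            uc = rng.normal(0, 1.0)
            for w in range(nw):
                uw = rng.normal(0, 1.2)
                for t in range(m):
                    x = rng.normal()
                    rows.append((f"c{c}", f"c{c}w{w}", x,
                                 2.0 + 0.5 * x + uc + uw + rng.normal(0, 0.7)))
        df = pd.DataFrame(rows, columns=["county", "ws", "x", "y"])
        dm = DesignMatrices.from_arrays(
            df.y, np.column_stack([np.ones(len(df)), df.x]), df.ws, df.county,
            x_names=["intercept", "x"])
        fit = fit_lmm(dm, "ML")
        res = smf.mixedlm("y ~ x", df, groups="county", re_formula="1",
                          vc_formula={"ws": "0 + C(ws)"}).fit(
            reml=False, method="lbfgs")
        assert fit.coefficients["intercept"] == pytest.approx(res.fe_params["Intercept"], rel=1e-4)
        assert fit.coefficients["x"] == pytest.approx(res.fe_params["x"], rel=1e-4)
        assert fit.vc.sigma2 == pytest.approx(res.scale, rel=1e-3)
        assert fit.vc.tau_watershed[0, 0] == pytest.approx(res.vcomp[0], rel=1e-3)
        assert fit.vc.tau_county[0, 0] == pytest.approx(res.cov_re.iloc[0, 0], rel=1e-3)
        assert fit.loglik == pytest.approx(res.llf, abs=1e-5)


class TestInvariances:
    def test_reml_and_ml_gls_agree_at_fixed_components(self, small_panel):
        panel, _, _ = small_panel
        dm = build_design(panel.assign(log_npp=np.log(panel["npp"])),
                          ModelSpec(fixed_terms=("1", "T")))
        fit = fit_lmm(dm, "ML")
        beta_gls = fixed_effects_at(dm, fit.vc)
        for j, nm in enumerate(fit.x_names):
            assert beta_gls[j] == pytest.approx(fit.coefficients[nm], rel=1e-8)
        fit_r = fit_lmm(dm, "REML")
        beta_gls_r = fixed_effects_at(dm, fit_r.vc)
        for j, nm in enumerate(fit_r.x_names):
            assert beta_gls_r[j] == pytest.approx(fit_r.coefficients[nm], rel=1e-8)

    def test_response_shift_moves_only_intercept(self, rng):
        y, groups = _one_way(rng)
        x = rng.normal(size=len(y))
        X = np.column_stack([np.ones(len(y)), x])
        dm = DesignMatrices.from_arrays(y, X, groups, groups // 2,
                                        x_names=["intercept", "x"])
        dm_shift = DesignMatrices.from_arrays(y + 100.0, X, groups, groups // 2,
                                              x_names=["intercept", "x"])
        f0, f1 = fit_lmm(dm, "ML"), fit_lmm(dm_shift, "ML")
        assert f1.coefficients["intercept"] == pytest.approx(
            f0.coefficients["intercept"] + 100.0, abs=1e-5)
        assert f1.coefficients["x"] == pytest.approx(f0.coefficients["x"], abs=1e-6)
        assert f1.vc.sigma2 == pytest.approx(f0.vc.sigma2, rel=1e-5)
        assert f1.vc.tau_watershed[0, 0] == pytest.approx(
            f0.vc.tau_watershed[0, 0], rel=1e-4, abs=1e-8)

    def test_zero_column_gets_zero_coefficient(self, rng):
        y, groups = _one_way(rng)
        X = np.column_stack([np.ones(len(y)), np.zeros(len(y))])
        dm = DesignMatrices.from_arrays(y, X, groups, groups // 2,
                                        x_names=["intercept", "dead"])
        fit = fit_lmm(dm, "ML")
        assert fit.coefficients["dead"] == 0.0
        dm_ref = DesignMatrices.from_arrays(y, np.ones((len(y), 1)), groups,
                                            groups // 2, x_names=["intercept"])
        assert fit.loglik == pytest.approx(fit_lmm(dm_ref, "ML").loglik, abs=1e-8)

    def test_collinear_columns_named(self, rng):
        y, groups = _one_way(rng)
        x = rng.normal(size=len(y))
        X = np.column_stack([np.ones(len(y)), x, 2.0 * x])
        dm = DesignMatrices.from_arrays(y, X, groups, groups // 2,
                                        x_names=["intercept", "x", "x_copy"])
        with pytest.raises(ValueError, match="collinear"):
            fit_lmm(dm, "ML")


class TestLRTest:
    def _fit_pair(self, rng):
        nc, nw, m = 5, 4, 6
        rows = []
        for c in range(nc):
            uc = rng.normal(0, 0.8)
            for w in range(nw):
                uw = rng.normal(0, 1.0)
                for t in range(m):
                    rows.append((f"c{c}", f"c{c}w{w}", float(t),
                                 1.0 + 0.3 * t + uc + uw + rng.normal(0, 0.5)))
        df = pd.DataFrame(rows, columns=["county", "ws", "t", "y"])
        X_full = np.column_stack([np.ones(len(df)), df.t])
        dm_full = DesignMatrices.from_arrays(df.y, X_full, df.ws, df.county,
                                             x_names=["intercept", "t"])
        dm_red = DesignMatrices.from_arrays(df.y, np.ones((len(df), 1)),
                                            df.ws, df.county, x_names=["intercept"])
        return fit_lmm(dm_full, "ML"), fit_lmm(dm_red, "ML")

    def test_identical_models_chi2_zero(self, rng):
        full, _ = self._fit_pair(rng)
        res = lr_test(full, full)
        assert res.chi2 == 0.0
        assert res.p_value == 1.0

    def test_chi2_equals_twice_delta_loglik(self, rng):
        full, red = self._fit_pair(rng)
        res = lr_test(full, red)
        assert res.chi2 == pytest.approx(2 * (full.loglik - red.loglik), rel=1e-12)
        assert res.df == 1
        assert res.p_value == pytest.approx(stats.chi2.sf(res.chi2, 1), rel=1e-12)
        assert "boundary" in res.note

    def test_reml_with_different_fixed_parts_refused(self, rng):
        rng2 = np.random.default_rng(rng.integers(2**31))
        nc, nw, m = 5, 4, 6
        rows = []
        for c in range(nc):
            for w in range(nw):
                for t in range(m):
                    rows.append((f"c{c}", f"c{c}w{w}", float(t),
                                 rng2.normal(1.0, 1.0)))
        df = pd.DataFrame(rows, columns=["county", "ws", "t", "y"])
        dm_full = DesignMatrices.from_arrays(
            df.y, np.column_stack([np.ones(len(df)), df.t]), df.ws, df.county,
            x_names=["intercept", "t"])
        dm_red = DesignMatrices.from_arrays(df.y, np.ones((len(df), 1)),
                                            df.ws, df.county, x_names=["intercept"])
        f, r = fit_lmm(dm_full, "REML"), fit_lmm(dm_red, "REML")
        with pytest.raises(ValueError, match="REML"):
            lr_test(f, r)

    def test_mixed_vs_pooled_chi2_grows_with_n(self):
        """With large true between-group variance, the evidence against
        pooled OLS accumulates with sample size."""
        def chi2_at(n_ws):
            rng = np.random.default_rng(7)
            groups = np.repeat(np.arange(n_ws), 4)
            u = rng.normal(0, 2.0, n_ws)
            y = u[groups] + rng.normal(0, 0.5, 4 * n_ws)
            dm = DesignMatrices.from_arrays(y, np.ones((len(y), 1)), groups,
                                            np.zeros(len(y)), random_county=())
            fit = fit_lmm(dm, "ML")
            s2 = np.var(y)
            ll_ols = -0.5 * len(y) * (np.log(2 * np.pi * s2) + 1)
            return 2 * (fit.loglik - ll_ols)

        assert chi2_at(40) > chi2_at(10) > 0


class TestPredictTrajectory:
    def test_intercept_only_flat_line(self, small_panel):
        panel, _, _ = small_panel
        fit = fit_lmm(build_design(panel, ModelSpec(fixed_terms=("1",))))
        curve = predict_trajectory(fit, {}, [1988, 2000, 2012])
        assert curve["log_npp"].nunique() == 1
        assert (curve["level"] == "population").all()

    def test_quadratic_curve_by_substitution(self, small_panel):
        panel, _, _ = small_panel
        fit = fit_lmm(build_design(panel, ModelSpec(fixed_terms=("1", "T", "T2"))))
        years = np.array([1988.0, 1995.0, 2012.0])
        curve = predict_trajectory(fit, {}, years)
        t = years - 1988.0
        expected = (fit.coefficients["intercept"] + fit.coefficients["T"] * t
                    + fit.coefficients["T2"] * t**2)
        np.testing.assert_allclose(curve["log_npp"], expected, rtol=1e-12)

    def test_blup_added_curve_flagged_and_shifted(self, small_panel):
        panel, _, _ = small_panel
        fit = fit_lmm(build_design(panel, ModelSpec(fixed_terms=("1", "T"))))
        wid = panel["watershed_id"].iloc[0]
        pop = predict_trajectory(fit, {}, [1990.0])
        grp = predict_trajectory(fit, {}, [1990.0], group=("watershed", wid))
        assert grp["level"].iloc[0] == f"watershed:{wid}"
        shift = grp["log_npp"].iloc[0] - pop["log_npp"].iloc[0]
        assert shift == pytest.approx(fit.blups["watershed"][wid][0], rel=1e-9)

    def test_interaction_curves_cross_with_negative_time_precipitation(self):
        """A negative time x precipitation coefficient makes the wet
        (+1 SD) trajectory flatter than the dry (-1 SD) one."""
        from grassnpp import SyntheticConfig, generate_panel, standardize

        cfg = SyntheticConfig(
            n_counties=8, watersheds_per_county=12, random_slopes=False,
            fixed_effects={"intercept": 5.0, "T": 0.01, "T2": 0.0005,
                           "precipitation": 0.2, "T:precipitation": -0.02,
                           "temperature": 0.1, "T:temperature": 0.02},
            sigma2_resid=0.05, tau_watershed=[[0.2]], tau_county=[[0.1]],
            missing_rate=0.0, seed=6)
        panel, _ = generate_panel(cfg)
        std = standardize(panel)
        spec = ModelSpec(fixed_terms=("1", "T", "T2", "precipitation",
                                      "temperature", "T:precipitation",
                                      "T:temperature"))
        fit = fit_lmm(build_design(std, spec))
        years = [1988.0, 2012.0]
        base = {"temperature": 0.0}
        wet = predict_trajectory(fit, {**base, "precipitation": 1.0}, years)
        dry = predict_trajectory(fit, {**base, "precipitation": -1.0}, years)
        slope_wet = wet["log_npp"].iloc[1] - wet["log_npp"].iloc[0]
        slope_dry = dry["log_npp"].iloc[1] - dry["log_npp"].iloc[0]
        assert slope_wet < slope_dry

    def test_missing_profile_term_raises(self, covariate_panel):
        panel, _, _ = covariate_panel
        fit = fit_lmm(build_design(panel, ModelSpec(fixed_terms=("1", "T", "gdp"))))
        with pytest.raises(KeyError, match="gdp"):
            predict_trajectory(fit, {}, [1990.0])
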