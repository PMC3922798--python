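"""Mixed-model engine: closed-form oracles, nesting, equivariance, recovery."""

import warnings

import numpy as np

import pytest

import pmcalib as pm
from pmcalib.reml import RandomEffect, VarianceComponentsModel, marginal_covariance

from conftest import simulate_table


def toy_effects(t):
    n = len(t["y"])
    return [
        RandomEffect("city", t["city"], np.ones(n)),
        RandomEffect("subject", t["subj"], np.ones(n)),
        RandomEffect("slope_city", t["city"], t["z"]),
    ]


def dense_reml_oracle(y, X, V):
    """Brute-force REML log-likelihood and GLS estimate from a dense V."""
    n, p = X.shape
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    r = y - X @ beta
    ll = -0.5 * (
        np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(A)[1]
        + r @ Vi @ r
        + (n - p) * np.log(2 * np.pi)
    )
    return beta, ll


class TestMarginalCovariance:
    def test_residual_only(self):
        V = marginal_covariance([], {}, 2.0, 4)
        np.testing.assert_allclose(V, 2.0 * np.eye(4))

    def test_compound_symmetry_block(self):
        eff = [RandomEffect("subject", np.zeros(3, int), np.ones(3))]
        V = marginal_covariance(eff, {"subject": 1.0}, 1.0, 3)
        expected = np.full((3, 3), 1.0) + np.eye(3)
        np.testing.assert_allclose(V, expected)  # ICC = 0.5

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            marginal_covariance([], {}, -1.0, 3)

    def test_monte_carlo_oracle(self, toy_balanced):
        """V matches the empirical covariance of simulated random effects."""
        t = toy_balanced
        effs = toy_effects(t)
        sig = {"city": 0.8, "subject": 1.5, "slope_city": 0.01}
        s2w = 0.5
        V = marginal_covariance(effs, sig, s2w, 16)
        rng = np.random.default_rng(17)
        nsim = 200_000
        draws = np.zeros((nsim, 16))
        for eff in effs:
            g = np.asarray(eff.groups)
            b = rng.normal(0, np.sqrt(sig[eff.name]), (nsim, g.max() + 1))
            draws += b[:, g] * np.asarray(eff.values)
        draws += rng.normal(0, np.sqrt(s2w), (nsim, 16))
        emp = np.cov(draws, rowvar=False)
        assert np.max(np.abs(emp - V)) < 0.1  # ~4 MC sigma at 200k draws

    def test_psd_and_symmetric(self, toy_balanced):
        t = toy_balanced
        V = marginal_covariance(
            toy_effects(t), {"city": 1.0, "subject": 2.0, "slope_city": 0.02},
            1.0, 16,
        )
        np.testing.assert_allclose(V, V.T)
        assert np.linalg.eigvalsh(V).min() > 0


class TestOracleEquivalence:
    """Woodbury block path vs dense brute-force likelihood/GLS, <= 24 obs."""

    @pytest.mark.parametrize(
        "log_ratios",
        [np.log([0.3, 0.7, 1e-3]), np.log([1.0, 1.0, 0.01]),
         np.log([1e-6, 2.0, 1e-6])],
    )
    def test_criterion_and_beta_match_dense(self, toy_balanced, log_ratios):
        t = toy_balanced
        m = VarianceComponentsModel(t["y"], t["X"], toy_effects(t), t["city"])
        beta, cov, s2, ll = m.fixed_effects_at(log_ratios)
        r = np.exp(log_ratios)
        sig = {"city": r[0] * s2, "subject": r[1] * s2, "slope_city": r[2] * s2}
        V = marginal_covariance(toy_effects(t), sig, s2, 16)
        beta_o, ll_o = dense_reml_oracle(t["y"], t["X"], V)
        np.testing.assert_allclose(beta, beta_o, atol=1e-8)
        assert ll == pytest.approx(ll_o, abs=1e-8)

    def test_fitted_beta_is_gls_at_fitted_components(self, toy_balanced):
        t = toy_balanced
        m = VarianceComponentsModel(t["y"], t["X"], toy_effects(t), t["city"])
        fit = m.fit()
        V = marginal_covariance(
            toy_effects(t),
            {k: max(v, 0.0) for k, v in fit.sigma2.items()},
            fit.sigma2_resid, 16,
        )
        beta_o, _ = dense_reml_oracle(t["y"], t["X"], V)
        np.testing.assert_allclose(fit.beta, beta_o, atol=1e-6)


class TestAgainstStatsmodels:
    """Independent cross-check: same REML criterion as statsmodels MixedLM."""

    def setup_method(self):
        _, self.table = simulate_table(
            n_cities=5, subjects_per_city=8, months_per_subject=6, seed=7
        )

    def test_model2_matches_mixedlm(self):
        import statsmodels.formula.api as smf

        df = self.table.dropna(subset=["x_ambient_origin", "z_monitor"]).copy()
        df["z"] = df["z_monitor"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_fit = smf.mixedlm(
                "x_ambient_origin ~ z + winter", df, groups="city_id",
                re_formula="1", vc_formula={"subject": "0 + C(subject_id)"},
            ).fit(reml=True, method="lbfgs")
        mine = pm.CalibrationModel(self.table, pm.ModelSpec(kind="model2")).fit()
        assert mine.llf == pytest.approx(sm_fit.llf, abs=1e-5)
        np.testing.assert_allclose(mine.params.to_numpy(), sm_fit.fe_params,
                                   atol=1e-4)
        assert mine.se_gamma1 == pytest.approx(float(sm_fit.bse_fe["z"]), rel=1e-3)

    def test_model1_criterion_not_worse_than_mixedlm(self):
        import statsmodels.formula.api as smf

        df = self.table.dropna(subset=["x_ambient_origin", "z_monitor"]).copy()
        df["z"] = df["z_monitor"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_fit = smf.mixedlm(
                "x_ambient_origin ~ z + winter", df, groups="city_id",
                re_formula="1",
                vc_formula={"subject": "0 + C(subject_id)", "slope": "0 + z"},
            ).fit(reml=True, method="lbfgs")
        mine = pm.CalibrationModel(self.table, pm.ModelSpec(kind="model1")).fit()
        assert mine.llf >= sm_fit.llf - 1e-6


class TestStructure:
    def test_monotone_nesting_slope_never_hurts(self):
        for seed in (1, 2, 3):
            _, table = simulate_table(
                n_cities=4, subjects_per_city=6, months_per_subject=4, seed=seed
            )
            f1 = pm.CalibrationModel(table, pm.ModelSpec(kind="model1")).fit()
            f2 = pm.CalibrationModel(table, pm.ModelSpec(kind="model2")).fit()
            assert f1.llf >= f2.llf - 1e-6

    def test_equivariance_scaling_and_centering(self):
        _, table = simulate_table(
            n_cities=4, subjects_per_city=8, months_per_subject=6, seed=12
        )
        base = pm.CalibrationModel(table, pm.ModelSpec(kind="model1")).fit()
        c = 3.0
        scaled = table.copy()
        scaled["x_ambient_origin"] = c * scaled["x_ambient_origin"]
        fs = pm.CalibrationModel(scaled, pm.ModelSpec(kind="model1")).fit()
        assert fs.gamma1 == pytest.approx(c * base.gamma1, rel=1e-4)
        assert fs.sigma2_w == pytest.approx(c**2 * base.sigma2_w, rel=1e-3)
        shifted = table.copy()
        shifted["z_monitor"] = shifted["z_monitor"] - 10.0
        fc = pm.CalibrationModel(shifted, pm.ModelSpec(kind="model1")).fit()
        assert fc.gamma1 == pytest.approx(base.gamma1, rel=1e-4)
        assert fc.params["intercept"] == pytest.approx(
            base.params["intercept"] + 10.0 * base.gamma1, rel=1e-3
        )

    def test_no_random_variation_reduces_to_ols(self):
        _, table = simulate_table(
            n_cities=4, subjects_per_city=20, months_per_subject=6,
            sigma_city=0.0, sigma_subject=0.0, sigma_slope_city=0.0,
            sigma_w=2.0, seed=30,
        )
        fit = pm.CalibrationModel(table, pm.ModelSpec(kind="model1")).fit()
        X = np.column_stack([
            np.ones(len(table)), table["z_monitor"], table["winter"]
        ])
        ols = np.linalg.lstsq(X, table["x_ambient_origin"], rcond=None)[0]
        np.testing.assert_allclose(fit.params.to_numpy(), ols, atol=0.05)
        assert fit.sigma2_city < 0.1 and fit.sigma2_slope_city < 0.01

    def test_rank_deficiency_names_columns(self):
        _, table = simulate_table(
            n_cities=3, subjects_per_city=4, months_per_subject=3, seed=2
        )
        single = table[table["season"] == "winter"]
        with pytest.raises(ValueError, match="winter"):
            pm.CalibrationModel(single, pm.ModelSpec(kind="model1"))

    def test_model4_single_city_and_degenerate_flag(self):
        _, table = simulate_table(
            n_cities=3, subjects_per_city=6, months_per_subject=4, seed=6
        )
        fit = pm.CalibrationModel(
            table, pm.ModelSpec(kind="model4", city_id="city00")
        ).fit()
        assert fit.n_cities == 1 and np.isfinite(fit.gamma1)
        # one observation per subject: subject variance confounded with residual
        city = table[table["city_id"] == "city00"]
        ranks = {s: i for i, s in enumerate(sorted(city["subject_id"].unique()))}
        one = city[
            city.apply(
                lambda r: r["month_index"] == ranks[r["subject_id"]]
                % city["month_index"].max(), axis=1)
        ].drop_duplicates("subject_id")
        m = pm.CalibrationModel(
            one, pm.ModelSpec(kind="model4", city_id="city00",
                              include_season=False)
        )
        res = m.fit()
        assert "non-identifiable" in res.message

    def test_parameter_recovery_median_error(self):
        """Median |gamma1_hat - truth| stays below 0.08 at study-like scale."""
        errs = []
        for rep in range(20):
            _, table = simulate_table(
                n_cities=5, subjects_per_city=30, months_per_subject=6,
                gamma1_true=0.54, seed=500 + rep,
            )
            fit = pm.CalibrationModel(table, pm.ModelSpec(kind="model1")).fit()
            errs.append(abs(fit.gamma1 - 0.54))
        assert np.median(errs) < 0.08
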