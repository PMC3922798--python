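"""Mixture LRT, step-wise meta-regression, Model 4, LOOCV metrics."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pmcalib as pm
from pmcalib.heterogeneity import loocv_metrics

from conftest import simulate_table


class TestMixtureP:
    def test_boundary_gives_exactly_half(self):
        assert pm.mixture_lrt_p(0.0, boundary=True) == 0.5
        assert pm.mixture_lrt_p(0.0, boundary=False) == 0.5

    def test_chi2_90th_percentile(self):
        # chi2_1 upper-tail 0.10 at 2.705543 -> mixture p = 0.05
        assert pm.mixture_lrt_p(2.705543) == pytest.approx(0.05, abs=1e-6)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pm.mixture_lrt_p(-0.1)

    def test_continuous_strictly_decreasing_approaches_half(self):
        grid = np.linspace(1e-9, 10, 200)
        ps = [pm.mixture_lrt_p(l) for l in grid]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert ps[0] == pytest.approx(0.5, abs=1e-4)
        assert all(0 < p <= 0.5 for p in ps)


class TestHeterogeneityTest:
    def test_boundary_branch_on_homogeneous_tiny_data(self):
        _, table = simulate_table(
            n_cities=3, subjects_per_city=4, months_per_subject=4,
            sigma_slope_city=0.0, sigma_city=0.0, seed=14,
        )
        res = pm.heterogeneity_test(table, pm.ModelSpec())
        if res.boundary:
            assert res.lrt == 0.0 and res.p_value == 0.5

    def test_strong_heterogeneity_detected(self):
        _, table = simulate_table(
            n_cities=10, subjects_per_city=25, months_per_subject=6,
            sigma_slope_city=0.5, seed=19,
        )
        res = pm.heterogeneity_test(table, pm.ModelSpec())
        assert res.p_value < 0.01
        assert res.lrt > 0

    def test_warns_below_three_cities(self):
        _, table = simulate_table(
            n_cities=2, subjects_per_city=8, months_per_subject=4, seed=4
        )
        with pytest.warns(UserWarning, match="cities"):
            pm.heterogeneity_test(table, pm.ModelSpec())


class TestCovariateShift:
    @pytest.mark.parametrize("g4, delta, expected",
                             [(-2.53, 0.1, -0.253), (5.0, 0.0, 0.0),
                              (2.0, 0.5, 1.0)])
    def test_values(self, g4, delta, expected):
        assert pm.predict_effect_of_covariate_shift(g4, delta) == pytest.approx(
            expected
        )

    def test_worked_example_rounds_to_quarter_decrease(self):
        assert round(pm.predict_effect_of_covariate_shift(-2.53, 0.1), 2) == -0.25


class TestStepwise:
    def _het_table(self, seed, gamma4=-2.5, n_cities=12):
        cfg = pm.SimulationConfig(
            n_cities=n_cities, subjects_per_city=15, months_per_subject=6,
            covariate_effects={"vehicles_per_unit": gamma4},
            sigma_slope_city=0.05, seed=seed,
        )
        ds = pm.simulate_panel(cfg)
        table = pm.build_analysis_table(ds.daily, ds.monitors, ds.model_pred)
        return ds, table

    def test_true_covariate_selected_under_strong_signal(self):
        hits = 0
        for seed in range(5):
            ds, table = self._het_table(100 + seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                step = pm.stepwise_select(
                    table, pm.ModelSpec(),
                    ["vehicles_per_unit", "heating_degree_days",
                     "residents_per_unit"],
                    ds.city_covariates,
                )
            hits += "vehicles_per_unit" in step.selected
        assert hits >= 4

    def test_selection_reduces_residual_heterogeneity(self):
        ds, table = self._het_table(7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            before = pm.heterogeneity_test(table, pm.ModelSpec())
            step = pm.stepwise_select(
                table, pm.ModelSpec(), ["vehicles_per_unit"], ds.city_covariates
            )
        if "vehicles_per_unit" in step.selected:
            assert step.residual_heterogeneity.p_value > before.p_value

    def test_null_candidates_rarely_selected(self):
        any_selected = 0
        for seed in range(6):
            cfg = pm.SimulationConfig(
                n_cities=8, subjects_per_city=12, months_per_subject=6,
                sigma_slope_city=0.0, seed=700 + seed,
            )
            ds = pm.simulate_panel(cfg)
            table = pm.build_analysis_table(ds.daily, ds.monitors, ds.model_pred)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                step = pm.stepwise_select(
                    table, pm.ModelSpec(),
                    ["vehicles_per_unit", "heating_degree_days"],
                    ds.city_covariates,
                )
            any_selected += bool(step.selected)
        assert any_selected <= 2

    def test_collinear_candidate_dropped(self):
        ds, table = self._het_table(5)
        cov = ds.city_covariates.copy()
        cov["vehicles_twin"] = cov["vehicles_per_unit"] * 2.0 + 0.1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            step = pm.stepwise_select(
                table, pm.ModelSpec(), ["vehicles_per_unit", "vehicles_twin"], cov
            )
        assert not {"vehicles_per_unit", "vehicles_twin"} <= set(step.selected)


class TestCitySpecific:
    def test_estimates_scatter_around_truth_homogeneous(self):
        _, table = simulate_table(
            n_cities=8, subjects_per_city=25, months_per_subject=6,
            gamma1_true=0.54, sigma_slope_city=0.0, seed=44,
        )
        per_city = pm.city_specific_fits(table, pm.ModelSpec())
        assert per_city["ok"].all()
        est, se = per_city["estimate"], per_city["se"]
        chi2 = float((((est - est.mean()) / se) ** 2).sum())
        # heterogeneity statistic ~ chi2 with I-1 dof under homogeneity
        assert chi2 < stats.chi2.ppf(0.999, len(per_city) - 1)
        assert np.all(np.abs(est - 0.54) < 5 * se)

    def test_constant_surrogate_flagged(self):
        _, table = simulate_table(
            n_cities=3, subjects_per_city=6, months_per_subject=4, seed=9
        )
        table = table.copy()
        table.loc[table["city_id"] == "city00", "z_monitor"] = 10.0
        per_city = pm.city_specific_fits(table, pm.ModelSpec())
        bad = per_city[per_city["city_id"] == "city00"]
        assert not bad["ok"].iloc[0]
        assert "identifiable" in bad["reason"].iloc[0]

    def test_single_city_equals_model4_direct(self):
        _, table = simulate_table(
            n_cities=3, subjects_per_city=8, months_per_subject=4, seed=10
        )
        per_city = pm.city_specific_fits(table, pm.ModelSpec())
        direct = pm.CalibrationModel(
            table, pm.ModelSpec(kind="model4", city_id="city01")
        ).fit()
        row = per_city[per_city["city_id"] == "city01"].iloc[0]
        assert row["estimate"] == pytest.approx(direct.gamma1, abs=1e-8)


class TestLoocv:
    def test_metrics_trivial_identity(self):
        r, _, mrb, mab = loocv_metrics([0.3, 0.5, 0.7], [0.3, 0.5, 0.7])
        assert r == pytest.approx(1.0)
        assert mrb == 0.0 and mab == 0.0

    def test_metrics_two_city_hand_example(self):
        _, _, mrb, mab = loocv_metrics([0.5, 0.5], [0.4, 0.6])
        assert mrb == pytest.approx((0.25 - 1 / 6) / 2, abs=1e-9)  # 0.041667
        assert mab == pytest.approx((0.25 + 1 / 6) / 2, abs=1e-9)  # 0.208333

    def test_absolute_bias_dominates_relative_bias(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p, o = rng.normal(0.5, 0.2, 6), rng.normal(0.5, 0.2, 6)
            _, _, mrb, mab = loocv_metrics(p, np.where(np.abs(o) < 0.05, 0.1, o))
            assert mab >= abs(mrb) - 1e-12

    def test_left_out_city_never_in_training_and_signal_recovered(self):
        cfg = pm.SimulationConfig(
            n_cities=10, subjects_per_city=15, months_per_subject=6,
            covariate_effects={"vehicles_per_unit": -2.5},
            sigma_slope_city=0.05, seed=31,
        )
        ds = pm.simulate_panel(cfg)
        table = pm.build_analysis_table(ds.daily, ds.monitors, ds.model_pred)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pm.loocv(table, pm.ModelSpec(),
                           ["vehicles_per_unit", "heating_degree_days"],
                           ds.city_covariates)
        assert len(res.per_city) == 10
        assert res.n_cities_used >= 8
        assert res.correlation > 0.3  # strong gamma4 signal is predictive

    def test_requires_three_cities(self):
        _, table = simulate_table(
            n_cities=2, subjects_per_city=6, months_per_subject=4, seed=3
        )
        with pytest.raises(ValueError):
            pm.loocv(table, pm.ModelSpec(), ["vehicles_per_unit"],
                     pd.DataFrame({"city_id": ["city00", "city01"],
                                   "vehicles_per_unit": [1.0, 2.0]}))
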