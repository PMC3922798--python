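"""Calibration mixed models, statsmodels-style.

:class:`CalibrationModel` holds one person-month analysis table plus a
:class:`ModelSpec`; ``fit()`` returns a :class:`CalibrationResults` carrying
the calibration coefficient and its uncertainty, the variance components,
the restricted log-likelihood and convergence/boundary diagnostics.

The four model kinds:

* ``model1`` - pooled, city random intercept + subject random intercept +
  city random slope on the surrogate (the full heterogeneity model);
* ``model2`` - model1 without the city random slope;
* ``model3`` - model1 plus city-level covariates and their surrogate
  interactions (meta-regression on city characteristics);
* ``model4`` - one city alone, subject random intercepts only.

Fixed effects: intercept (gamma0), surrogate slope (gamma1 - the calibration
coefficient), winter indicator (gamma2; winter = 1, summer = 0), and for
model3 each covariate main effect (gamma3) and surrogate x covariate
interaction (gamma4).  City covariates are z-scored across cities by default
(``standardize_covariates=False`` gives raw-unit gamma4).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .reml import RandomEffect, VarianceComponentsModel

__all__ = ["ModelSpec", "CalibrationModel", "CalibrationResults"]

X_COLUMNS = {
    "ambient_origin": "x_ambient_origin",
    "total_personal": "x_total_personal",
}
Z_COLUMNS = {"monitor": "z_monitor", "model_pred": "z_model_pred"}


@dataclass(frozen=True)
class ModelSpec:
    """Which calibration model to fit, on which exposure pair."""

    kind: str = "model1"  # model1 | model2 | model3 | model4
    true_exposure: str = "ambient_origin"  # or total_personal
    surrogate: str = "monitor"  # or model_pred
    city_covariates: tuple = ()  # model3 only
    city_id: str | None = None  # model4 only
    interaction: str | None = None  # extra surrogate x column interaction
    include_season: bool = True
    standardize_covariates: bool = True
    reml: bool = True

    def __post_init__(self):
        if self.kind not in ("model1", "model2", "model3", "model4"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.true_exposure not in X_COLUMNS:
            raise ValueError(f"unknown true_exposure {self.true_exposure!r}")
        if self.surrogate not in Z_COLUMNS:
            raise ValueError(f"unknown surrogate {self.surrogate!r}")
        if self.kind == "model3" and not self.city_covariates:
            raise ValueError("model3 requires at least one city covariate")
        if self.kind == "model4" and self.city_id is None:
            raise ValueError("model4 requires a city_id")


def _collinear_columns(X: np.ndarray, names, tol=1e-8):
    """Names of columns beyond the numerical rank (QR with pivoting)."""
    if X.shape[1] == 0:
        return []
    rank = np.linalg.matrix_rank(X, tol=tol * max(1.0, float(np.abs(X).max())))
    if rank == X.shape[1]:
        return []
    bad = []
    keep: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(
            trial, tol=tol * max(1.0, float(np.abs(trial).max()))
        ) > len(keep):
            keep.append(j)
        else:
            bad.append(names[j])
    return bad


class CalibrationModel:
    """A calibration mixed model bound to one analysis table.

    Parameters
    ----------
    table : person-month table from
        :func:`pmcalib.exposure.build_analysis_table` (or equivalent columns).
    spec : :class:`ModelSpec`.
    covariate_table : city-level covariates (city_id + one column per
        variable); required for model3.
    """

    def __init__(self, table: pd.DataFrame, spec: ModelSpec,
                 covariate_table: pd.DataFrame | None = None):
        self.spec = spec
        self.covariate_table = covariate_table
        self._build(table)

    @classmethod
    def from_dataframe(cls, table, covariate_table=None, **spec_kwargs):
        return cls(table, ModelSpec(**spec_kwargs), covariate_table)

    # -- design construction -----------------------------------------------

    def _build(self, table: pd.DataFrame):
        spec = self.spec
        xcol = X_COLUMNS[spec.true_exposure]
        zcol = Z_COLUMNS[spec.surrogate]
        need = [xcol, zcol, "city_id", "subject_id"]
        if spec.include_season:
            need.append("winter")
        if spec.interaction is not None and spec.interaction not in ("winter",):
            need.append(spec.interaction)
        missing = [c for c in need if c not in table.columns]
        if missing:
            raise ValueError(f"analysis table lacks column(s) {missing}")

        df = table.dropna(subset=[xcol, zcol]).copy()
        if spec.kind == "model4":
            df = df[df["city_id"] == spec.city_id]
            if len(df) == 0:
                raise ValueError(f"no rows for city {spec.city_id!r}")
        n_cities = df["city_id"].nunique()
        if spec.kind != "model4" and n_cities < 2:
            raise ValueError(
                f"{spec.kind} needs >= 2 cities with data, found {n_cities}"
            )

        names = ["intercept"]
        cols = [np.ones(len(df))]
        z = df[zcol].to_numpy(float)
        names.append("z")
        cols.append(z)
        if spec.include_season:
            names.append("winter")
            cols.append(df["winter"].to_numpy(float))
        self._cov_scale: dict = {}
        if spec.kind == "model3":
            if self.covariate_table is None:
                raise ValueError("model3 requires a covariate_table")
            cov = self.covariate_table.set_index("city_id")
            for name in spec.city_covariates:
                if name not in cov.columns:
                    raise ValueError(f"covariate_table lacks column {name!r}")
                by_city = cov[name]
                per_city = df.groupby("city_id")[xcol].size()
                vals_city = by_city.reindex(per_city.index)
                if vals_city.isna().any():
                    raise ValueError(f"covariate {name!r} missing for some cities")
                mu, sd = 0.0, 1.0
                if spec.standardize_covariates:
                    mu = float(vals_city.mean())
                    sd = float(vals_city.std(ddof=1))
                    if not sd > 0:
                        raise ValueError(f"covariate {name!r} constant across cities")
                self._cov_scale[name] = (mu, sd)
                v = (df["city_id"].map(by_city).to_numpy(float) - mu) / sd
                names.append(name)
                cols.append(v)
                names.append(f"z:{name}")
                cols.append(z * v)
        if spec.interaction is not None:
            w = df[spec.interaction].to_numpy(float)
            if np.nanstd(w) == 0:
                raise ValueError(
                    f"interaction column {spec.interaction!r} is constant"
                )
            if spec.interaction != "winter" or not spec.include_season:
                names.append(spec.interaction)
                cols.append(w)
            names.append(f"z:{spec.interaction}")
            cols.append(z * w)

        X = np.column_stack(cols)
        bad = _collinear_columns(X, names)
        if bad:
            raise ValueError(
                "rank-deficient fixed-effect design; collinear column(s): "
                + ", ".join(map(str, bad))
            )

        city_codes = pd.factorize(df["city_id"])[0]
        subj_codes = pd.factorize(
            df["city_id"].astype(str) + "||" + df["subject_id"].astype(str)
        )[0]
        effects = []
        if spec.kind in ("model1", "model2", "model3"):
            effects.append(RandomEffect("city", city_codes, np.ones(len(df))))
            effects.append(RandomEffect("subject", subj_codes, np.ones(len(df))))
            if spec.kind in ("model1", "model3"):
                effects.append(RandomEffect("slope_city", city_codes, z))
            blocks = city_codes
        else:  # model4
            effects.append(RandomEffect("subject", subj_codes, np.ones(len(df))))
            blocks = subj_codes

        self.data = df
        self.exog_names = names
        self.endog = df[xcol].to_numpy(float)
        self.exog = X
        self.n_cities = n_cities
        self.n_subjects = int(df["subject_id"].nunique())
        self._engine = VarianceComponentsModel(
            self.endog, X, effects, blocks, xnames=names
        )

    # -- fitting -------------------------------------------------------------

    def fit(self, reml: bool | None = None, **kwargs) -> "CalibrationResults":
        use_reml = self.spec.reml if reml is None else reml
        vc = self._engine.fit(reml=use_reml, **kwargs)
        return CalibrationResults(self, vc)

    def profiled_criterion(self, log_ratios, reml: bool = True):
        """Profiled (RE)ML criterion at fixed variance ratios (diagnostics)."""
        return self._engine.profiled_criterion(log_ratios, reml=reml)

    def fixed_effects_at(self, log_ratios, reml: bool = True):
        """GLS fixed effects at fixed variance ratios (diagnostics/tests)."""
        return self._engine.fixed_effects_at(log_ratios, reml=reml)


class CalibrationResults:
    """Results of one calibration mixed-model fit.

    Attributes mirror the quantities the analysis needs downstream:
    ``params``/``cov_params`` for the fixed effects, ``sigma2_city``,
    ``sigma2_subject``, ``sigma2_slope_city`` (None when the model has no
    city random slope), ``sigma2_w``, ``llf`` (the criterion optimised;
    ``loglik_reml`` or ``loglik_ml`` is populated accordingly, the other is
    None), ``converged`` and ``boundary_flags``.
    """

    def __init__(self, model: CalibrationModel, vc):
        self.model = model
        self.spec = model.spec
        self._vc = vc
        self.params = pd.Series(vc.beta, index=model.exog_names)
        self.cov_params = pd.DataFrame(
            vc.cov_beta, index=model.exog_names, columns=model.exog_names
        )
        self.sigma2_city = vc.sigma2.get("city")
        self.sigma2_subject = vc.sigma2.get("subject")
        self.sigma2_slope_city = vc.sigma2.get("slope_city")
        self.sigma2_w = vc.sigma2_resid
        self.llf = vc.llf
        self.loglik_reml = vc.llf if vc.reml else None
        self.loglik_ml = None if vc.reml else vc.llf
        self.converged = vc.converged
        self.boundary_flags = list(vc.boundary)
        self.n_obs = vc.n_obs
        self.n_subjects = model.n_subjects
        self.n_cities = model.n_cities
        self.message = vc.message

    # -- calibration coefficient ------------------------------------------

    @property
    def gamma1(self) -> float:
        return float(self.params["z"])

    @property
    def se_gamma1(self) -> float:
        return float(np.sqrt(self.cov_params.loc["z", "z"]))

    def conf_int_gamma1(self, alpha: float = 0.05):
        q = stats.norm.ppf(1 - alpha / 2)
        g, se = self.gamma1, self.se_gamma1
        return (g - q * se, g + q * se)

    def wald_gamma1_equals_1(self) -> float:
        """p-value for H0: gamma1 = 1, using (gamma1_hat-1)^2/var ~ chi2_1."""
        from .inference import wald_test_gamma1_equals_1

        return wald_test_gamma1_equals_1(
            self.gamma1, float(self.cov_params.loc["z", "z"])
        )

    def linear_combination(self, weights: dict):
        """Estimate and delta-method SE of sum_j w_j * beta_j."""
        w = pd.Series(0.0, index=self.params.index)
        for k, v in weights.items():
            w[k] = v
        est = float(w @ self.params)
        var = float(w @ self.cov_params.to_numpy() @ w)
        return est, float(np.sqrt(max(var, 0.0)))

    @property
    def gamma(self) -> dict:
        """Fixed effects under their conventional gamma aliases."""
        out = {"gamma0": float(self.params["intercept"]),
               "gamma1": self.gamma1}
        if "winter" in self.params.index:
            out["gamma2"] = float(self.params["winter"])
        for name in self.spec.city_covariates:
            out[f"gamma3_{name}"] = float(self.params[name])
            out[f"gamma4_{name}"] = float(self.params[f"z:{name}"])
        return out

    def to_dict(self) -> dict:
        lo, hi = self.conf_int_gamma1()
        return {
            "kind": self.spec.kind,
            "true_exposure": self.spec.true_exposure,
            "surrogate": self.spec.surrogate,
            "params": self.params.to_dict(),
            "gamma1": self.gamma1,
            "se_gamma1": self.se_gamma1,
            "ci95_gamma1": [lo, hi],
            "p_gamma1_eq_1": self.wald_gamma1_equals_1(),
            "sigma2_city": self.sigma2_city,
            "sigma2_subject": self.sigma2_subject,
            "sigma2_slope_city": self.sigma2_slope_city,
            "sigma2_w": self.sigma2_w,
            "loglik_reml": self.loglik_reml,
            "loglik_ml": self.loglik_ml,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "n_cities": self.n_cities,
            "converged": self.converged,
            "boundary_flags": self.boundary_flags,
        }

    def summary(self) -> str:
        lo, hi = self.conf_int_gamma1()
        lines = [
            "Calibration mixed model"
            f" ({self.spec.kind}, {self.spec.true_exposure} ~ {self.spec.surrogate})",
            "=" * 74,
            f"n person-months: {self.n_obs:5d}   subjects: {self.n_subjects:4d}"
            f"   cities: {self.n_cities:3d}   "
            + ("REML" if self._vc.reml else "ML")
            + f" loglik: {self.llf:.3f}",
            "-" * 74,
            f"{'term':<22}{'estimate':>10}{'se':>10}{'ci95 low':>10}{'ci95 high':>11}",
        ]
        q = stats.norm.ppf(0.975)
        for name in self.params.index:
            est = self.params[name]
            se = float(np.sqrt(self.cov_params.loc[name, name]))
            lines.append(
                f"{name:<22}{est:>10.4f}{se:>10.4f}"
                f"{est - q * se:>10.4f}{est + q * se:>11.4f}"
            )
        lines += [
            "-" * 74,
            f"calibration coefficient gamma1 = {self.gamma1:.4f} "
            f"(95% CI {lo:.4f}, {hi:.4f}); "
            f"p[gamma1=1] = {self.wald_gamma1_equals_1():.4g}",
            "variance components: "
            + ", ".join(
                f"{k}={v:.4f}"
                for k, v in [
                    ("city", self.sigma2_city),
                    ("subject", self.sigma2_subject),
                    ("slope_city", self.sigma2_slope_city),
                    ("residual", self.sigma2_w),
                ]
                if v is not None
            ),
        ]
        if self.boundary_flags:
            lines.append("boundary components: " + ", ".join(self.boundary_flags))
        if not self.converged:
            lines.append(f"WARNING: optimiser did not converge ({self.message})")
        return "\n".join(lines)
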