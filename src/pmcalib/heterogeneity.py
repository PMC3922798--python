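"""Between-city heterogeneity of the calibration coefficient.

The null hypothesis sigma2_slope_city = 0 lies on the boundary of the
parameter space, so the REML likelihood-ratio statistic comparing the full
model (city random slope) to the reduced model is referred to a 50:50
mixture of chi2_0 and chi2_1: p = 0.5 when the variance estimate is zero,
p = 0.5 * P(chi2_1 > LRT) otherwise.

When heterogeneity is present, forward step-wise selection of city-level
covariates (each entering with a surrogate interaction) seeks variables
explaining it; leave-one-city-out cross-validation then checks whether the
selected meta-regression actually predicts held-out cities' calibration
coefficients, judged by the correlation with the observed city-specific
(per-city mixed model) coefficients and by the mean relative and absolute
bias of (predicted - observed) / observed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .model import CalibrationModel, ModelSpec

logger = logging.getLogger(__name__)

__all__ = [
    "mixture_lrt_p",
    "heterogeneity_test",
    "HeterogeneityResult",
    "stepwise_select",
    "StepwiseResult",
    "predict_effect_of_covariate_shift",
    "city_specific_fits",
    "loocv",
    "LoocvResult",
]

LRT_CLIP_TOL = 1e-6  # LRT below this counts as the boundary case
LRT_NEG_TOL = 5e-3  # optimiser noise tolerance before a negative LRT is an error


def mixture_lrt_p(lrt: float, boundary: bool = False) -> float:
    """Mixture-null p-value for a single variance component on the boundary.

    p = 0.5 when the variance estimate is on the boundary (LRT = 0);
    otherwise p = 0.5 * P(chi2_1 > LRT).  A negative statistic signals an
    upstream fitting fault and is rejected rather than silently clamped.
    """
    lrt = float(lrt)
    if lrt < 0:
        raise ValueError(f"negative LRT statistic ({lrt}); check the nested fits")
    if boundary or lrt == 0.0:
        return 0.5
    return float(0.5 * stats.chi2.sf(lrt, df=1))


@dataclass
class HeterogeneityResult:
    lrt: float
    p_value: float
    boundary: bool
    fit_full: object = None  # model1 results
    fit_reduced: object = None  # model2 results

    def to_dict(self) -> dict:
        return {"lrt": self.lrt, "p_value": self.p_value, "boundary": self.boundary}


def heterogeneity_test(table: pd.DataFrame, spec: ModelSpec,
                       covariate_table=None) -> HeterogeneityResult:
    """REML LRT of the city random slope (Model 1 vs Model 2), mixture null.

    Valid under REML because the two models share identical fixed effects.
    """
    spec1 = replace(spec, kind="model1", interaction=None, city_covariates=())
    spec2 = replace(spec1, kind="model2")
    m1 = CalibrationModel(table, spec1, covariate_table)
    if m1.n_cities < 3:
        warnings.warn(
            f"heterogeneity test with only {m1.n_cities} cities is unreliable",
            stacklevel=2,
        )
    f1 = m1.fit()
    f2 = CalibrationModel(table, spec2, covariate_table).fit()
    for name, f in (("model1", f1), ("model2", f2)):
        if not f.converged:
            raise RuntimeError(f"{name} fit did not converge: {f.message}")
    lrt = 2.0 * (f1.llf - f2.llf)
    if lrt < -LRT_NEG_TOL:
        raise RuntimeError(
            f"model1 REML log-likelihood below model2 by {-lrt/2:.3g}; "
            "the full-model optimisation has failed"
        )
    boundary = ("slope_city" in f1.boundary_flags) or lrt <= LRT_CLIP_TOL
    lrt = max(lrt, 0.0)
    if boundary:
        lrt = 0.0
    return HeterogeneityResult(lrt, mixture_lrt_p(lrt, boundary), boundary, f1, f2)


# --------------------------------------------------------------------------
# step-wise city-covariate selection (Model 3)


@dataclass
class StepwiseResult:
    selected: list
    fit: object  # final model3 results (model1 results if nothing selected)
    interaction_p: dict  # covariate -> p at the step it was evaluated last
    residual_heterogeneity: HeterogeneityResult | None
    dropped: list = field(default_factory=list)  # collinear candidates removed


def _city_covariate_matrix(table, spec, covariate_table, candidates):
    xcol = {"ambient_origin": "x_ambient_origin",
            "total_personal": "x_total_personal"}[spec.true_exposure]
    zcol = {"monitor": "z_monitor", "model_pred": "z_model_pred"}[spec.surrogate]
    cities = sorted(table.dropna(subset=[xcol, zcol])["city_id"].unique())
    cov = covariate_table.set_index("city_id").reindex(cities)
    return cov, cities


def stepwise_select(table: pd.DataFrame, spec: ModelSpec, candidates,
                    covariate_table: pd.DataFrame, alpha: float = 0.05) -> StepwiseResult:
    """Forward selection of city covariates explaining slope heterogeneity.

    At each step the candidate whose surrogate-interaction Wald p-value is
    smallest and below ``alpha`` enters; selection stops when none qualifies.
    Candidates collinear (|r| > 0.99 across cities) with already-selected
    variables, or constant across cities, are dropped with a warning - with a
    handful of cities perfect confounding is common.  Finally the residual
    heterogeneity (mixture LRT of the city random slope in the selected
    Model 3) is reported.
    """
    candidates = list(candidates)
    cov, cities = _city_covariate_matrix(table, spec, covariate_table, candidates)
    dropped = []
    usable = []
    for c in candidates:
        if c not in cov.columns:
            raise ValueError(f"unknown candidate covariate {c!r}")
        v = cov[c].to_numpy(float)
        if np.isnan(v).any() or np.nanstd(v) == 0:
            dropped.append(c)
            warnings.warn(f"candidate {c!r} constant or missing across cities; dropped",
                          stacklevel=2)
        else:
            usable.append(c)

    selected: list = []
    pvals: dict = {}
    while True:
        best = None
        for c in usable:
            if c in selected:
                continue
            v = cov[c].to_numpy(float)
            if selected:
                vs = cov[selected].to_numpy(float)
                r = np.corrcoef(np.column_stack([vs, v]), rowvar=False)[-1, :-1]
                if np.any(np.abs(r) > 0.99):
                    if c not in dropped:
                        dropped.append(c)
                        warnings.warn(
                            f"candidate {c!r} collinear with selected covariates; "
                            "dropped", stacklevel=2)
                    continue
            try:
                fit = CalibrationModel(
                    table,
                    replace(spec, kind="model3",
                            city_covariates=tuple(selected + [c])),
                    covariate_table,
                ).fit()
            except (ValueError, RuntimeError) as exc:
                logger.info("candidate %r unusable at this step: %s", c, exc)
                continue
            term = f"z:{c}"
            est = float(fit.params[term])
            se = float(np.sqrt(fit.cov_params.loc[term, term]))
            p = float(2 * stats.norm.sf(abs(est) / se)) if se > 0 else 1.0
            pvals[c] = p
            if p < alpha and (best is None or p < best[0]):
                best = (p, c)
        if best is None:
            break
        selected.append(best[1])

    if selected:
        final_spec = replace(spec, kind="model3", city_covariates=tuple(selected))
        final = CalibrationModel(table, final_spec, covariate_table).fit()
        # residual heterogeneity: mixture LRT of the random slope inside model3
        reduced = _model3_without_slope(table, final_spec, covariate_table)
        lrt = 2.0 * (final.llf - reduced.llf)
        if lrt < -LRT_NEG_TOL:
            raise RuntimeError(
                "model3 REML log-likelihood below its no-slope reduction; "
                "the optimisation has failed")
        boundary = ("slope_city" in final.boundary_flags) or lrt <= LRT_CLIP_TOL
        lrt = max(lrt, 0.0)
        if boundary:
            lrt = 0.0
        resid = HeterogeneityResult(lrt, mixture_lrt_p(lrt, boundary), boundary,
                                    final, reduced)
    else:
        final = CalibrationModel(
            table, replace(spec, kind="model1", city_covariates=()),
            covariate_table).fit()
        resid = heterogeneity_test(table, spec, covariate_table)
    return StepwiseResult(selected, final, pvals, resid, dropped)


def _model3_without_slope(table, spec3, covariate_table):
    """Model 3 with the city random slope removed (for the residual-LRT)."""
    m = CalibrationModel(table, spec3, covariate_table)
    # rebuild with model2-style random effects but model3 fixed effects
    from .reml import RandomEffect, VarianceComponentsModel

    df = m.data
    city_codes = pd.factorize(df["city_id"])[0]
    subj_codes = pd.factorize(
        df["city_id"].astype(str) + "||" + df["subject_id"].astype(str)
    )[0]
    eng = VarianceComponentsModel(
        m.endog, m.exog,
        [RandomEffect("city", city_codes, np.ones(len(df))),
         RandomEffect("subject", subj_codes, np.ones(len(df)))],
        city_codes, xnames=m.exog_names,
    )
    from .model import CalibrationResults

    return CalibrationResults(m, eng.fit(reml=spec3.reml))


def predict_effect_of_covariate_shift(gamma4: float, delta: float) -> float:
    """Change in the city calibration coefficient for a raw-unit covariate
    shift of ``delta``: simply gamma4 * delta (Model 3 is linear in the
    covariate)."""
    return float(gamma4) * float(delta)


# --------------------------------------------------------------------------
# city-specific fits (Model 4) and leave-one-city-out cross-validation


def city_specific_fits(table: pd.DataFrame, spec: ModelSpec,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Per-city calibration coefficients from independent Model-4 fits.

    Each city gets its own mixed model with subject random intercepts only.
    Cities with fewer than 2 subjects or 2 distinct months, or a constant
    surrogate, are flagged (``ok = False``, reason given) and should be
    excluded from forest plots.  Output is ordered by city and carries
    inverse-variance weights for precision-proportional plotting.
    """
    xcol = {"ambient_origin": "x_ambient_origin",
            "total_personal": "x_total_personal"}[spec.true_exposure]
    zcol = {"monitor": "z_monitor", "model_pred": "z_model_pred"}[spec.surrogate]
    rows = []
    df = table.dropna(subset=[xcol, zcol])
    q = stats.norm.ppf(1 - alpha / 2)
    for city in sorted(df["city_id"].unique()):
        sub = df[df["city_id"] == city]
        reason = None
        if sub["subject_id"].nunique() < 2:
            reason = "fewer than 2 subjects"
        elif sub["month"].nunique() < 2:
            reason = "fewer than 2 months"
        elif float(np.std(sub[zcol])) == 0:
            reason = "constant surrogate; slope not identifiable"
        rec = {"city_id": city, "n_subjects": sub["subject_id"].nunique(),
               "n_person_months": len(sub)}
        if reason is None:
            include_season = sub["winter"].nunique() > 1
            try:
                fit = CalibrationModel(
                    table,
                    replace(spec, kind="model4", city_id=city,
                            city_covariates=(), interaction=None,
                            include_season=include_season),
                ).fit()
                se = fit.se_gamma1
                rec.update(
                    estimate=fit.gamma1, se=se,
                    ci_low=fit.gamma1 - q * se, ci_high=fit.gamma1 + q * se,
                    weight=1.0 / se**2 if se > 0 else np.nan,
                    ok=True, reason="",
                )
            except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
                reason = str(exc)
        if reason is not None:
            rec.update(estimate=np.nan, se=np.nan, ci_low=np.nan,
                       ci_high=np.nan, weight=np.nan, ok=False, reason=reason)
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class LoocvResult:
    per_city: pd.DataFrame  # city_id, observed, predicted, selected, ok, reason
    correlation: float
    correlation_p: float
    mean_relative_bias: float
    mean_absolute_bias: float
    n_cities_used: int
    n_cities_total: int

    def to_dict(self) -> dict:
        return {
            "correlation": self.correlation,
            "correlation_p": self.correlation_p,
            "mean_relative_bias": self.mean_relative_bias,
            "mean_absolute_bias": self.mean_absolute_bias,
            "n_cities_used": self.n_cities_used,
            "n_cities_total": self.n_cities_total,
            "per_city": self.per_city.to_dict(orient="records"),
        }


def loocv_metrics(predicted, observed):
    """Correlation and mean relative/absolute bias of predicted vs observed."""
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    rel = (predicted - observed) / observed
    if len(predicted) >= 3 and np.std(predicted) > 0 and np.std(observed) > 0:
        r, rp = stats.pearsonr(predicted, observed)
    elif len(predicted) == 2:
        r, rp = np.nan, np.nan
    else:
        r, rp = np.nan, np.nan
    return float(r), float(rp), float(rel.mean()), float(np.abs(rel).mean())


def loocv(table: pd.DataFrame, spec: ModelSpec, candidates,
          covariate_table: pd.DataFrame, alpha: float = 0.05,
          correlation: str = "pearson") -> LoocvResult:
    """Leave-one-city-out validation of the covariate selection.

    For each city i the step-wise selection and Model-3 fit are re-run on the
    remaining cities only (an assertion guarantees the held-out city never
    enters training), and city i's coefficient is predicted as
    gamma1(-i) + sum over selected covariates of gamma4(-i) x covariate_i
    (covariates standardised with training-set statistics when the spec asks
    for standardisation).  Observed coefficients come from per-city Model-4
    fits.  Cities whose Model-4 fit fails are excluded from the metrics with
    the count disclosed.
    """
    xcol = {"ambient_origin": "x_ambient_origin",
            "total_personal": "x_total_personal"}[spec.true_exposure]
    zcol = {"monitor": "z_monitor", "model_pred": "z_model_pred"}[spec.surrogate]
    df = table.dropna(subset=[xcol, zcol])
    cities = sorted(df["city_id"].unique())
    if len(cities) < 3:
        raise ValueError(f"LOOCV needs >= 3 cities, found {len(cities)}")
    observed = city_specific_fits(table, spec, alpha).set_index("city_id")
    cov = covariate_table.set_index("city_id")

    rows = []
    for city in cities:
        train = table[table["city_id"] != city]
        assert city not in set(train["city_id"]), "left-out city leaked into training"
        step = stepwise_select(train, spec, candidates, covariate_table, alpha)
        pred = step.fit.gamma1
        for c in step.selected:
            gamma4 = float(step.fit.params[f"z:{c}"])
            v = float(cov.loc[city, c])
            mu, sd = step.fit.model._cov_scale.get(c, (0.0, 1.0))
            pred += gamma4 * (v - mu) / sd
        obs_row = observed.loc[city]
        rows.append(
            {
                "city_id": city,
                "observed": float(obs_row["estimate"]),
                "predicted": float(pred),
                "selected": list(step.selected),
                "ok": bool(obs_row["ok"]),
                "reason": obs_row["reason"],
            }
        )
    per_city = pd.DataFrame(rows)
    good = per_city[per_city["ok"] & np.isfinite(per_city["observed"])
                    & (per_city["observed"] != 0)]
    n_excl = len(per_city) - len(good)
    if n_excl:
        logger.warning("LOOCV: %d cities excluded from metrics", n_excl)
    r, rp, mrb, mab = loocv_metrics(good["predicted"], good["observed"])
    if correlation == "spearman" and len(good) >= 3:
        r, rp = stats.spearmanr(good["predicted"], good["observed"])
        r, rp = float(r), float(rp)
    return LoocvResult(per_city, r, rp, mrb, mab, len(good), len(per_city))
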