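"""Calibration-coefficient inference: Wald test against 1, season effect
modification with stratified coefficients, and subgroup sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .model import CalibrationModel, ModelSpec

__all__ = [
    "wald_test_gamma1_equals_1",
    "season_modification",
    "subgroup_interaction",
    "CalibrationReport",
]


def wald_test_gamma1_equals_1(gamma1_hat: float, var_gamma1: float) -> float:
    """p-value for H0: gamma1 = 1 via (gamma1_hat - 1)^2 / var ~ chi2_1.

    A calibration coefficient of 1 means the surrogate introduces no
    multiplicative bias; values below 1 imply proportional attenuation of
    health-effect estimates that use the surrogate.
    """
    if not var_gamma1 > 0:
        raise ValueError(f"var_gamma1 must be > 0, got {var_gamma1}")
    stat = (float(gamma1_hat) - 1.0) ** 2 / float(var_gamma1)
    return float(stats.chi2.sf(stat, df=1))


@dataclass
class CalibrationReport:
    """Calibration coefficient with its CI and effect-modification summary."""

    gamma1_hat: float
    ci95: tuple
    p_value_gamma1_eq_1: float
    interaction_term: str | None = None
    interaction_p: float | None = None
    stratified: dict | None = None  # level -> {"estimate", "ci95"}
    spec: ModelSpec | None = None
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "gamma1_hat": self.gamma1_hat,
            "ci95": list(self.ci95),
            "p_value_gamma1_eq_1": self.p_value_gamma1_eq_1,
            "interaction_term": self.interaction_term,
            "interaction_p": self.interaction_p,
            "stratified": self.stratified,
            "alpha": self.alpha,
        }


def _interaction_p(results, term: str) -> float:
    est = float(results.params[term])
    se = float(np.sqrt(results.cov_params.loc[term, term]))
    if not se > 0:
        raise ValueError(f"degenerate standard error for {term}")
    return float(2 * stats.norm.sf(abs(est) / se))


def _stratified(results, term: str, alpha: float) -> dict:
    """Per-level slopes as linear combinations with delta-method CIs.

    Reference level (indicator = 0): gamma1 itself; indicator = 1 level:
    gamma1 + interaction.  For the reference level the linear-combination CI
    is identical to the main-effect CI by construction.
    """
    q = stats.norm.ppf(1 - alpha / 2)
    out = {}
    for level, weights in (
        ("0", {"z": 1.0}),
        ("1", {"z": 1.0, f"z:{term}": 1.0}),
    ):
        est, se = results.linear_combination(weights)
        out[level] = {"estimate": est, "ci95": (est - q * se, est + q * se)}
    return out


def _modification(table, spec: ModelSpec, term: str, alpha: float,
                  covariate_table=None, label_map=None) -> CalibrationReport:
    base = CalibrationModel(table, replace(spec, interaction=None),
                            covariate_table).fit()
    aug = CalibrationModel(table, replace(spec, interaction=term),
                           covariate_table).fit()
    p_int = _interaction_p(aug, f"z:{term}")
    strat = None
    if p_int < alpha:
        raw = _stratified(aug, term, alpha)
        if label_map:
            strat = {label_map[k]: v for k, v in raw.items()}
        else:
            strat = raw
    return CalibrationReport(
        gamma1_hat=base.gamma1,
        ci95=base.conf_int_gamma1(alpha),
        p_value_gamma1_eq_1=base.wald_gamma1_equals_1(),
        interaction_term=term,
        interaction_p=p_int,
        stratified=strat,
        spec=spec,
        alpha=alpha,
    )


def season_modification(table: pd.DataFrame, spec: ModelSpec,
                        alpha: float = 0.05,
                        covariate_table=None) -> CalibrationReport:
    """Test surrogate x season interaction; stratify when significant.

    Fits the base model and the model augmented with a winter x surrogate
    interaction.  When the interaction is significant at ``alpha`` the report
    carries season-stratified coefficients (summer is the reference season;
    the winter slope is gamma1 + interaction with a delta-method CI).
    """
    xcol = {"ambient_origin": "x_ambient_origin",
            "total_personal": "x_total_personal"}[spec.true_exposure]
    zcol = {"monitor": "z_monitor", "model_pred": "z_model_pred"}[spec.surrogate]
    present = table.dropna(subset=[xcol, zcol])
    if present["winter"].nunique() < 2:
        raise ValueError("both seasons must be present to test season modification")
    return _modification(table, spec, "winter", alpha, covariate_table,
                         label_map={"0": "summer", "1": "winter"})


def subgroup_interaction(table: pd.DataFrame, spec: ModelSpec,
                         flags=("senior", "copd", "mi", "chd"),
                         alpha: float = 0.05,
                         covariate_table=None) -> dict:
    """Effect modification by subject subpopulation flags.

    Same mechanics as :func:`season_modification` with a binary subject flag
    (seniors = age over 65, COPD, MI, CHD) replacing season in the
    interaction.  Each flag must have both levels represented; a constant
    flag raises.
    Returns {flag: CalibrationReport}.
    """
    out = {}
    for flag in flags:
        if flag not in table.columns:
            raise ValueError(f"analysis table lacks subgroup flag {flag!r}")
        if table[flag].nunique() < 2:
            raise ValueError(f"subgroup flag {flag!r} is constant")
        out[flag] = _modification(table, spec, flag, alpha, covariate_table)
    return out
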