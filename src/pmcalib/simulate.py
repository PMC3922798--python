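"""Synthetic multi-city personal-exposure panel generator.

Emulates pooled PM2.5 validation-study data: daily personal PM2.5 and
sulfate, a central ambient monitor per city, monthly outdoor-home model
predictions, and city-level covariates, with known ground-truth calibration
parameters so that every downstream stage (exposure construction, mixed-model
fitting, heterogeneity testing, cross-validation) can be tested against truth.

Two generation modes:

``regression-truth``
    The surrogate exposure is drawn first and the "true" monthly exposure is
    then generated from the calibration mixed model itself
    (intercept + city/subject random intercepts + (slope + city random slope)
    * surrogate + season effect + residual).  Fitted coefficients are directly
    comparable to the configured truth.

``mechanistic``
    City-month ambient concentrations are drawn, each subject has an
    infiltration ratio (personal/ambient sulfate ratio), personal exposure of
    ambient origin is ratio x ambient, total personal adds non-ambient-source
    PM2.5, the monitor observes ambient plus instrument error and the outdoor
    model predicts ambient plus prediction error.  The implied attenuation is
    stored in the truth record.
"""

from __future__ import annotations

import calendar
import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "PanelDataset",
    "simulate_panel",
    "write_fixture",
    "read_fixture",
]

_EARTH_RADIUS_MI = 3958.8
_DEG_LAT_MI = 69.0  # miles per degree latitude (spherical)

# default per-city covariate generators: name -> (low, high) of a uniform draw
_DEFAULT_COVARIATE_RANGES = {
    "vehicles_per_unit": (1.2, 2.2),
    "heating_degree_days": (2.0, 7.0),  # thousands of degree-days
    "residents_per_unit": (2.0, 3.0),
}


@dataclass
class SimulationConfig:
    """Ground-truth parameters and study-design knobs for :func:`simulate_panel`.

    Concentration parameters are in ug/m3; the calibration slope and the
    sulfate ratio are unitless.  Defaults emulate a pooled multi-city
    validation panel: monitor-scale ambient field ~15.9 +/- 5 ug/m3, personal
    / ambient sulfate ratio 0.64 +/- 0.25 (lower in winter), non-ambient
    personal sources ~15 ug/m3, and a calibration slope of 0.54 with modest
    between-city slope heterogeneity.
    """

    # design
    n_cities: int = 9
    subjects_per_city: int = 30
    months_per_subject: int = 6
    days_per_month_sampled: int = 7
    mode: str = "regression-truth"  # or "mechanistic"
    target_surrogate: str = "monitor"  # surrogate that Eq-style truth is drawn from
    seed: int = 0

    # fixed effects of the generating calibration model
    gamma0: float = 5.0
    gamma1_true: float = 0.54
    gamma2_true: float = -1.5  # winter (Oct-Mar) additive effect
    gamma_seasonslope_true: float = 0.0  # winter x surrogate slope modification
    gamma_seniorslope_true: float = 0.0  # (age>=65) x surrogate slope modification

    # variance components
    sigma_city: float = 1.0
    sigma_subject: float = 2.0
    sigma_slope_city: float = 0.1
    sigma_w: float = 3.0

    # exposure physics
    ambient_mean: float = 15.9
    ambient_sd: float = 5.0
    sulfate_ratio_mean: float = 0.64
    sulfate_ratio_sd: float = 0.25
    sulfate_ratio_winter_shift: float = -0.11  # mechanistic mode only
    nonambient_mean: float = 15.0
    nonambient_sd: float = 8.0
    monitor_error_sd: float = 2.0
    model_pred_error_sd: float = 3.0
    ambient_so4_mean: float = 4.0
    ambient_so4_sd: float = 1.0
    so4_noise_sd: float = 0.3  # day-level personal sulfate noise, mechanistic mode

    # city covariates and their raw-scale interaction effects on the slope
    covariate_effects: dict = field(default_factory=dict)  # name -> gamma4_true
    covariate_values: dict = field(default_factory=dict)  # name -> per-city array
    covariate_ranges: dict = field(
        default_factory=lambda: dict(_DEFAULT_COVARIATE_RANGES)
    )

    # geography / demographics
    residence_radius_mi: float = 10.0
    monitor_offset_mi: float = 2.0
    distant_monitor_city: int | None = None  # place that city's monitor ~60 mi away
    age_range: tuple = (40.0, 90.0)
    include_minors: bool = False
    minor_fraction: float = 0.1
    condition_prevalence: dict = field(
        default_factory=lambda: {"copd": 0.25, "mi": 0.15, "chd": 0.15}
    )
    time_indoors_range: tuple = (0.65, 0.95)
    year: int = 2000

    def validate(self) -> None:
        for name in (
            "n_cities",
            "subjects_per_city",
            "months_per_subject",
            "days_per_month_sampled",
        ):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in (
            "sigma_city",
            "sigma_subject",
            "sigma_slope_city",
            "sigma_w",
            "ambient_sd",
            "sulfate_ratio_sd",
            "nonambient_sd",
            "monitor_error_sd",
            "model_pred_error_sd",
            "ambient_so4_sd",
            "so4_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.mode not in ("regression-truth", "mechanistic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.target_surrogate not in ("monitor", "model_pred"):
            raise ValueError(f"unknown target_surrogate {self.target_surrogate!r}")
        if self.months_per_subject > 12:
            raise ValueError("months_per_subject must be <= 12")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class PanelDataset:
    """Container for one simulated (or loaded) panel study."""

    daily: pd.DataFrame
    monitors: pd.DataFrame
    model_pred: pd.DataFrame
    city_covariates: pd.DataFrame
    truth: dict

    def is_empty(self) -> bool:
        return len(self.daily) == 0


def _truncnorm(rng, mean, sd, low, high, size):
    """Truncated normal by rejection; falls back to clipping after 100 rounds."""
    if sd == 0:
        return np.clip(np.full(size, float(mean)), low, high)
    out = rng.normal(mean, sd, size)
    bad = (out < low) | (out > high)
    for _ in range(100):
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < low) | (out > high)
    return np.clip(out, low, high)


def _city_geography(cfg: SimulationConfig):
    """City centroids strung across the continent, >300 mi apart."""
    i = np.arange(cfg.n_cities)
    lat = np.full(cfg.n_cities, 38.0)
    lon = -120.0 + 6.0 * i
    return lat, lon


def _sampled_months(cfg: SimulationConfig) -> np.ndarray:
    """Calendar months spread evenly over the year so both seasons appear."""
    m = cfg.months_per_subject
    return np.array([int(12 * t / m) + 1 for t in range(m)])


def simulate_panel(config: SimulationConfig) -> PanelDataset:
    """Generate one synthetic panel study with known ground truth.

    Returns a :class:`PanelDataset` whose ``truth`` dict records every
    configured parameter plus realised per-city intercepts/slopes and, in
    mechanistic mode, the implied population attenuation slope.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n_c, n_s, n_m = cfg.n_cities, cfg.subjects_per_city, cfg.months_per_subject
    months = _sampled_months(cfg)
    winter_m = np.isin(months, [10, 11, 12, 1, 2, 3]).astype(float)
    city_lat, city_lon = _city_geography(cfg)

    # --- city level -------------------------------------------------------
    cov_names = list(cfg.covariate_ranges)
    cov_vals = {}
    for name in cov_names:
        if name in cfg.covariate_values:
            v = np.asarray(cfg.covariate_values[name], dtype=float)
            if len(v) != n_c:
                raise ValueError(
                    f"covariate_values[{name!r}] has {len(v)} entries, "
                    f"expected {n_c}"
                )
        else:
            lo, hi = cfg.covariate_ranges[name]
            v = rng.uniform(lo, hi, n_c)
        cov_vals[name] = v
    for name in cfg.covariate_effects:
        if name not in cov_vals:
            raise ValueError(f"covariate_effects names unknown covariate {name!r}")

    g1 = rng.normal(0.0, cfg.sigma_city, n_c)  # city random intercepts
    g3 = rng.normal(0.0, cfg.sigma_slope_city, n_c)  # city random slopes
    # covariate-driven slope structure (raw-unit gamma4 on centred covariates,
    # so the population-average slope stays at gamma1_true)
    cov_slope = np.zeros(n_c)
    for name, gamma4 in cfg.covariate_effects.items():
        v = cov_vals[name]
        cov_slope += gamma4 * (v - v.mean())
    city_slope = cfg.gamma1_true + cov_slope + g3

    # --- subject level ----------------------------------------------------
    n_subj = n_c * n_s
    subj_city = np.repeat(np.arange(n_c), n_s)
    subj_idx = np.tile(np.arange(n_s), n_c)
    subject_ids = np.array(
        [f"c{c:02d}_s{s:03d}" for c, s in zip(subj_city, subj_idx)]
    )
    ages = rng.uniform(cfg.age_range[0], cfg.age_range[1], n_subj)
    if cfg.include_minors:
        minor = rng.random(n_subj) < cfg.minor_fraction
        ages[minor] = rng.uniform(8.0, 17.5, minor.sum())
    senior = (ages >= 65.0).astype(float)
    flags = {
        k: (rng.random(n_subj) < p).astype(int)
        for k, p in cfg.condition_prevalence.items()
    }
    g2 = rng.normal(0.0, cfg.sigma_subject, n_subj)
    ratio_subj = _truncnorm(
        rng, cfg.sulfate_ratio_mean, cfg.sulfate_ratio_sd, 0.0, 1.5, n_subj
    )
    t_indoors = rng.uniform(*cfg.time_indoors_range, n_subj)

    # residences: uniform in a disc around the city centroid
    r = cfg.residence_radius_mi * np.sqrt(rng.random(n_subj))
    theta = rng.uniform(0, 2 * np.pi, n_subj)
    res_lat = city_lat[subj_city] + (r * np.sin(theta)) / _DEG_LAT_MI
    res_lon = city_lon[subj_city] + (r * np.cos(theta)) / (
        _DEG_LAT_MI * np.cos(np.deg2rad(city_lat[subj_city]))
    )

    # --- city-month ambient fields ---------------------------------------
    A = np.clip(rng.normal(cfg.ambient_mean, cfg.ambient_sd, (n_c, n_m)), 1.0, None)
    SO4 = np.clip(
        rng.normal(cfg.ambient_so4_mean, cfg.ambient_so4_sd, (n_c, n_m)), 0.5, None
    )

    # --- subject-month (= analysis unit) quantities -----------------------
    # arrays shaped (n_subj, n_m)
    A_sm = A[subj_city, :]
    SO4_sm = SO4[subj_city, :]
    winter_sm = np.broadcast_to(winter_m, (n_subj, n_m))

    pred_err = rng.normal(0.0, cfg.model_pred_error_sd, (n_subj, n_m))
    eps = rng.normal(0.0, cfg.sigma_w, (n_subj, n_m))
    nonamb = np.clip(
        rng.normal(cfg.nonambient_mean, cfg.nonambient_sd, (n_subj, n_m)), 0.0, None
    )

    truth: dict = {
        f"cfg_{k}": v
        for k, v in dataclasses.asdict(cfg).items()
        if np.isscalar(v) or isinstance(v, (str, bool))
    }
    truth.update(
        {
            "city_random_intercepts": g1.tolist(),
            "city_random_slopes": g3.tolist(),
            "city_slopes": city_slope.tolist(),
            "covariate_names": cov_names,
        }
    )

    if cfg.mode == "regression-truth":
        if cfg.target_surrogate == "monitor":
            Z = A_sm
            model_pred_vals = A_sm + pred_err
        else:
            Z = A_sm + pred_err
            model_pred_vals = Z
        slope_sm = (
            city_slope[subj_city][:, None]
            + cfg.gamma_seasonslope_true * winter_sm
            + cfg.gamma_seniorslope_true * senior[:, None]
        )
        x_amb = (
            cfg.gamma0
            + g1[subj_city][:, None]
            + g2[:, None]
            + slope_sm * Z
            + cfg.gamma2_true * winter_sm
            + eps
        )
        n_floored = int((x_amb < 0).sum())
        x_amb = np.clip(x_amb, 0.0, None)
        x_total = x_amb + nonamb
        # encode x_amb into sulfate so the tracer recovers it exactly
        # (monitor series are flat within the month in this mode)
        ratio_enc = x_amb / A_sm
        personal_so4_sm = ratio_enc * SO4_sm
        truth["n_floored_at_zero"] = n_floored
    else:  # mechanistic
        ratio_sm = np.clip(
            ratio_subj[:, None] + cfg.sulfate_ratio_winter_shift * winter_sm, 0.0, 1.5
        )
        x_amb = ratio_sm * A_sm
        x_total = x_amb + nonamb
        model_pred_vals = np.clip(A_sm + pred_err, 0.0, None)
        personal_so4_sm = ratio_sm * SO4_sm
        mean_ratio = float(ratio_sm.mean())
        var_A = float(A.var())
        n_days_month = 30.0
        truth["mean_infiltration_ratio"] = mean_ratio
        truth["implied_slope_ambient_monitor"] = mean_ratio * var_A / (
            var_A + cfg.monitor_error_sd**2 / n_days_month
        )

    # --- expand to daily records ------------------------------------------
    n_d = cfg.days_per_month_sampled
    day_offsets = np.arange(n_d)
    rows = n_subj * n_m * n_d
    s_idx = np.repeat(np.arange(n_subj), n_m * n_d)
    m_idx = np.tile(np.repeat(np.arange(n_m), n_d), n_subj)
    d_idx = np.tile(day_offsets, n_subj * n_m)

    dates = np.array(
        [
            dt.date(cfg.year, months[m], 3 + d).isoformat()
            for m in range(n_m)
            for d in day_offsets
        ]
    )
    date_col = np.tile(dates, n_subj)

    if cfg.mode == "regression-truth":
        # flat within month: monthly means reproduce the generated values exactly
        personal_pm25 = x_total[s_idx, m_idx]
        personal_so4 = personal_so4_sm[s_idx, m_idx]
    else:
        day_noise = rng.normal(0.0, cfg.sigma_w, rows)
        so4_noise = rng.normal(0.0, cfg.so4_noise_sd, rows)
        personal_pm25 = np.clip(
            x_amb[s_idx, m_idx] + nonamb[s_idx, m_idx] + day_noise, 0.0, None
        )
        personal_so4 = np.clip(personal_so4_sm[s_idx, m_idx] + so4_noise, 0.0, None)

    daily = pd.DataFrame(
        {
            "city_id": np.array([f"city{c:02d}" for c in subj_city])[s_idx],
            "subject_id": subject_ids[s_idx],
            "date": date_col,
            "age": np.round(ages[s_idx], 1),
            "personal_pm25": personal_pm25,
            "personal_so4": personal_so4,
            "ambient_so4": SO4_sm[s_idx, m_idx],
            "lat": res_lat[s_idx],
            "lon": res_lon[s_idx],
            "time_fraction_indoors": t_indoors[s_idx],
        }
    )
    for k, v in flags.items():
        daily[k] = v[s_idx]

    # --- monitor series: every calendar day of each sampled month ---------
    mon_rows = []
    for c in range(n_c):
        mlat = city_lat[c]
        offset = cfg.monitor_offset_mi
        if cfg.distant_monitor_city is not None and c == cfg.distant_monitor_city:
            offset = 60.0
        mlon = city_lon[c] + offset / (_DEG_LAT_MI * np.cos(np.deg2rad(mlat)))
        for m in range(n_m):
            ndays = calendar.monthrange(cfg.year, months[m])[1]
            if cfg.mode == "regression-truth":
                vals = np.full(ndays, A[c, m])
            else:
                vals = np.clip(
                    A[c, m] + rng.normal(0.0, cfg.monitor_error_sd, ndays), 0.0, None
                )
            mon_rows.append(
                pd.DataFrame(
                    {
                        "monitor_id": f"mon{c:02d}",
                        "lat": mlat,
                        "lon": mlon,
                        "date": [
                            dt.date(cfg.year, months[m], d + 1).isoformat()
                            for d in range(ndays)
                        ],
                        "ambient_pm25": vals,
                    }
                )
            )
    monitors = pd.concat(mon_rows, ignore_index=True)

    model_pred = pd.DataFrame(
        {
            "city_id": np.array([f"city{c:02d}" for c in subj_city]).repeat(n_m),
            "subject_id": subject_ids.repeat(n_m),
            "year": cfg.year,
            "month": np.tile(months, n_subj),
            "predicted_pm25": np.clip(model_pred_vals.ravel(), 0.0, None),
        }
    )

    city_covariates = pd.DataFrame(
        {"city_id": [f"city{c:02d}" for c in range(n_c)], **cov_vals}
    )

    return PanelDataset(daily, monitors, model_pred, city_covariates, truth)


# --------------------------------------------------------------------------
# fixtures on disk

_FILES = {
    "daily": "daily.csv",
    "monitors": "monitors.csv",
    "model_pred": "model_pred.csv",
    "city_covariates": "city_covariates.csv",
}


def write_fixture(dataset: PanelDataset, directory) -> dict:
    """Write a dataset to CSV files (+ truth.json); returns the file paths.

    Files round-trip losslessly through :func:`read_fixture` (floats written
    with repr precision).  Refuses to write an empty dataset.
    """
    if dataset.is_empty():
        raise ValueError("refusing to write an empty dataset")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for attr, fname in _FILES.items():
        p = directory / fname
        getattr(dataset, attr).to_csv(p, index=False, float_format="%.17g")
        paths[attr] = p
    tp = directory / "truth.json"
    tp.write_text(json.dumps(dataset.truth, indent=1, sort_keys=True))
    paths["truth"] = tp
    return paths


def read_fixture(directory) -> PanelDataset:
    """Read a dataset previously written by :func:`write_fixture` (truth optional)."""
    directory = Path(directory)
    frames = {}
    for attr, fname in _FILES.items():
        p = directory / fname
        if not p.exists():
            raise FileNotFoundError(f"missing fixture file {p}")
        frames[attr] = pd.read_csv(p, float_precision="round_trip")
    tp = directory / "truth.json"
    truth = json.loads(tp.read_text()) if tp.exists() else {}
    return PanelDataset(truth=truth, **frames)
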