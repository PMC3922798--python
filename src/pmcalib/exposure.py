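"""From daily records to the monthly analysis table.

The analysis unit is the person-month: monthly-averaged "true" personal
exposures (total personal PM2.5, and PM2.5 of ambient origin via the sulfate
tracer) paired with two surrogate exposures (nearest-monitor ambient PM2.5 and
an outdoor-home model prediction), a season label and the nesting ids needed
by the calibration mixed models.

Key field conventions
---------------------
* season: October-March is winter, April-September is summer; the ``winter``
  column codes winter = 1, summer = 0.
* subjects younger than 18 are excluded (long-term studies target adults);
* the nearest-monitor match is a haversine great-circle distance capped at
  30 miles by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExposureConfig",
    "ambient_origin_tracer",
    "ambient_origin_timeweighted",
    "assign_season",
    "haversine_miles",
    "nearest_monitor",
    "monthly_monitor_average",
    "build_analysis_table",
]

EARTH_RADIUS_MI = 3958.8
WINTER_MONTHS = frozenset({10, 11, 12, 1, 2, 3})

DAILY_REQUIRED = [
    "city_id",
    "subject_id",
    "date",
    "age",
    "personal_pm25",
    "personal_so4",
    "ambient_so4",
    "lat",
    "lon",
]
MONITOR_REQUIRED = ["monitor_id", "lat", "lon", "date", "ambient_pm25"]
PRED_REQUIRED = ["city_id", "subject_id", "year", "month", "predicted_pm25"]


@dataclass
class ExposureConfig:
    """Eligibility and matching rules for building the analysis table."""

    min_age: float = 18.0
    min_days_per_month: int = 1
    max_monitor_distance_mi: float = 30.0
    matched_days: bool = False  # monitor monthly mean over personal sampling days only
    tracer_daily_ratios: bool = False  # mean of daily SO4 ratios vs ratio of means


def ambient_origin_tracer(personal_so4, ambient_so4, ambient_pm25):
    """Sulfate-tracer estimate of personal PM2.5 of ambient origin.

    The personal/ambient sulfate ratio approximates the fraction of ambient
    PM2.5 that infiltrates indoors and remains airborne, so

        PM_ambient-origin = (SO4_personal / SO4_ambient) * PM2.5_ambient.

    A zero or missing ambient sulfate yields NaN (with a logged reason),
    never a division error.  Accepts scalars or arrays.
    """
    p = np.asarray(personal_so4, dtype=float)
    a = np.asarray(ambient_so4, dtype=float)
    pm = np.asarray(ambient_pm25, dtype=float)
    bad = ~(a > 0)
    if np.any(bad):
        logger.info(
            "ambient_origin_tracer: %d value(s) with ambient SO4 <= 0 or missing "
            "set to missing",
            int(np.sum(bad)),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, p / np.where(bad, np.nan, a) * pm)
    if out.ndim == 0:
        return float(out)
    return out


def ambient_origin_timeweighted(ambient_pm25, infiltration_efficiency,
                                time_fraction_indoors):
    """Time-weighted ambient-origin exposure for subjects without personal sulfate.

    Weighted average of indoor PM2.5 of ambient origin (ambient x home
    infiltration efficiency) and ambient PM2.5, weighted by the fractions of
    time spent indoors and outdoors.
    """
    t = np.asarray(time_fraction_indoors, dtype=float)
    if np.any((t < 0) | (t > 1)):
        raise ValueError("time_fraction_indoors must lie in [0, 1]")
    f = np.asarray(infiltration_efficiency, dtype=float)
    a = np.asarray(ambient_pm25, dtype=float)
    out = t * f * a + (1.0 - t) * a
    return float(out) if out.ndim == 0 else out


def assign_season(month_of_year: int) -> str:
    """Map a calendar month to its season: Oct-Mar winter, Apr-Sep summer."""
    m = int(month_of_year)
    if not 1 <= m <= 12:
        raise ValueError(f"month must be in 1..12, got {month_of_year}")
    return "winter" if m in WINTER_MONTHS else "summer"


def haversine_miles(lat1, lon1, lat2, lon2):
    """Great-circle distance in miles (sphere of radius 3958.8 mi)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (np.asarray(lat1, float),
                                              np.asarray(lon1, float),
                                              np.asarray(lat2, float),
                                              np.asarray(lon2, float)))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    out = 2 * EARTH_RADIUS_MI * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return float(out) if out.ndim == 0 else out


def _check_coords(lat, lon, what):
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError(f"invalid {what} coordinates (|lat|>90 or |lon|>180)")


def nearest_monitor(residence_lat, residence_lon, monitor_locations: pd.DataFrame,
                    max_distance_mi: float = 30.0):
    """Nearest monitor to a residence, or ``None`` beyond ``max_distance_mi``.

    ``monitor_locations`` needs columns monitor_id, lat, lon (one row per
    monitor).  Distance ties are broken by lexicographically smallest
    monitor_id for determinism.
    """
    if len(monitor_locations) == 0:
        raise ValueError("at least one monitor must be supplied")
    _check_coords(residence_lat, residence_lon, "residence")
    _check_coords(monitor_locations["lat"], monitor_locations["lon"], "monitor")
    locs = monitor_locations.sort_values("monitor_id", kind="stable")
    d = haversine_miles(residence_lat, residence_lon,
                        locs["lat"].to_numpy(), locs["lon"].to_numpy())
    d = np.atleast_1d(d)
    best = int(np.argmin(d))  # first occurrence wins -> lexicographic tie-break
    if d[best] > max_distance_mi:
        return None
    return locs["monitor_id"].iloc[best]


def monthly_monitor_average(series: pd.DataFrame, year: int, month: int,
                            mode: str = "all_days", personal_days=None):
    """Monthly mean ambient PM2.5 for one monitor.

    ``all_days`` averages every non-missing day of the calendar month (the
    monitor typically reports on more days than the subject was sampled);
    ``matched_days`` averages only the supplied personal sampling dates.
    Returns NaN when no day qualifies.
    """
    if mode not in ("all_days", "matched_days"):
        raise ValueError(f"unknown mode {mode!r}")
    dates = pd.to_datetime(series["date"])
    sel = (dates.dt.year == int(year)) & (dates.dt.month == int(month))
    if mode == "matched_days":
        if personal_days is None:
            raise ValueError("matched_days mode requires personal_days")
        wanted = {pd.Timestamp(d) for d in personal_days}
        sel &= dates.isin(wanted)
    vals = series.loc[sel, "ambient_pm25"].dropna()
    return float(vals.mean()) if len(vals) else float("nan")


def _validate_schema(df: pd.DataFrame, required, name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{name}: missing required column(s) {missing}")


def build_analysis_table(daily: pd.DataFrame, monitors: pd.DataFrame,
                         model_pred: pd.DataFrame,
                         config: ExposureConfig | None = None) -> pd.DataFrame:
    """Aggregate daily records into the person-month analysis table.

    Steps: exclude subjects under 18; average personal PM2.5 (and the sulfate
    tracer quantities) within subject-month; attach the nearest-monitor
    monthly surrogate (<= 30 mi) and the outdoor-home model prediction; label
    the season.  Person-month counts retained are logged.

    Returns one row per (city, subject, year, month) that meets the
    minimum-days rule, with columns::

        city_id subject_id year month month_index season winter
        x_ambient_origin x_total_personal z_monitor z_model_pred
        n_personal_days age senior [copd mi chd ...]
    """
    cfg = config or ExposureConfig()
    _validate_schema(daily, DAILY_REQUIRED, "daily")
    _validate_schema(monitors, MONITOR_REQUIRED, "monitors")
    _validate_schema(model_pred, PRED_REQUIRED, "model_pred")

    d = daily.copy()
    d["date"] = pd.to_datetime(d["date"], errors="raise")
    n_subjects_in = d["subject_id"].nunique()
    d = d[d["age"] >= cfg.min_age]
    logger.info(
        "age filter (>= %g): kept %d of %d subjects",
        cfg.min_age, d["subject_id"].nunique(), n_subjects_in,
    )
    if len(d) == 0:
        raise ValueError("no eligible daily records after the age filter")
    d["year"] = d["date"].dt.year
    d["month"] = d["date"].dt.month

    mon = monitors.copy()
    mon["date"] = pd.to_datetime(mon["date"], errors="raise")
    mon["year"] = mon["date"].dt.year
    mon["month"] = mon["date"].dt.month
    mon_locs = mon[["monitor_id", "lat", "lon"]].drop_duplicates("monitor_id")
    # monthly all-days means per monitor
    mon_month = (
        mon.dropna(subset=["ambient_pm25"])
        .groupby(["monitor_id", "year", "month"], as_index=False)["ambient_pm25"]
        .mean()
        .rename(columns={"ambient_pm25": "monitor_month_mean"})
    )

    # nearest monitor per subject (static residence; first row's coordinates)
    subj = (
        d.groupby("subject_id", as_index=False)
        .agg(lat=("lat", "first"), lon=("lon", "first"), age=("age", "first"))
    )
    _check_coords(subj["lat"], subj["lon"], "residence")
    _check_coords(mon_locs["lat"], mon_locs["lon"], "monitor")
    locs = mon_locs.sort_values("monitor_id", kind="stable")
    dist = haversine_miles(
        subj["lat"].to_numpy()[:, None], subj["lon"].to_numpy()[:, None],
        locs["lat"].to_numpy()[None, :], locs["lon"].to_numpy()[None, :],
    )
    dist = np.atleast_2d(dist)
    best = np.argmin(dist, axis=1)
    best_d = dist[np.arange(len(subj)), best]
    subj["nearest_monitor"] = np.where(
        best_d <= cfg.max_monitor_distance_mi,
        locs["monitor_id"].to_numpy()[best], None,
    )
    n_unmatched = int(pd.isna(subj["nearest_monitor"]).sum())
    if n_unmatched:
        logger.info("%d subject(s) beyond %g mi of any monitor",
                    n_unmatched, cfg.max_monitor_distance_mi)

    # same-day nearest-monitor value alongside each daily record (tracer input)
    d = d.merge(subj[["subject_id", "nearest_monitor"]], on="subject_id", how="left")
    d = d.merge(
        mon[["monitor_id", "date", "ambient_pm25"]].dropna(
            subset=["ambient_pm25"]
        ).rename(columns={"ambient_pm25": "mon_pm_same_day"}),
        left_on=["nearest_monitor", "date"],
        right_on=["monitor_id", "date"],
        how="left",
    ).drop(columns=["monitor_id"])

    # sulfate tracer quantities over the days where both SO4 values exist
    both = d["personal_so4"].notna() & d["ambient_so4"].notna()
    d["_p_so4"] = d["personal_so4"].where(both)
    d["_a_so4"] = d["ambient_so4"].where(both)
    with np.errstate(divide="ignore", invalid="ignore"):
        daily_ratio = d["_p_so4"] / d["_a_so4"]
    d["_so4_ratio_day"] = daily_ratio.replace([np.inf, -np.inf], np.nan)
    d["_mon_pm_so4day"] = d["mon_pm_same_day"].where(both)

    keys = ["city_id", "subject_id", "year", "month"]
    grouped = d.groupby(keys, as_index=False).agg(
        x_total_personal=("personal_pm25", "mean"),
        n_personal_days=("date", "nunique"),
        _p_so4_mean=("_p_so4", "mean"),
        _a_so4_mean=("_a_so4", "mean"),
        _ratio_daily=("_so4_ratio_day", "mean"),
        _mon_pm_so4=("_mon_pm_so4day", "mean"),
    )
    grouped = grouped[grouped["n_personal_days"] >= cfg.min_days_per_month]
    grouped = grouped.merge(
        subj[["subject_id", "age", "nearest_monitor"]], on="subject_id", how="left"
    )
    if cfg.tracer_daily_ratios:
        ratio = grouped["_ratio_daily"]
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = grouped["_p_so4_mean"] / grouped["_a_so4_mean"]
        ratio = ratio.where(grouped["_a_so4_mean"] > 0)
    grouped["so4_ratio"] = ratio.replace([np.inf, -np.inf], np.nan)
    grouped["x_ambient_origin"] = grouped["so4_ratio"] * grouped["_mon_pm_so4"]

    # surrogate 1: nearest-monitor monthly average
    if not cfg.matched_days:
        grouped = grouped.merge(
            mon_month,
            left_on=["nearest_monitor", "year", "month"],
            right_on=["monitor_id", "year", "month"],
            how="left",
        ).drop(columns=["monitor_id"])
        grouped["z_monitor"] = grouped["monitor_month_mean"]
    else:
        # per day, fall back to the nearest monitor WITH data that day
        sidx = {sid: i for i, sid in enumerate(subj["subject_id"])}
        midx = {mid: j for j, mid in enumerate(locs["monitor_id"])}
        days = d[keys + ["date"]].drop_duplicates(subset=["subject_id", "date"])
        cand = days.merge(
            mon[["monitor_id", "date", "ambient_pm25"]].dropna(
                subset=["ambient_pm25"]),
            on="date", how="inner",
        )
        cand["_dist"] = dist[
            cand["subject_id"].map(sidx).to_numpy(),
            cand["monitor_id"].map(midx).to_numpy(),
        ]
        cand = cand[cand["_dist"] <= cfg.max_monitor_distance_mi]
        cand = cand.sort_values(
            ["subject_id", "date", "_dist", "monitor_id"], kind="stable"
        ).drop_duplicates(subset=["subject_id", "date"], keep="first")
        zm = cand.groupby(keys, as_index=False)["ambient_pm25"].mean().rename(
            columns={"ambient_pm25": "z_monitor"})
        grouped = grouped.merge(zm, on=keys, how="left")
        grouped["monitor_month_mean"] = np.nan

    # surrogate 2: outdoor-home model prediction
    mp = model_pred.rename(columns={"predicted_pm25": "z_model_pred"})
    grouped = grouped.merge(
        mp[["subject_id", "year", "month", "z_model_pred"]],
        on=["subject_id", "year", "month"],
        how="left",
    )

    grouped["season"] = grouped["month"].map(assign_season)
    grouped["winter"] = (grouped["season"] == "winter").astype(int)
    grouped["senior"] = (grouped["age"] >= 65.0).astype(int)
    grouped = grouped.sort_values(
        ["city_id", "subject_id", "year", "month"], kind="stable"
    ).reset_index(drop=True)
    grouped["month_index"] = grouped.groupby("subject_id").cumcount()

    # carry through optional subject-level binary flags
    extra = [c for c in daily.columns if c not in DAILY_REQUIRED
             and c not in ("time_fraction_indoors",)]
    if extra:
        fl = d.groupby("subject_id", as_index=False)[extra].first()
        grouped = grouped.merge(fl, on="subject_id", how="left")

    cols = [
        "city_id", "subject_id", "year", "month", "month_index", "season",
        "winter", "x_ambient_origin", "x_total_personal", "z_monitor",
        "z_model_pred", "n_personal_days", "age", "senior", *extra,
    ]
    out = grouped[cols]
    logger.info(
        "analysis table: %d person-months, %d subjects, %d cities "
        "(%d with tracer ambient-origin exposure)",
        len(out), out["subject_id"].nunique(), out["city_id"].nunique(),
        int(out["x_ambient_origin"].notna().sum()),
    )
    return out
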