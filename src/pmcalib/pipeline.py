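"""End-to-end orchestration of the calibration analysis.

A run reproduces the analysis sequence on one dataset (simulated or loaded
from CSV files): build the person-month table, then for each cell of the
2 x 2 grid (true exposure: ambient-origin / total personal; surrogate:
nearest monitor / outdoor-home prediction) fit the pooled mixed model,
test gamma1 = 1, test season effect modification, test between-city
heterogeneity, and - when heterogeneity is present - run the step-wise
city-covariate selection with leave-one-city-out validation; when it is
absent, re-fit without the city random slope (Model 2) and report that
coefficient as final.

Outputs: a summary table shaped like the published calibration-factor table,
per-city CSVs, forest plots and a machine-readable run log (seed, config
hash, convergence and person-month counts per cell).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exposure import ExposureConfig, build_analysis_table
from .heterogeneity import city_specific_fits, heterogeneity_test, loocv, stepwise_select
from .inference import season_modification, subgroup_interaction
from .model import CalibrationModel, ModelSpec
from .simulate import PanelDataset, SimulationConfig, read_fixture, simulate_panel

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run"]

ALL_CELLS = (
    ("ambient_origin", "monitor"),
    ("ambient_origin", "model_pred"),
    ("total_personal", "monitor"),
    ("total_personal", "model_pred"),
)
DEFAULT_CANDIDATES = ("vehicles_per_unit", "heating_degree_days", "residents_per_unit")


@dataclass
class RunConfig:
    """Configuration of one end-to-end analysis run."""

    mode: str = "synthetic"  # synthetic | files
    sim: SimulationConfig | None = None  # synthetic mode
    input_dir: str | None = None  # files mode: directory with the CSV contract
    cells: tuple = ALL_CELLS
    candidates: tuple = DEFAULT_CANDIDATES
    matched_days: bool = False
    restrict_to_tracer_subset: bool = False
    subgroup_flags: tuple = ()
    alpha: float = 0.05
    seed: int = 0
    min_days_per_month: int = 1
    max_monitor_distance_mi: float = 30.0
    out_dir: str | None = None

    def __post_init__(self):
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"mode must be 'synthetic' or 'files', got {self.mode!r}")
        if self.mode == "files" and not self.input_dir:
            raise ValueError("files mode requires input_dir")
        if self.mode == "synthetic" and self.sim is None:
            self.sim = SimulationConfig(seed=self.seed)

    # -- YAML round trip ---------------------------------------------------

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        sim = d.pop("sim", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in d.items()})
        if sim is not None:
            for k in ("age_range", "time_indoors_range"):
                if k in sim and isinstance(sim[k], list):
                    sim[k] = tuple(sim[k])
            cfg.sim = SimulationConfig(**sim)
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config: RunConfig
    table: pd.DataFrame
    cells: dict  # (true_exposure, surrogate) -> dict
    log: dict

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for (x, z), cell in self.cells.items():
            row = {"true_exposure": x, "surrogate": z}
            if "error" in cell:
                row["error"] = cell["error"]
            else:
                row.update(
                    n_person_months=cell["n_person_months"],
                    n_subjects=cell["n_subjects"],
                    n_cities=cell["n_cities"],
                    gamma1=cell["model1"]["gamma1"],
                    ci_low=cell["model1"]["ci95_gamma1"][0],
                    ci_high=cell["model1"]["ci95_gamma1"][1],
                    p_gamma1_eq_1=cell["model1"]["p_gamma1_eq_1"],
                    season_interaction_p=cell["season"]["interaction_p"],
                    heterogeneity_p=cell["heterogeneity"]["p_value"],
                    final_gamma1=cell["final"]["gamma1"],
                    final_ci_low=cell["final"]["ci95"][0],
                    final_ci_high=cell["final"]["ci95"][1],
                    final_model=cell["final"]["model"],
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def summary_text(self) -> str:
        df = self.summary_frame()
        lines = ["Season-adjusted calibration coefficients", "=" * 60]
        for _, r in df.iterrows():
            lines.append(f"{r['true_exposure']} ~ {r['surrogate']}:")
            if "error" in df.columns and isinstance(r.get("error"), str) \
                    and r.get("error"):
                lines.append(f"  failed: {r['error']}")
                continue
            lines.append(
                f"  gamma1 = {r['gamma1']:.2f} ({r['ci_low']:.2f}, {r['ci_high']:.2f})"
                f"   p[gamma1=1] = {r['p_gamma1_eq_1']:.3g}"
            )
            lines.append(
                f"  between-city heterogeneity p = {r['heterogeneity_p']:.4f}"
                f"   season-interaction p = {r['season_interaction_p']:.3g}"
            )
            lines.append(
                f"  final ({r['final_model']}): {r['final_gamma1']:.2f} "
                f"({r['final_ci_low']:.2f}, {r['final_ci_high']:.2f})"
            )
        return "\n".join(lines)


def _load_dataset(config: RunConfig) -> PanelDataset:
    if config.mode == "synthetic":
        sim = config.sim
        return simulate_panel(sim)
    return read_fixture(config.input_dir)


def _analyse_cell(table, covariates, x, z, config: RunConfig) -> dict:
    spec = ModelSpec(kind="model1", true_exposure=x, surrogate=z)
    xcol = {"ambient_origin": "x_ambient_origin",
            "total_personal": "x_total_personal"}[x]
    zcol = {"monitor": "z_monitor", "model_pred": "z_model_pred"}[z]
    sub = table.dropna(subset=[xcol, zcol])
    if config.restrict_to_tracer_subset and x == "total_personal":
        sub = sub[sub["x_ambient_origin"].notna()]
        assert sub.index.isin(table.index).all()
    cell: dict = {
        "n_person_months": int(len(sub)),
        "n_subjects": int(sub["subject_id"].nunique()),
        "n_cities": int(sub["city_id"].nunique()),
    }
    m1 = CalibrationModel(sub, spec).fit()
    cell["model1"] = m1.to_dict()
    cell["converged"] = m1.converged
    season = season_modification(sub, spec, alpha=config.alpha)
    cell["season"] = season.to_dict()
    if config.subgroup_flags:
        flags = [f for f in config.subgroup_flags
                 if f in sub.columns and sub[f].nunique() > 1]
        cell["subgroups"] = {
            k: v.to_dict()
            for k, v in subgroup_interaction(sub, spec, flags=flags,
                                             alpha=config.alpha).items()
        } if flags else {}
    het = heterogeneity_test(sub, spec)
    cell["heterogeneity"] = het.to_dict()
    per_city = city_specific_fits(sub, spec, alpha=config.alpha)
    cell["per_city"] = per_city
    if het.p_value < config.alpha:
        step = stepwise_select(sub, spec, config.candidates, covariates,
                               alpha=config.alpha)
        cell["stepwise"] = {
            "selected": step.selected,
            "interaction_p": step.interaction_p,
            "residual_heterogeneity_p": step.residual_heterogeneity.p_value,
            "dropped": step.dropped,
        }
        if cell["n_cities"] >= 3:
            cv = loocv(sub, spec, config.candidates, covariates,
                       alpha=config.alpha)
            cell["loocv"] = cv.to_dict()
        # heterogeneity present: Model 1 remains the pooled coefficient
        cell["final"] = {
            "model": "model1",
            "gamma1": m1.gamma1,
            "ci95": list(m1.conf_int_gamma1(config.alpha)),
        }
    else:
        m2 = het.fit_reduced
        cell["model2"] = m2.to_dict()
        cell["final"] = {
            "model": "model2",
            "gamma1": m2.gamma1,
            "ci95": list(m2.conf_int_gamma1(config.alpha)),
        }
    return cell


def run(config: RunConfig) -> RunReport:
    """Execute the full analysis; optionally write a report bundle.

    Any cell failure is recorded under that cell with the stage name; the
    other cells and partial outputs are preserved.
    """
    dataset = _load_dataset(config)
    expo = ExposureConfig(
        min_days_per_month=config.min_days_per_month,
        max_monitor_distance_mi=config.max_monitor_distance_mi,
        matched_days=config.matched_days,
    )
    table = build_analysis_table(dataset.daily, dataset.monitors,
                                 dataset.model_pred, expo)
    cells = {}
    for x, z in config.cells:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cells[(x, z)] = _analyse_cell(
                    table, dataset.city_covariates, x, z, config)
        except Exception as exc:  # keep the other cells alive
            logger.exception("cell (%s, %s) failed", x, z)
            cells[(x, z)] = {"error": f"{type(exc).__name__}: {exc}"}

    log = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "pmcalib_version": __version__,
        "n_person_months": int(len(table)),
        "n_subjects": int(table["subject_id"].nunique()),
        "n_cities": int(table["city_id"].nunique()),
        "cells": {
            f"{x}~{z}": {
                k: cells[(x, z)].get(k)
                for k in ("n_person_months", "converged", "error")
                if k in cells[(x, z)]
            }
            for (x, z) in cells
        },
    }
    report = RunReport(config, table, cells, log)
    if config.out_dir:
        _write_bundle(report, dataset)
    return report


def _write_bundle(report: RunReport, dataset: PanelDataset) -> None:
    from .plots import forest_plot

    out = Path(report.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.summary_frame().to_csv(out / "summary.csv", index=False)
    (out / "summary.txt").write_text(report.summary_text() + "\n")
    (out / "run_log.json").write_text(json.dumps(report.log, indent=1))
    (out / "config.yaml").write_text(report.config.to_yaml())
    for (x, z), cell in report.cells.items():
        if "per_city" not in cell:
            continue
        stem = f"{x}__{z}"
        per_city = cell["per_city"]
        per_city.to_csv(out / f"per_city_{stem}.csv", index=False)
        if per_city["ok"].any():
            ax = forest_plot(per_city, pooled=cell["model1"]["gamma1"],
                             title=f"{x} ~ {z}")
            ax.figure.savefig(out / f"forest_{stem}.png", dpi=150)
            import matplotlib.pyplot as plt

            plt.close(ax.figure)
        serialisable = {k: v for k, v in cell.items() if k != "per_city"}
        (out / f"cell_{stem}.json").write_text(json.dumps(serialisable, indent=1))
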