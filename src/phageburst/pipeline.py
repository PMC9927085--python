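"""End-to-end workflow: wells → summaries → model fit → noise decomposition.

The stages mirror the analysis of a limiting-dilution burst-size experiment:
per-lysis-time distribution summaries (with bootstrap CIs and outlier
trimming), the sigmoid fit to the mean curve, a noise-decomposition table
comparing the observed CV² profile with the first-order predictions under
each pure-heterogeneity hypothesis, and optionally a CV-equality comparison
between two groups of wells.  Outputs are deterministic given the config:
rerunning reproduces every file byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from . import __version__
from .burst_model import BurstParams, sensitivities
from .model_fitting import FitResult, fit_burst_model, predict_curve
from .singlecell_stats import (read_well_csv, samples_from_wells,
                               summarize_by_lysis_time, write_summary_csv)
from .synthetic_data import (AssayConfig, ConfigError, simulate_experiment,
                             write_assay_csv, write_truth_json)
from .cv_tests import cv_test_asymptotic, cv_test_mslr

__all__ = ["PipelineConfig", "run_pipeline", "noise_decomposition",
           "cv2_trend"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for a full analysis run.

    Exactly one of ``input_csv`` (a well-level table) or ``simulate`` (an
    :class:`AssayConfig`) must be given.  ``correction`` rescales reported
    means (e.g. 1/0.81 to undo the chloroform viability loss); CV-based
    quantities are unaffected.
    """

    outdir: Union[str, Path]
    input_csv: Optional[Union[str, Path]] = None
    simulate: Optional[AssayConfig] = None
    use_trimmed: bool = False  # feed trimmed stats to the fit/noise stages
    n_boot: int = 1000
    level: float = 0.95
    boot_seed: int = 0
    fit_n_starts: int = 10
    fit_seed: int = 0
    weighting: str = "none"  # or "inverse_variance"
    correction: float = 1.0
    compare_csvs: Optional[tuple[str, str]] = None  # two well-level CSVs

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.simulate is None):
            raise ConfigError(
                "exactly one of input_csv or a simulate block is required"
            )
        if self.weighting not in ("none", "inverse_variance"):
            raise ConfigError("weighting must be 'none' or 'inverse_variance'")
        if self.correction <= 0:
            raise ConfigError("correction must be positive")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("simulate") is not None:
            d["simulate"] = AssayConfig.from_dict(d["simulate"])
        if d.get("compare_csvs") is not None:
            d["compare_csvs"] = tuple(d["compare_csvs"])
        return cls(**d)


def cv2_trend(summary: pd.DataFrame, use_trimmed: bool = False,
              n_boot: int = 1000, seed: int = 0) -> dict:
    """OLS slope of CV² against mean burst size, with two 95% CIs.

    A flat profile (CI covering 0) is the signature of capacity-dominated
    heterogeneity; a negative slope with CV² falling toward 0 points to
    timing-parameter heterogeneity.  Reported descriptively: the t-based OLS
    CI and a seeded pairs-bootstrap percentile CI.
    """
    ycol = "cv2_trimmed" if use_trimmed else "cv2"
    xcol = "mean_trimmed" if use_trimmed else "mean"
    d = summary.dropna(subset=[xcol, ycol])
    x, y = d[xcol].to_numpy(float), d[ycol].to_numpy(float)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    lo, hi = res.conf_int()[1]
    rng = np.random.default_rng(seed)
    slopes = []
    n = len(x)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(x[idx])) < 2:
            continue
        slopes.append(np.polyfit(x[idx], y[idx], 1)[0])
    blo, bhi = np.percentile(slopes, [2.5, 97.5]) if slopes else (np.nan, np.nan)
    return {
        "slope": float(res.params[1]),
        "intercept": float(res.params[0]),
        "ci_lo": float(lo), "ci_hi": float(hi),
        "boot_ci_lo": float(blo), "boot_ci_hi": float(bhi),
        "n_points": int(n),
    }


def noise_decomposition(summary: pd.DataFrame, params: BurstParams,
                        use_trimmed: bool = False) -> pd.DataFrame:
    """Observed CV² per time point against pure-heterogeneity predictions.

    For each hypothesis (all heterogeneity in k_max, in LT50, or in r) the
    single free CV² is set by least squares of the observed CV² profile on
    the squared sensitivity profile; the fitted prediction is tabulated
    alongside the observations.  The k_max column is necessarily flat, the
    LT50/r columns decay toward 0 at long lysis times.
    """
    ycol = "cv2_trimmed" if use_trimmed else "cv2"
    d = summary.dropna(subset=[ycol]).copy()
    lts = d["lysis_time_min"].to_numpy(float)
    obs = d[ycol].to_numpy(float)
    usable = lts > params.delay
    s = sensitivities(lts[usable], params)
    s2 = {"kmax": np.asarray(s.s_kmax) ** 2, "LT50": np.asarray(s.s_lt50) ** 2,
          "r": np.asarray(s.s_r) ** 2}
    out = d[["lysis_time_min", "mean", ycol]].rename(columns={ycol: "cv2_obs"})
    for name, prof in s2.items():
        cv2_x = float(prof @ obs[usable] / (prof @ prof))  # 1-param LS
        col = np.full(len(d), np.nan)
        col[usable] = cv2_x * prof
        out[f"pred_cv2_{name}_only"] = col
        out.attrs[f"fitted_cv2_{name}"] = cv2_x
    return out


def _fit_points(summary: pd.DataFrame, weighting: str, use_trimmed: bool):
    mcol = "mean_trimmed" if use_trimmed else "mean"
    pts = summary[["lysis_time_min", mcol]].to_numpy(float)
    if weighting == "inverse_variance":
        se = summary["sd"].to_numpy(float) / np.sqrt(summary["n"].to_numpy(float))
        w = np.where(se > 0, 1.0 / se, 0.0)
        return pts, w
    return pts, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle into ``config.outdir``.

    Returns a dict of output paths: wells/truth (when simulated), the
    per-lysis-time summary CSV, fit JSON + predicted-curve CSV, the
    noise-decomposition CSV + trend JSON, the optional CV-test table, and a
    run log echoing versions, seeds and config.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    if config.simulate is not None:
        wells, truth = simulate_experiment(config.simulate)
        outputs["wells_csv"] = outdir / "wells.csv"
        write_assay_csv(wells, outputs["wells_csv"])
        outputs["truth_json"] = outdir / "truth.json"
        write_truth_json(truth, outputs["truth_json"])
        wells = wells[["plate", "well", "lysis_time_min", "plaque_count"]]
    else:
        wells = read_well_csv(config.input_csv)

    summary = summarize_by_lysis_time(wells, n_boot=config.n_boot,
                                      level=config.level, seed=config.boot_seed,
                                      correction=config.correction)
    if summary.empty:
        raise ConfigError("no occupied wells: nothing to analyse")
    outputs["summary_csv"] = outdir / "summary.csv"
    write_summary_csv(summary, outputs["summary_csv"])

    fit_json: dict = {"note": "fit skipped: fewer than 5 distinct lysis times"}
    fit: Optional[FitResult] = None
    if summary["lysis_time_min"].nunique() >= 5:
        pts, w = _fit_points(summary, config.weighting, config.use_trimmed)
        fit = fit_burst_model(pts, weights=w, n_starts=config.fit_n_starts,
                              seed=config.fit_seed)
        fit_json = fit.to_dict()
        grid = np.linspace(0.0, float(summary["lysis_time_min"].max()) * 1.1, 200)
        curve = pd.DataFrame({"lysis_time_min": grid,
                              "predicted_mean": predict_curve(fit, grid)})
        outputs["curve_csv"] = outdir / "curve.csv"
        curve.to_csv(outputs["curve_csv"], index=False, float_format="%.10g")
    outputs["fit_json"] = outdir / "fit.json"
    with open(outputs["fit_json"], "w") as fh:
        json.dump(fit_json, fh, indent=2, sort_keys=True)

    trend = cv2_trend(summary, use_trimmed=config.use_trimmed,
                      n_boot=config.n_boot, seed=config.boot_seed)
    if fit is not None:
        decomp = noise_decomposition(summary, fit.params,
                                     use_trimmed=config.use_trimmed)
        outputs["decomposition_csv"] = outdir / "decomposition.csv"
        decomp.to_csv(outputs["decomposition_csv"], index=False,
                      float_format="%.10g")
        trend["fitted_pure_cv2"] = {k.split("_")[-1]: v
                                    for k, v in decomp.attrs.items()}
    outputs["trend_json"] = outdir / "trend.json"
    with open(outputs["trend_json"], "w") as fh:
        json.dump(trend, fh, indent=2, sort_keys=True)

    if config.compare_csvs is not None:
        rows = []
        gs = []
        for p in config.compare_csvs:
            w = read_well_csv(p)
            counts = w.loc[w["plaque_count"] > 0, "plaque_count"].to_numpy(float)
            gs.append(counts)
        for res in (cv_test_asymptotic(gs), cv_test_mslr(gs)):
            rows.append({"method": res.method, "statistic": res.statistic,
                         "df": res.df, "p_value": res.p_value})
        outputs["cvtest_csv"] = outdir / "cvtest.csv"
        pd.DataFrame(rows).to_csv(outputs["cvtest_csv"], index=False,
                                  float_format="%.10g")

    outputs["log_txt"] = outdir / "run_log.txt"
    with open(outputs["log_txt"], "w") as fh:
        fh.write(f"phageburst {__version__}\n")
        fh.write(f"numpy {np.__version__}, pandas {pd.__version__}, "
                 f"statsmodels {sm.__version__}\n")
        fh.write(f"boot_seed={config.boot_seed} fit_seed={config.fit_seed} "
                 f"n_boot={config.n_boot} level={config.level}\n")
        cfg_echo = {k: (str(v) if isinstance(v, Path) else v)
                    for k, v in vars(config).items()}
        if config.simulate is not None:
            cfg_echo["simulate"] = config.simulate.to_dict()
        cfg_echo["outdir"] = str(config.outdir)
        if config.input_csv is not None:
            cfg_echo["input_csv"] = str(config.input_csv)
        fh.write(yaml.safe_dump(cfg_echo, sort_keys=True))
    return {k: str(v) for k, v in outputs.items()}
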