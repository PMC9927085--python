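"""Synthetic limiting-dilution burst-size assays.

Generates complete 96-well-plate experiments with the statistical structure
the analysis assumes: Poisson well occupancy at a configurable mean (0.25 to
0.61 cells/well in the study design), per-cell burst sizes from the sigmoidal
model with lognormal cell-to-cell parameter heterogeneity, right-skew from
multi-cell wells, optional per-cell natural lysis timing, and binomial virion
viability thinning (chloroform handling costs ~19% of virions, i.e. survival
0.81).

Every run is fully determined by the config seed.  The analysis-facing CSV
carries only what a real experiment records (plate, well, lysis time, plaque
count); the latent per-well cell count is kept in a separate column/truth
sidecar so conditioning biases can be quantified but never leak into the
analysis path.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .burst_model import BurstParams, NoiseBudget, burst_size, cv2_burst

__all__ = ["AssayConfig", "WellRecord", "ConfigError", "draw_cell_params",
           "simulate_well", "simulate_experiment", "write_assay_csv",
           "write_truth_json"]

_DEFAULT_PARAMS = BurstParams(k_max=1430.0, lt50=119.0, r=0.027, delay=25.0)
# Capacity-only heterogeneity at CV 0.4: the regime the constant observed
# burst-size noise points to.
_DEFAULT_BUDGET = NoiseBudget(cv2_kmax=0.16, cv2_lt50=0.0, cv2_r=0.0)

_WELL_IDS = [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)]


class ConfigError(ValueError):
    """Invalid assay configuration."""


@dataclass(frozen=True)
class AssayConfig:
    """Full specification of a synthetic limiting-dilution assay.

    Attributes
    ----------
    lysis_times:
        Chemical lysis times (minutes), one batch of plates per time point.
    n_plates_per_timepoint, n_wells, mean_occupancy:
        Plate geometry and Poisson mean cells/well.
    true_params:
        Population-mean model parameters.
    heterogeneity:
        Cell-to-cell CV² of k_max, LT50 and r (D is fixed at its mean).
    parameter_family:
        "lognormal" (default) or "gamma"; moment-matched to mean and CV.
    lysis_mode:
        "chemical": every cell lyses exactly at the plate's nominal time.
        "natural": each cell draws its own lysis time from a normal
        distribution truncated at D (mean ``natural_lysis_mean``, CV
        ``natural_lysis_cv``); the nominal time only labels the batch.
    viability:
        Per-virion survival probability through lysis and plating
        (binomial thinning); 0.81 reflects the ~19% handling loss.
    """

    lysis_times: tuple[float, ...] = (40, 60, 80, 100, 120, 140, 160, 180,
                                      200, 220, 240)
    n_plates_per_timepoint: int = 5
    n_wells: int = 96
    mean_occupancy: float = 0.25
    true_params: BurstParams = _DEFAULT_PARAMS
    heterogeneity: NoiseBudget = _DEFAULT_BUDGET
    parameter_family: str = "lognormal"
    lysis_mode: str = "chemical"
    natural_lysis_mean: float = 40.89
    natural_lysis_cv: float = 0.05
    viability: float = 0.81
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lysis_times or any(t <= 0 for t in self.lysis_times):
            raise ConfigError("lysis_times must be a nonempty tuple of positive minutes")
        if self.n_plates_per_timepoint < 1:
            raise ConfigError("n_plates_per_timepoint must be >= 1")
        if self.n_wells < 1:
            raise ConfigError("n_wells must be >= 1")
        if self.mean_occupancy < 0:
            raise ConfigError("mean_occupancy must be >= 0")
        if not 0 < self.viability <= 1:
            raise ConfigError("viability must be in (0, 1]")
        if self.parameter_family not in ("lognormal", "gamma"):
            raise ConfigError("parameter_family must be 'lognormal' or 'gamma'")
        if self.lysis_mode not in ("chemical", "natural"):
            raise ConfigError("lysis_mode must be 'chemical' or 'natural'")
        if self.natural_lysis_cv < 0 or self.natural_lysis_mean <= 0:
            raise ConfigError("natural lysis mean must be > 0 and CV >= 0")
        object.__setattr__(self, "lysis_times",
                           tuple(float(t) for t in self.lysis_times))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_params"] = self.true_params.to_dict()
        d["heterogeneity"] = self.heterogeneity.to_dict()
        d["lysis_times"] = list(self.lysis_times)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AssayConfig":
        d = dict(d)
        if "true_params" in d:
            d["true_params"] = BurstParams.from_dict(d["true_params"])
        if "heterogeneity" in d:
            d["heterogeneity"] = NoiseBudget.from_dict(d["heterogeneity"])
        if "lysis_times" in d:
            d["lysis_times"] = tuple(d["lysis_times"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "AssayConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass(frozen=True)
class WellRecord:
    plate: str
    well: str
    lysis_time: float
    n_cells: int  # latent truth; excluded from the analysis-facing CSV
    plaque_count: int


def _draw_positive(mean: float, cv2: float, family: str, size: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Moment-matched positive draws with the requested mean and CV²."""
    if cv2 == 0:
        return np.full(size, mean)
    if family == "lognormal":
        sigma2 = np.log1p(cv2)
        mu = np.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), size=size)
    shape = 1.0 / cv2
    return rng.gamma(shape, mean * cv2, size=size)


def draw_cell_params(config: AssayConfig, rng: np.random.Generator,
                     size: int = 1) -> list[BurstParams]:
    """Per-cell model parameters: independent moment-matched draws.

    k_max, LT50 and r are drawn independently with the configured means and
    CV²s; D stays at its mean.  Zero-CV² components return the mean exactly.
    LT50 draws are floored just above D to stay in the valid domain (only
    relevant at heterogeneity levels far beyond the study's).
    """
    tp, h = config.true_params, config.heterogeneity
    kmax = _draw_positive(tp.k_max, h.cv2_kmax, config.parameter_family, size, rng)
    lt50 = _draw_positive(tp.lt50, h.cv2_lt50, config.parameter_family, size, rng)
    r = _draw_positive(tp.r, h.cv2_r, config.parameter_family, size, rng)
    lt50 = np.maximum(lt50, tp.delay + 1e-6)
    return [BurstParams(k_max=float(kmax[i]), lt50=float(lt50[i]),
                        r=float(r[i]), delay=tp.delay) for i in range(size)]


def _cell_lysis_times(config: AssayConfig, nominal: float, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    if config.lysis_mode == "chemical" or config.natural_lysis_cv == 0:
        t = nominal if config.lysis_mode == "chemical" else config.natural_lysis_mean
        return np.full(n, float(t))
    mean, sd = config.natural_lysis_mean, config.natural_lysis_cv * config.natural_lysis_mean
    a = (config.true_params.delay - mean) / sd  # truncate at D
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n,
                               random_state=rng)


def simulate_well(config: AssayConfig, lysis_time: float,
                  rng: np.random.Generator, plate: str = "p1",
                  well: str = "A1") -> WellRecord:
    """One well: Poisson cell count, per-cell bursts, viability thinning.

    Each cell receives its own parameter draw and (in natural mode) its own
    lysis time; per-cell bursts are rounded to whole virions, summed, and
    thinned binomially by the viability.
    """
    n_cells = int(rng.poisson(config.mean_occupancy))
    total = 0
    if n_cells > 0:
        cells = draw_cell_params(config, rng, size=n_cells)
        lts = _cell_lysis_times(config, lysis_time, n_cells, rng)
        for p, lt in zip(cells, lts):
            total += int(round(burst_size(float(lt), p)))
    plaques = int(rng.binomial(total, config.viability)) if total else 0
    return WellRecord(plate=plate, well=well, lysis_time=float(lysis_time),
                      n_cells=n_cells, plaque_count=plaques)


def simulate_experiment(config: AssayConfig) -> tuple[pd.DataFrame, dict]:
    """All plates and time points; returns (well table, truth sidecar).

    The table has columns plate, well, lysis_time_min, plaque_count and a
    latent n_cells column (dropped by :func:`write_assay_csv`).  The truth
    sidecar records the config and, per time point, the model-true mean burst
    and first-order CV² so downstream estimates can be checked against truth.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for lt in config.lysis_times:
        for ip in range(config.n_plates_per_timepoint):
            plate = f"lt{lt:g}-p{ip + 1}"
            for iw in range(config.n_wells):
                well = _WELL_IDS[iw % 96] if config.n_wells <= 96 else f"w{iw + 1}"
                rec = simulate_well(config, lt, rng, plate=plate, well=well)
                rows.append(rec)
    df = pd.DataFrame([{
        "plate": r.plate, "well": r.well, "lysis_time_min": r.lysis_time,
        "plaque_count": r.plaque_count, "n_cells": r.n_cells,
    } for r in rows])

    truth_per_lt = {}
    tp = config.true_params
    for lt in config.lysis_times:
        nominal = (config.natural_lysis_mean if config.lysis_mode == "natural"
                   else lt)
        truth_per_lt[f"{lt:g}"] = {
            "true_mean_burst": float(burst_size(nominal, tp)) * config.viability,
            "true_cv2_first_order": (float(cv2_burst(nominal, tp,
                                                     config.heterogeneity))
                                     if nominal > tp.delay else None),
        }
    truth = {"config": config.to_dict(), "per_lysis_time": truth_per_lt}
    return df, truth


def write_assay_csv(wells: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write the analysis-facing CSV (latent truth columns stripped)."""
    cols = ["plate", "well", "lysis_time_min", "plaque_count"]
    wells[cols].to_csv(path, index=False)


def write_truth_json(truth: dict, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
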