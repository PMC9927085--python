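"""Per-lysis-time burst-size distribution summaries.

A burst sample is the set of plaque counts from the occupied wells of a
limiting-dilution plate lysed at one time point (typically ~100 cells).  This
module computes the sample moments used throughout the analysis — mean, SD,
CV, CV² and moment skewness — plus one-pass outlier trimming at twice the
observed mean (which removes most multi-cell wells) and seeded percentile
bootstrap confidence intervals.

Conventions: the SD (and hence CV) uses the n-1 denominator; the skewness is
the biased moment estimator g1 = m3 / m2^{3/2} with 1/n central moments, the
definition used by the R ``moments`` package.  Wells with zero plaques are
indistinguishable from empty wells in this assay and are treated as empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BurstSample",
    "SummaryStats",
    "TrimResult",
    "DegenerateSampleError",
    "MalformedTableError",
    "summarize",
    "trim_outliers",
    "bootstrap_ci",
    "read_well_csv",
    "samples_from_wells",
    "summarize_by_lysis_time",
    "write_summary_csv",
]

WELL_COLUMNS = ("plate", "well", "lysis_time_min", "plaque_count")


class DegenerateSampleError(ValueError):
    """Sample too small (n < 2) or zero-mean: summary statistics undefined."""


class MalformedTableError(ValueError):
    """Well-level table fails validation (missing columns, bad counts)."""


@dataclass(frozen=True)
class BurstSample:
    """Plaque counts from occupied wells lysed at a single lysis time."""

    lysis_time: float
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1:
            raise MalformedTableError("counts must be one-dimensional")
        if counts.size and (np.any(~np.isfinite(counts)) or np.any(counts < 0)):
            raise MalformedTableError("plaque counts must be finite and >= 0")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.size)


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sd: float
    cv: float
    cv2: float
    skewness: float


@dataclass(frozen=True)
class TrimResult:
    """Outcome of one-pass trimming at twice the untrimmed mean."""

    kept: BurstSample
    n_removed: int
    mean_before: float
    mean_after: float
    skew_before: float
    skew_after: float

    @property
    def removed_fraction(self) -> float:
        n0 = self.kept.n + self.n_removed
        return self.n_removed / n0 if n0 else 0.0

    @property
    def mean_reduction(self) -> float:
        """Relative drop of the mean caused by trimming."""
        return 1.0 - self.mean_after / self.mean_before


def _moment_skewness(x: np.ndarray) -> float:
    # g1 = m3/m2^1.5 with 1/n moments; constant samples -> 0 by convention
    m2 = np.mean((x - x.mean()) ** 2)
    if m2 == 0:
        return 0.0
    return float(stats.skew(x, bias=True))


def summarize(sample: BurstSample) -> SummaryStats:
    """Mean, SD (n-1), CV, CV² and moment skewness of a burst sample."""
    x = sample.counts
    if x.size < 2:
        raise DegenerateSampleError(f"need n >= 2 observations, got {x.size}")
    mean = float(x.mean())
    if mean <= 0:
        raise DegenerateSampleError("sample mean must be positive for CV")
    sd = float(x.std(ddof=1))
    cv = sd / mean
    return SummaryStats(n=x.size, mean=mean, sd=sd, cv=cv, cv2=cv * cv,
                        skewness=_moment_skewness(x))


def trim_outliers(sample: BurstSample) -> TrimResult:
    """Drop values strictly greater than twice the untrimmed mean, once.

    Multi-cell wells sit in the far right tail of the single-cell burst
    distribution; this single pass removes most of them while keeping ties
    at exactly twice the mean.
    """
    x = sample.counts
    if x.size < 2:
        raise DegenerateSampleError(f"need n >= 2 observations, got {x.size}")
    mean_before = float(x.mean())
    keep = x <= 2.0 * mean_before
    kept = BurstSample(sample.lysis_time, x[keep])
    return TrimResult(
        kept=kept,
        n_removed=int((~keep).sum()),
        mean_before=mean_before,
        mean_after=float(kept.counts.mean()) if kept.n else float("nan"),
        skew_before=_moment_skewness(x),
        skew_after=_moment_skewness(kept.counts) if kept.n else float("nan"),
    )


_STATISTICS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "mean": lambda m: m.mean(axis=1),
    "cv": lambda m: m.std(axis=1, ddof=1) / m.mean(axis=1),
    "cv2": lambda m: (m.std(axis=1, ddof=1) / m.mean(axis=1)) ** 2,
}


def bootstrap_ci(
    sample: BurstSample,
    statistic: str = "mean",
    n_boot: int = 1000,
    level: float = 0.95,
    seed: Union[int, np.random.Generator, None] = None,
) -> tuple[float, float]:
    """Seeded percentile bootstrap interval for mean, CV or CV².

    Resamples the wells with replacement ``n_boot`` times and returns the
    (1-level)/2 and (1+level)/2 percentiles of the resampled statistic.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"statistic must be one of {sorted(_STATISTICS)}")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    summarize(sample)  # reuse degeneracy checks
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, sample.n, size=(n_boot, sample.n))
    with np.errstate(divide="ignore", invalid="ignore"):
        reps = _STATISTICS[statistic](sample.counts[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(reps, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def read_well_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a well-level plaque-count table.

    Expects columns ``plate, well, lysis_time_min, plaque_count``.  Fails
    fast with row-level diagnostics on missing columns, non-numeric or
    negative counts, and missing lysis times.
    """
    df = pd.read_csv(path)
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedTableError(f"{path}: missing required columns {missing}")
    counts = pd.to_numeric(df["plaque_count"], errors="coerce")
    bad = df.index[counts.isna() | (counts < 0)]
    if len(bad):
        raise MalformedTableError(
            f"{path}: non-numeric or negative plaque_count at rows "
            f"{list(bad[:10])}{'...' if len(bad) > 10 else ''}"
        )
    lts = pd.to_numeric(df["lysis_time_min"], errors="coerce")
    bad = df.index[lts.isna() | (lts < 0)]
    if len(bad):
        raise MalformedTableError(
            f"{path}: non-numeric or negative lysis_time_min at rows {list(bad[:10])}"
        )
    df = df.copy()
    df["plaque_count"] = counts.astype(int)
    df["lysis_time_min"] = lts.astype(float)
    return df


def samples_from_wells(wells: pd.DataFrame) -> list[BurstSample]:
    """Group occupied wells (plaque_count > 0) into per-lysis-time samples."""
    out = []
    for lt, grp in wells.groupby("lysis_time_min", sort=True):
        counts = grp.loc[grp["plaque_count"] > 0, "plaque_count"].to_numpy(float)
        if counts.size:
            out.append(BurstSample(float(lt), counts))
    return out


def summarize_by_lysis_time(
    wells: pd.DataFrame,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: Union[int, None] = 0,
    correction: float = 1.0,
) -> pd.DataFrame:
    """Per-lysis-time summary table, untrimmed and trimmed side by side.

    ``correction`` multiplies the reported means/SDs (e.g. 1/0.81 to undo a
    19% virion viability loss from chloroform handling); CV, CV² and skewness
    are scale-free and unaffected.  Bootstrap CIs are for the untrimmed mean.
    """
    if correction <= 0:
        raise ValueError("correction factor must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for sample in samples_from_wells(wells):
        s = summarize(sample)
        ci_lo, ci_hi = bootstrap_ci(sample, "mean", n_boot=n_boot, level=level,
                                    seed=rng)
        trim = trim_outliers(sample)
        ts = summarize(trim.kept) if trim.kept.n >= 2 else None
        rows.append({
            "lysis_time_min": sample.lysis_time,
            "n": s.n,
            "mean": s.mean * correction,
            "sd": s.sd * correction,
            "cv": s.cv,
            "cv2": s.cv2,
            "skewness": s.skewness,
            "ci_lo": ci_lo * correction,
            "ci_hi": ci_hi * correction,
            "n_trimmed": trim.kept.n,
            "n_removed": trim.n_removed,
            "mean_trimmed": (ts.mean * correction) if ts else float("nan"),
            "cv_trimmed": ts.cv if ts else float("nan"),
            "cv2_trimmed": ts.cv2 if ts else float("nan"),
            "skewness_trimmed": ts.skewness if ts else float("nan"),
        })
    return pd.DataFrame(rows)


def write_summary_csv(summary: pd.DataFrame, path: Union[str, Path]) -> None:
    summary.to_csv(path, index=False, float_format="%.10g")
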