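"""Nonlinear least-squares fitting of the burst-size/lysis-time model.

Fits the four-parameter sigmoid to (lysis time, mean burst size) points.  The
valid domain (k_max > 0, r > 0, D >= 0, LT50 > D) is enforced by fitting in
the transformed coordinates (ln k_max, ln(LT50 - D), ln r, D).  Because the
LT <= D clause puts a kink in the objective along D, each start is refined
with Nelder-Mead before a derivative-based least-squares polish, and several
seeded starts are tried (multi-start), keeping the best.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize

from .burst_model import BurstParams, ParameterDomainError, burst_size

__all__ = ["FitResult", "IdentifiabilityError", "fit_burst_model",
           "predict_curve", "bootstrap_param_cis"]


class IdentifiabilityError(ValueError):
    """Too few (or too few distinct) points to identify the four parameters."""


@dataclass(frozen=True)
class FitResult:
    params: BurstParams
    residual_sum_of_squares: float
    n_points: int
    converged: bool
    param_cis: Optional[dict] = None

    def to_dict(self) -> dict:
        d = {
            "params": self.params.to_dict(),
            "residual_sum_of_squares": self.residual_sum_of_squares,
            "n_points": self.n_points,
            "converged": self.converged,
        }
        if self.param_cis is not None:
            d["param_cis"] = self.param_cis
        return d


def _theta_to_params(theta: np.ndarray) -> BurstParams:
    lk, llt, lr, d = theta
    d = max(float(d), 0.0)
    return BurstParams(k_max=float(np.exp(lk)), lt50=d + float(np.exp(llt)),
                       r=float(np.exp(lr)), delay=d)


def _params_to_theta(p: BurstParams) -> np.ndarray:
    return np.array([np.log(p.k_max), np.log(p.lt50 - p.delay), np.log(p.r),
                     p.delay])


def auto_init(lt: np.ndarray, y: np.ndarray) -> BurstParams:
    """Heuristic starting parameters from the data.

    k_max from the largest observed mean; LT50 from the first crossing of
    half-maximum; D from the earliest lysis time with a positive burst minus
    one sampling interval (floored at 0); r from the log-linear slope of the
    rising phase.
    """
    k0 = float(y.max())
    order = np.argsort(lt)
    lt_s, y_s = lt[order], y[order]
    half = k0 / 2.0
    above = np.nonzero(y_s >= half)[0]
    lt50_0 = float(lt_s[above[0]]) if above.size else float(lt_s[-1])
    pos = np.nonzero(y_s > 0)[0]
    step = float(np.median(np.diff(lt_s))) if lt_s.size > 1 else 10.0
    d0 = max(0.0, (float(lt_s[pos[0]]) if pos.size else float(lt_s[0])) - step)
    rising = (y_s > 0.05 * k0) & (y_s < 0.8 * k0) & (y_s > 0)
    if rising.sum() >= 2:
        slope = np.polyfit(lt_s[rising], np.log(y_s[rising]), 1)[0]
        r0 = float(slope) if slope > 0 else 0.02
    else:
        r0 = 0.02
    if lt50_0 <= d0 + 1e-6:
        lt50_0 = d0 + max(step, 1.0)
    return BurstParams(k_max=k0, lt50=lt50_0, r=r0, delay=d0)


def fit_burst_model(
    points: Union[Sequence[tuple[float, float]], np.ndarray],
    init: Optional[BurstParams] = None,
    weights: Optional[np.ndarray] = None,
    n_starts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Least-squares fit of the sigmoid to (lysis time, mean burst) points.

    Parameters
    ----------
    points:
        Sequence of ``(lysis_time_min, mean_burst)`` pairs; at least 5, with
        lysis times spanning the rise and the plateau.
    init:
        Optional explicit starting parameters; defaults to :func:`auto_init`.
    weights:
        Optional per-point weights applied to the residuals (e.g. inverse
        standard errors); default is unweighted.
    n_starts:
        Number of seeded multi-starts (jittered around the init).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (lysis_time, mean)")
    lt, y = pts[:, 0], pts[:, 1]
    if len(np.unique(lt)) < 5:
        raise IdentifiabilityError(
            "need >= 5 distinct lysis times to identify 4 parameters"
        )
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)
    if w.shape != y.shape or np.any(w < 0):
        raise ValueError("weights must be nonnegative and match points")

    def residuals(theta: np.ndarray) -> np.ndarray:
        try:
            p = _theta_to_params(theta)
        except ParameterDomainError:
            return np.full_like(y, 1e9)
        return w * (burst_size(lt, p) - y)

    def sse(theta: np.ndarray) -> float:
        r = residuals(theta)
        return float(r @ r)

    p0 = init if init is not None else auto_init(lt, y)
    theta0 = _params_to_theta(p0)
    rng = np.random.default_rng(seed)
    lb = np.array([-np.inf, -np.inf, -np.inf, 0.0])
    ub = np.full(4, np.inf)

    best_theta, best_sse, converged = None, np.inf, False
    for start in range(max(1, n_starts)):
        t0 = theta0.copy()
        if start > 0:  # jitter the transformed coordinates
            t0[:3] = t0[:3] + rng.normal(0.0, 0.3, size=3)
            t0[3] = max(0.0, t0[3] * np.exp(rng.normal(0.0, 0.3)))
        nm = optimize.minimize(sse, t0, method="Nelder-Mead",
                               options={"xatol": 1e-10, "fatol": 1e-12,
                                        "maxiter": 4000, "maxfev": 4000})
        t1 = np.clip(nm.x, lb, ub)
        try:
            ls = optimize.least_squares(residuals, t1, bounds=(lb, ub),
                                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
            cand, cand_sse, ok = ls.x, float(2 * ls.cost), bool(ls.success)
        except Exception:
            cand, cand_sse, ok = t1, sse(t1), False
        if cand_sse < best_sse:
            best_theta, best_sse, converged = cand, cand_sse, ok or bool(nm.success)

    return FitResult(params=_theta_to_params(best_theta),
                     residual_sum_of_squares=best_sse,
                     n_points=len(y), converged=converged)


def predict_curve(result: FitResult, grid: np.ndarray) -> np.ndarray:
    """Model means on a lysis-time grid (for plots and residual diagnostics)."""
    return np.asarray(burst_size(np.asarray(grid, float), result.params))


def bootstrap_param_cis(
    samples: Sequence,
    n_boot: int = 200,
    level: float = 0.95,
    seed: int = 0,
    n_starts: int = 4,
) -> dict:
    """Percentile CIs for the fitted parameters by resampling cells.

    Resamples wells with replacement within each lysis time, recomputes the
    per-time means and refits.  This uncertainty attaches to the fit as an
    add-on diagnostic; the primary fit itself is on the observed means.

    ``samples`` is a sequence of :class:`~phageburst.singlecell_stats.BurstSample`.
    """
    rng = np.random.default_rng(seed)
    draws = {k: [] for k in ("k_max", "LT50", "r", "D")}
    for _ in range(n_boot):
        pts = []
        for s in samples:
            counts = s.counts[rng.integers(0, s.n, size=s.n)]
            pts.append((s.lysis_time, float(counts.mean())))
        try:
            fr = fit_burst_model(pts, n_starts=n_starts,
                                 seed=int(rng.integers(2**31)))
        except (IdentifiabilityError, ParameterDomainError):
            continue
        for k, v in fr.params.to_dict().items():
            draws[k].append(v)
    alpha = (1 - level) / 2
    return {
        k: [float(np.percentile(v, 100 * alpha)),
            float(np.percentile(v, 100 * (1 - alpha)))]
        for k, v in draws.items() if v
    }
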