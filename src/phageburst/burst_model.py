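"""Sigmoidal burst-size/lysis-time model and first-order noise propagation.

The mean number of virions released by a single induced lysogen lysed at time
``LT`` (minutes after induction) is modelled phenomenologically as

    BS(LT) = k_max * (e^{r(LT-D)} - 1) / (e^{r(LT50-D)} + e^{r(LT-D)} - 2)

for ``LT > D`` and ``BS = 0`` otherwise.  ``k_max`` (PFU/cell) is the cellular
capacity — the asymptotic maximum burst size; ``LT50`` is the lysis time at
which the burst reaches half of ``k_max``; ``r`` (per minute) is the
exponential accumulation rate of intracellular progeny; ``D`` (minutes) is the
eclipse-like delay before the first virions appear.

Cell-to-cell variability propagates to the burst size, to first order, through
the dimensionless log-sensitivities (elasticities) S_x = (x/f)·∂f/∂x:

    CV²_BS = S_kmax² · CV²_kmax + S_LT50² · CV²_LT50 + S_r² · CV²_r

S_kmax ≡ 1 at every lysis time, so heterogeneity in cellular capacity alone
produces a burst-size CV² that is constant in lysis time, whereas |S_LT50| and
|S_r| decay to 0 at long lysis times, so heterogeneity in timing parameters
alone produces a CV² that vanishes as the mean burst saturates.  This contrast
is the discriminating prediction the package is organised around.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "BurstParams",
    "NoiseBudget",
    "SensitivityProfile",
    "ParameterDomainError",
    "UndefinedSensitivityError",
    "burst_size",
    "sensitivities",
    "cv2_burst",
]

ArrayLike = Union[float, np.ndarray]

# exp() overflows double precision near 709; switch to the scaled asymptotic
# form safely below that
_EXP_GUARD = 700.0


class ParameterDomainError(ValueError):
    """Model parameters violate the domain k_max>0, r>0, D>=0, LT50>D."""


class UndefinedSensitivityError(ValueError):
    """Log-sensitivities requested at a lysis time where the burst size is 0."""


@dataclass(frozen=True)
class BurstParams:
    """Parameters of the sigmoidal burst-size model.

    Attributes
    ----------
    k_max:
        Maximum (saturating) burst size, PFU/cell. Must be positive.
    lt50:
        Lysis time at which the mean burst equals ``k_max / 2``, minutes.
        Must exceed ``delay``.
    r:
        Exponential progeny accumulation rate, per minute. Must be positive.
    delay:
        Time delay ``D`` before phage accumulation starts, minutes. The burst
        size is identically zero for lysis times at or below the delay.
    """

    k_max: float
    lt50: float
    r: float
    delay: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k_max) and self.k_max > 0):
            raise ParameterDomainError(f"k_max must be positive, got {self.k_max}")
        if not (np.isfinite(self.r) and self.r > 0):
            raise ParameterDomainError(f"r must be positive, got {self.r}")
        if not (np.isfinite(self.delay) and self.delay >= 0):
            raise ParameterDomainError(f"D must be >= 0, got {self.delay}")
        if not (np.isfinite(self.lt50) and self.lt50 > self.delay):
            raise ParameterDomainError(
                f"LT50 must exceed D, got LT50={self.lt50}, D={self.delay}"
            )

    def to_dict(self) -> dict:
        """Flat JSON-ready mapping with the conventional key names."""
        return {"k_max": self.k_max, "LT50": self.lt50, "r": self.r, "D": self.delay}

    @classmethod
    def from_dict(cls, d: dict) -> "BurstParams":
        return cls(k_max=float(d["k_max"]), lt50=float(d["LT50"]),
                   r=float(d["r"]), delay=float(d["D"]))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "BurstParams":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class NoiseBudget:
    """Cell-to-cell CV² of each model parameter (the noise-propagation inputs).

    ``D`` carries no budget term: to first order its fluctuations enter only
    through the timing parameters, and the decomposition used here follows the
    three-parameter expansion in ``k_max``, ``LT50`` and ``r``.
    """

    cv2_kmax: float = 0.0
    cv2_lt50: float = 0.0
    cv2_r: float = 0.0

    def __post_init__(self) -> None:
        for name in ("cv2_kmax", "cv2_lt50", "cv2_r"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ParameterDomainError(f"{name} must be finite and >= 0, got {v}")

    def to_dict(self) -> dict:
        return {"cv2_kmax": self.cv2_kmax, "cv2_LT50": self.cv2_lt50,
                "cv2_r": self.cv2_r}

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseBudget":
        return cls(cv2_kmax=float(d.get("cv2_kmax", 0.0)),
                   cv2_lt50=float(d.get("cv2_LT50", 0.0)),
                   cv2_r=float(d.get("cv2_r", 0.0)))


@dataclass(frozen=True)
class SensitivityProfile:
    """Dimensionless log-sensitivities of the burst size at one lysis time."""

    lysis_time: ArrayLike
    s_kmax: ArrayLike
    s_lt50: ArrayLike
    s_r: ArrayLike


def _exponents(lysis_time: np.ndarray, params: BurstParams) -> tuple[np.ndarray, float]:
    a = params.r * (lysis_time - params.delay)
    b = params.r * (params.lt50 - params.delay)
    return a, float(b)


def burst_size(lysis_time: ArrayLike, params: BurstParams) -> ArrayLike:
    """Mean burst size (PFU/cell) at the given lysis time(s).

    Evaluates the sigmoidal model; returns 0 for lysis times at or below the
    delay ``D``.  Monotone nondecreasing in lysis time and bounded above by
    ``k_max``.  Large exponents are handled by rescaling with the dominant
    exponential so that no overflow or NaN can occur for valid parameters.

    Parameters
    ----------
    lysis_time:
        Scalar or array of lysis times, minutes; must be >= 0.
    params:
        Model parameters.
    """
    lt = np.asarray(lysis_time, dtype=float)
    scalar = lt.ndim == 0
    lt = np.atleast_1d(lt)
    if np.any(~np.isfinite(lt)) or np.any(lt < 0):
        raise ParameterDomainError("lysis_time must be finite and >= 0")

    a, b = _exponents(lt, params)
    out = np.zeros_like(lt)
    pos = a > 0
    if np.any(pos):
        ap = a[pos]
        m = np.maximum(ap, b)
        safe = m <= _EXP_GUARD
        vals = np.empty_like(ap)
        if np.any(safe):
            # e^a + e^b - 2 == expm1(a) + expm1(b): accurate near a -> 0+
            ea = np.expm1(ap[safe])
            vals[safe] = params.k_max * ea / (ea + np.expm1(b))
        if np.any(~safe):
            # divide through by e^m, m = max(a, b); all exponents <= 0
            au, mu = ap[~safe], m[~safe]
            num = np.exp(au - mu) - np.exp(-mu)
            den = np.exp(au - mu) + np.exp(b - mu) - 2.0 * np.exp(-mu)
            vals[~safe] = params.k_max * num / den
        # guard against 1-ulp division overshoot at saturation
        out[pos] = np.minimum(vals, params.k_max)
    return float(out[0]) if scalar else out


def sensitivities(lysis_time: ArrayLike, params: BurstParams) -> SensitivityProfile:
    """Log-sensitivities S_x = (x/f)·∂f/∂x of the burst size f at ``lysis_time``.

    Computed analytically.  With a = r(LT-D) and b = r(LT50-D):

        S_kmax = 1                                  (identically)
        S_LT50 = -r·LT50 · e^b / (e^a + e^b - 2)
        S_r    = a / (1 - e^{-a}) - (a·e^a + b·e^b) / (e^a + e^b - 2)

    Only defined for lysis times strictly above the delay (positive burst).
    """
    lt = np.asarray(lysis_time, dtype=float)
    scalar = lt.ndim == 0
    lt = np.atleast_1d(lt)
    if np.any(lt <= params.delay):
        raise UndefinedSensitivityError(
            "sensitivities undefined at lysis_time <= D (burst size is 0)"
        )
    a, b = _exponents(lt, params)
    m = np.maximum(a, b)
    safe = m <= _EXP_GUARD

    s_lt50 = np.empty_like(a)
    term2 = np.empty_like(a)
    if np.any(safe):
        asel = a[safe]
        den = np.expm1(asel) + np.expm1(b)
        ea, eb = np.exp(asel), np.exp(b)
        s_lt50[safe] = -params.r * params.lt50 * eb / den
        term2[safe] = (asel * ea + b * eb) / den
    if np.any(~safe):
        asel, msel = a[~safe], m[~safe]
        ea, eb, e0 = np.exp(asel - msel), np.exp(b - msel), np.exp(-msel)
        den = ea + eb - 2.0 * e0
        s_lt50[~safe] = -params.r * params.lt50 * eb / den
        term2[~safe] = (asel * ea + b * eb) / den
    # a·e^a/(e^a-1) = a/(1 - e^{-a}), stable for any a > 0
    s_r = a / (-np.expm1(-a)) - term2
    s_kmax = np.ones_like(a)
    if scalar:
        return SensitivityProfile(float(lt[0]), 1.0, float(s_lt50[0]), float(s_r[0]))
    return SensitivityProfile(lt, s_kmax, s_lt50, s_r)


def cv2_burst(lysis_time: ArrayLike, params: BurstParams,
              budget: NoiseBudget) -> ArrayLike:
    """First-order burst-size CV² from per-parameter cell-to-cell CV²s.

    Returns ``S_kmax²·cv2_kmax + S_LT50²·cv2_lt50 + S_r²·cv2_r`` with the
    sensitivities evaluated at ``lysis_time``.  Parameters are treated as
    independent across cells (no covariance terms).
    """
    s = sensitivities(lysis_time, params)
    out = (np.asarray(s.s_kmax) ** 2 * budget.cv2_kmax
           + np.asarray(s.s_lt50) ** 2 * budget.cv2_lt50
           + np.asarray(s.s_r) ** 2 * budget.cv2_r)
    return float(out) if np.ndim(lysis_time) == 0 else out
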