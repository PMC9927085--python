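"""Burst-size model: anchors, limits, sensitivities, CV² propagation."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phageburst import (BurstParams, NoiseBudget, ParameterDomainError,
                        UndefinedSensitivityError, burst_size, cv2_burst,
                        sensitivities)

from conftest import FITTED, random_params


def exact_burst(lt: float, p: BurstParams) -> float:
    """Unguarded closed-form oracle (only valid away from overflow)."""
    if lt <= p.delay:
        return 0.0
    num = math.exp(p.r * (lt - p.delay)) - 1.0
    den = math.exp(p.r * (p.lt50 - p.delay)) + math.exp(p.r * (lt - p.delay)) - 2.0
    return p.k_max * num / den


class TestBurstSize:
    def test_zero_at_and_below_delay(self, fitted_params):
        assert burst_size(fitted_params.delay, fitted_params) == 0.0
        assert burst_size(0.0, fitted_params) == 0.0
        assert burst_size(10.0, fitted_params) == 0.0

    def test_half_maximum_at_lt50(self, rng):
        for _ in range(100):
            p = random_params(rng)
            assert burst_size(p.lt50, p) == pytest.approx(p.k_max / 2, rel=1e-12)

    def test_matches_closed_form_oracle(self, fitted_params):
        # high-precision evaluation of the closed form at LT = 180 min
        assert burst_size(180.0, fitted_params) == pytest.approx(
            exact_burst(180.0, fitted_params), rel=1e-12)
        assert burst_size(180.0, fitted_params) == pytest.approx(1.2e3, rel=0.02)

    def test_monotone_and_bounded(self, rng):
        for _ in range(50):
            p = random_params(rng)
            lts = np.linspace(p.delay + 1e-3, p.lt50 + 80.0 / p.r, 200)
            vals = burst_size(lts, p)
            assert np.all(np.diff(vals) >= -1e-9 * p.k_max)
            assert np.all(vals <= p.k_max)
            # strictly below k_max wherever the gap is representable
            near = lts < p.lt50 + 30.0 / p.r
            assert np.all(vals[near] < p.k_max)

    def test_saturates_to_k_max(self, rng):
        for _ in range(20):
            p = random_params(rng)
            lt = p.lt50 + 50.0 / p.r
            assert burst_size(lt, p) == pytest.approx(p.k_max, rel=0.01)

    def test_overflow_guard_returns_finite(self, fitted_params):
        # r*(LT-D) far beyond double-precision exp range
        big = BurstParams(k_max=1000.0, lt50=900.0, r=2.0, delay=10.0)
        for lt in (5e2, 1e4, 1e8):
            v = burst_size(lt, big)
            assert np.isfinite(v) and 0.0 <= v <= big.k_max * (1 + 1e-12)
        assert burst_size(1e4, big) == pytest.approx(big.k_max, rel=1e-9)
        assert burst_size(1e8, big) == pytest.approx(big.k_max, rel=1e-9)

    def test_invalid_inputs_raise(self, fitted_params):
        with pytest.raises(ParameterDomainError):
            BurstParams(k_max=-1, lt50=100, r=0.02, delay=10)
        with pytest.raises(ParameterDomainError):
            BurstParams(k_max=10, lt50=100, r=-0.1, delay=10)
        with pytest.raises(ParameterDomainError):
            BurstParams(k_max=10, lt50=5, r=0.1, delay=10)  # LT50 <= D
        with pytest.raises(ParameterDomainError):
            burst_size(-5.0, fitted_params)


class TestSensitivities:
    def test_capacity_sensitivity_is_exactly_one(self, rng):
        for _ in range(100):
            p = random_params(rng)
            lt = p.delay + rng.uniform(1.0, 3.0 / p.r)
            assert sensitivities(lt, p).s_kmax == 1.0

    def test_matches_finite_difference_oracle(self, rng):
        # central differences of log f in log x, step 1e-5
        h = 1e-5
        for _ in range(100):
            p = random_params(rng)
            lt = p.delay + rng.uniform(5.0, p.lt50 - p.delay + 3.0 / p.r)
            s = sensitivities(lt, p)

            def logf(k=p.k_max, l50=p.lt50, r=p.r):
                return math.log(burst_size(lt, BurstParams(k, l50, r, p.delay)))

            fd_lt50 = (logf(l50=p.lt50 * math.exp(h))
                       - logf(l50=p.lt50 * math.exp(-h))) / (2 * h)
            fd_r = (logf(r=p.r * math.exp(h))
                    - logf(r=p.r * math.exp(-h))) / (2 * h)
            assert s.s_lt50 == pytest.approx(fd_lt50, rel=1e-6, abs=1e-8)
            assert s.s_r == pytest.approx(fd_r, rel=1e-6, abs=1e-8)

    def test_timing_sensitivities_vanish_at_long_lysis_times(self, fitted_params):
        s = sensitivities(10 * fitted_params.lt50, fitted_params)
        assert abs(s.s_lt50) < 0.01
        assert abs(s.s_r) < 0.01

    def test_undefined_at_or_below_delay(self, fitted_params):
        with pytest.raises(UndefinedSensitivityError):
            sensitivities(fitted_params.delay, fitted_params)
        with pytest.raises(UndefinedSensitivityError):
            sensitivities(1.0, fitted_params)


class TestCv2Burst:
    def test_capacity_only_budget_is_flat_in_lysis_time(self, fitted_params):
        budget = NoiseBudget(cv2_kmax=0.2)
        lts = np.linspace(60.0, 400.0, 50)
        vals = np.array([cv2_burst(lt, fitted_params, budget) for lt in lts])
        assert vals.max() - vals.min() < 1e-12
        assert vals[0] == pytest.approx(0.2)

    def test_zero_budget_gives_zero(self, fitted_params):
        assert cv2_burst(100.0, fitted_params, NoiseBudget()) == 0.0

    def test_timing_budget_decays_to_zero(self, fitted_params):
        budget = NoiseBudget(cv2_lt50=0.1)
        lts = np.arange(60.0, 401.0, 20.0)
        vals = np.array([cv2_burst(lt, fitted_params, budget) for lt in lts])
        # equals S_LT50^2 * 0.1 exactly, and decreases toward 0 past the knee
        for lt, v in zip(lts, vals):
            assert v == pytest.approx(
                sensitivities(lt, fitted_params).s_lt50 ** 2 * 0.1, rel=1e-12)
        assert np.all(np.diff(vals[lts > fitted_params.lt50]) < 0)
        assert vals[-1] < 1e-4


@given(scale=st.floats(min_value=0.1, max_value=10.0))
@settings(deadline=None, max_examples=30, derandomize=True)
def test_burst_size_scales_linearly_in_capacity(scale):
    p = FITTED
    q = BurstParams(p.k_max * scale, p.lt50, p.r, p.delay)
    assert burst_size(150.0, q) == pytest.approx(scale * burst_size(150.0, p),
                                                 rel=1e-12)


def test_serialization_round_trip():
    p = FITTED
    assert BurstParams.from_json(p.to_json()) == p
    assert set(p.to_dict()) == {"k_max", "LT50", "r", "D"}
    b = NoiseBudget(0.16, 0.01, 0.002)
    assert NoiseBudget.from_dict(b.to_dict()) == b
    flat = {**p.to_dict(), **b.to_dict()}
    assert set(flat) == {"k_max", "LT50", "r", "D",
                         "cv2_kmax", "cv2_LT50", "cv2_r"}
    assert BurstParams.from_dict(flat) == p
    assert NoiseBudget.from_dict(flat) == b
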