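"""Burst-sample summaries, trimming, bootstrap intervals, CSV round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phageburst import (BurstSample, DegenerateSampleError,
                        MalformedTableError, bootstrap_ci, read_well_csv,
                        samples_from_wells, summarize, summarize_by_lysis_time,
                        trim_outliers)


class TestSummarize:
    def test_hand_computed_moments(self):
        # counts {1,2,3,4,10}: mean 4, m2 = 10, m3 = 36 (1/n moments),
        # g1 = 36 / 10^1.5; SD uses n-1.
        s = summarize(BurstSample(60.0, np.array([1.0, 2, 3, 4, 10])))
        assert s.mean == 4.0
        assert s.sd == pytest.approx(np.sqrt(12.5))
        assert s.cv == pytest.approx(np.sqrt(12.5) / 4.0)
        assert s.cv2 == pytest.approx(12.5 / 16.0)
        assert s.skewness == pytest.approx(36.0 / 10.0**1.5)
        assert s.skewness > 0

    def test_constant_sample(self):
        s = summarize(BurstSample(60.0, np.array([7.0, 7, 7])))
        assert s.sd == 0.0 and s.cv == 0.0 and s.skewness == 0.0

    def test_degenerate_samples_raise(self):
        with pytest.raises(DegenerateSampleError):
            summarize(BurstSample(60.0, np.array([5.0])))
        with pytest.raises(DegenerateSampleError):
            summarize(BurstSample(60.0, np.array([0.0, 0.0])))

    @given(a=st.floats(min_value=0.01, max_value=100.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_scale_consistency(self, a):
        x = np.array([1.0, 2, 3, 4, 10])
        s0 = summarize(BurstSample(60.0, x))
        s1 = summarize(BurstSample(60.0, a * x))
        assert s1.mean == pytest.approx(a * s0.mean, rel=1e-12)
        assert s1.sd == pytest.approx(a * s0.sd, rel=1e-12)
        assert s1.cv == pytest.approx(s0.cv, rel=1e-12)
        assert s1.skewness == pytest.approx(s0.skewness, rel=1e-9)


class TestTrim:
    def test_forced_removal(self):
        tr = trim_outliers(BurstSample(60.0, np.array([10.0, 10, 10, 50])))
        assert tr.n_removed == 1
        assert list(tr.kept.counts) == [10.0, 10.0, 10.0]
        assert tr.mean_before == 20.0 and tr.mean_after == 10.0
        assert tr.removed_fraction == 0.25

    def test_identity_when_no_outliers(self):
        x = np.array([5.0, 6, 7, 8])
        tr = trim_outliers(BurstSample(60.0, x))
        assert tr.n_removed == 0
        assert np.array_equal(tr.kept.counts, x)
        assert tr.mean_reduction == 0.0

    def test_ties_at_twice_mean_are_kept(self):
        x = np.array([2.0, 2, 2, 6])  # mean 3; 6 == 2*mean exactly, kept
        assert trim_outliers(BurstSample(60.0, x)).n_removed == 0
        y = np.array([2.0, 2, 2, 6.01])  # strictly greater: removed
        assert trim_outliers(BurstSample(60.0, y)).n_removed == 1

    def test_trim_reduces_skew_and_mean_on_right_skewed_samples(self, rng):
        for _ in range(20):
            x = rng.lognormal(4.0, 0.6, size=120)
            tr = trim_outliers(BurstSample(60.0, x))
            assert tr.mean_after <= tr.mean_before
            if tr.n_removed:
                assert tr.skew_after <= tr.skew_before


class TestBootstrap:
    def test_constant_sample_degenerate_interval(self):
        lo, hi = bootstrap_ci(BurstSample(60.0, np.full(10, 3.0)), "mean",
                              seed=0)
        assert lo == hi == 3.0

    def test_seeded_determinism(self):
        x = np.array([3.0, 8, 1, 7, 5, 9, 2, 2, 4, 6])
        a = bootstrap_ci(BurstSample(60.0, x), "cv", seed=42)
        b = bootstrap_ci(BurstSample(60.0, x), "cv", seed=42)
        assert a == b

    def test_endpoints_are_percentiles_of_resampled_statistic(self):
        # brute-force re-implementation on a tiny sample, same seed
        x = np.array([1.0, 4, 2, 9, 5])
        n_boot = 200
        lo, hi = bootstrap_ci(BurstSample(60.0, x), "mean", n_boot=n_boot,
                              level=0.9, seed=7)
        rng = np.random.default_rng(7)
        idx = rng.integers(0, 5, size=(n_boot, 5))
        reps = x[idx].mean(axis=1)
        assert (lo, hi) == pytest.approx(tuple(np.percentile(reps, [5, 95])))

    def test_mean_interval_coverage(self):
        # lognormal n=100: the 95% percentile interval should cover the true
        # mean in roughly 95% of repetitions
        mu, sigma = 4.0, 0.5
        true_mean = np.exp(mu + sigma**2 / 2)
        rng = np.random.default_rng(2026)
        hits = 0
        reps = 500
        for _ in range(reps):
            x = rng.lognormal(mu, sigma, size=100)
            lo, hi = bootstrap_ci(BurstSample(60.0, x), "mean", n_boot=500,
                                  seed=rng)
            hits += lo <= true_mean <= hi
        assert 0.91 <= hits / reps <= 0.98


class TestWellCsv:
    def _write(self, tmp_path, text):
        p = tmp_path / "wells.csv"
        p.write_text(text)
        return p

    def test_round_trip_and_grouping(self, tmp_path):
        txt = ("plate,well,lysis_time_min,plaque_count\n"
               "p1,A1,60,5\np1,A2,60,0\np1,A3,90,7\np1,A4,90,9\np1,A5,90,0\n")
        df = read_well_csv(self._write(tmp_path, txt))
        samples = samples_from_wells(df)
        assert [s.lysis_time for s in samples] == [60.0, 90.0]
        assert list(samples[0].counts) == [5.0]       # zero wells are empty
        assert list(samples[1].counts) == [7.0, 9.0]

    def test_missing_column_fails_fast(self, tmp_path):
        p = self._write(tmp_path, "plate,well,plaque_count\np1,A1,5\n")
        with pytest.raises(MalformedTableError, match="lysis_time_min"):
            read_well_csv(p)

    def test_negative_count_reports_row(self, tmp_path):
        p = self._write(tmp_path,
                        "plate,well,lysis_time_min,plaque_count\n"
                        "p1,A1,60,5\np1,A2,60,-3\n")
        with pytest.raises(MalformedTableError, match="rows"):
            read_well_csv(p)

    def test_summary_table_columns_and_correction(self, tmp_path):
        txt = "plate,well,lysis_time_min,plaque_count\n" + "\n".join(
            f"p1,A{i},60,{c}" for i, c in enumerate([8, 12, 9, 11, 40], 1))
        df = read_well_csv(self._write(tmp_path, txt))
        base = summarize_by_lysis_time(df, n_boot=50, seed=0)
        corr = summarize_by_lysis_time(df, n_boot=50, seed=0,
                                       correction=1 / 0.81)
        assert {"lysis_time_min", "n", "mean", "cv", "cv2", "skewness",
                "ci_lo", "ci_hi", "n_trimmed", "mean_trimmed",
                "cv2_trimmed"}.issubset(base.columns)
        assert corr["mean"].iloc[0] == pytest.approx(
            base["mean"].iloc[0] / 0.81)
        assert corr["cv2"].iloc[0] == base["cv2"].iloc[0]  # scale-free
        assert base["n_removed"].iloc[0] == 1  # the 40 exceeds 2x mean
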