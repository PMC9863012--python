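"""Circadian metrics (M10/L5/RA/ADAT, IS, IV), day thirds, and the
Savitzky-Golay boundary features, checked against closed forms and an
exhaustive window-search oracle."""

import numpy as np
import pytest

from actipheno.rhythm import (day_matrix, interdaily_stability,
                              interdaily_stability_hourly,
                              intradaily_variability,
                              intradaily_variability_hourly,
                              nonparametric_profile, savgol_boundary_features,
                              thirds_and_daily)
from actipheno.types import DegenerateInputError


def brute_force_m10_l5(days):
    """Exhaustive circular window search, per day."""
    m10s, l5s = [], []
    for day in days:
        ext = np.concatenate([day, day])
        w10 = [ext[i:i + 600].mean() for i in range(1440)]
        w5 = [ext[i:i + 300].mean() for i in range(1440)]
        m10s.append(max(w10))
        l5s.append(min(w5))
    return float(np.mean(m10s)), float(np.mean(l5s))


class TestNonparametricProfile:
    def test_block_profile(self, make_epochs):
        day = np.zeros(1440)
        day[8 * 60:18 * 60] = 100.0
        e = make_epochs(np.tile(day, 2))
        out = nonparametric_profile(e)
        assert out["M10"] == pytest.approx(100.0)
        assert out["L5"] == pytest.approx(0.0)
        assert out["RA"] == pytest.approx(1.0)
        assert out["ADAT"] == pytest.approx(100.0 * 600)

    def test_constant_profile(self, make_epochs):
        out = nonparametric_profile(make_epochs(np.full(1440, 50.0)))
        assert out["M10"] == out["L5"] == pytest.approx(50.0)
        assert out["RA"] == pytest.approx(0.0)
        assert out["ADAT"] == pytest.approx(50.0 * 1440)

    def test_matches_exhaustive_window_search(self, make_epochs):
        rng = np.random.default_rng(11)
        counts = rng.uniform(0, 80, 2 * 1440)
        e = make_epochs(counts)
        out = nonparametric_profile(e)
        m10, l5 = brute_force_m10_l5(day_matrix(e))
        assert out["M10"] == pytest.approx(m10, abs=1e-9)
        assert out["L5"] == pytest.approx(l5, abs=1e-9)

    def test_needs_a_full_day(self, make_epochs):
        with pytest.raises(DegenerateInputError):
            nonparametric_profile(make_epochs(np.ones(100)))


class TestInterdailyStability:
    def test_periodic_pattern_gives_one(self, make_epochs):
        rng = np.random.default_rng(0)
        pattern = np.repeat(rng.uniform(0, 10, 24), 60)  # hourly-constant day
        e = make_epochs(np.tile(pattern, 5))
        assert interdaily_stability(e) == pytest.approx(1.0)

    def test_iid_noise_mean_is_inverse_days(self):
        rng = np.random.default_rng(1)
        vals = [interdaily_stability_hourly(rng.standard_normal((10, 24)))
                for _ in range(1000)]
        assert np.mean(vals) == pytest.approx(0.1, abs=0.01)

    def test_constant_series_errors(self, make_epochs):
        with pytest.raises(DegenerateInputError):
            interdaily_stability(make_epochs(np.full(3 * 1440, 4.0)))

    def test_affine_invariance_and_range(self):
        rng = np.random.default_rng(2)
        h = rng.uniform(0, 5, (4, 24))
        v = interdaily_stability_hourly(h)
        assert 0 <= v <= 1
        assert interdaily_stability_hourly(3.5 * h + 11) == pytest.approx(v)


class TestIntradailyVariability:
    def test_iid_noise_mean_is_two(self):
        rng = np.random.default_rng(3)
        vals = [intradaily_variability_hourly(rng.standard_normal(240))
                for _ in range(1000)]
        assert np.mean(vals) == pytest.approx(2.0, abs=0.05)

    def test_cosine_closed_form(self):
        t = np.arange(240)
        x = np.cos(2 * np.pi * t / 24)
        expected = 2 * (1 - np.cos(2 * np.pi / 24))
        assert intradaily_variability_hourly(x) == pytest.approx(expected, rel=0.02)

    def test_constant_errors(self, make_epochs):
        with pytest.raises(DegenerateInputError):
            intradaily_variability(make_epochs(np.full(3 * 1440, 1.0)))

    def test_affine_invariance_and_time_reversal(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 7, 96)
        v = intradaily_variability_hourly(x)
        assert intradaily_variability_hourly(2 * x + 5) == pytest.approx(v)
        assert intradaily_variability_hourly(x[::-1]) == pytest.approx(v)


class TestThirdsAndDaily:
    def test_constant(self, make_epochs):
        out = thirds_and_daily(make_epochs(np.full(1440, 10.0)))
        assert out["1_thrd"] == out["2_thrd"] == out["3_thrd"] == 10.0
        assert out["daily_activity_mean"] == 10.0
        assert out["daily_activity_stdev"] == 0.0

    def test_evening_block(self, make_epochs):
        day = np.zeros(1440)
        day[16 * 60:] = 30.0
        out = thirds_and_daily(make_epochs(day))
        assert out["3_thrd"] == pytest.approx(30.0)
        assert out["1_thrd"] == out["2_thrd"] == 0.0
        assert out["daily_activity_mean"] == pytest.approx(10.0)

    def test_averages_over_days(self, make_epochs):
        counts = np.concatenate([np.full(1440, 10.0), np.full(1440, 20.0)])
        out = thirds_and_daily(make_epochs(counts))
        assert out["1_thrd"] == out["2_thrd"] == out["3_thrd"] == pytest.approx(15.0)


class TestBoundaryFeatures:
    def test_sinusoid_envelopes(self, make_epochs):
        t = np.arange(3 * 1440)
        mesor, amp, period = 50.0, 10.0, 480.0
        e = make_epochs(mesor + amp * np.sin(2 * np.pi * t / period))
        out = savgol_boundary_features(e)
        assert out["avg_ceiling_value"] == pytest.approx(mesor + amp, rel=0.05)
        assert out["avg_floor_value"] == pytest.approx(mesor - amp, rel=0.05)
        assert out["avg_ceiling_floor_diff"] == pytest.approx(2 * amp, rel=0.05)
        assert out["e_v_avg_value"] == pytest.approx(mesor, rel=0.02)

    def test_single_hump_and_trough_gives_zero_upper_std(self, make_epochs):
        # one up-down-up sweep: exactly one interior maximum and one minimum
        x = np.arange(4000.0)
        phase = -np.pi / 2 + 2.5 * np.pi * x / 4000.0
        out = savgol_boundary_features(make_epochs(25.0 + 10.0 * np.sin(phase)))
        assert out["std_upper"] == 0.0
        assert out["floor_sum_values"] == out["avg_floor_value"]

    def test_constant_series_errors(self, make_epochs):
        with pytest.raises(DegenerateInputError):
            savgol_boundary_features(make_epochs(np.full(2000, 5.0)))
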