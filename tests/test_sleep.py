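"""Sleep-period detection, nocturnal peak extraction and the peak-family,
zero-ratio and fragmentation features."""

import numpy as np
import pytest

from actipheno.config import RunConfig
from actipheno.sleep import (collect_peaks, detect_sleep_periods, extract_peaks,
                             fragmentation_index, peak_family_features,
                             sleep_length_minutes, split_peaks, zero_ratio)
from actipheno.types import DegenerateInputError, Peak, SleepPeriod

from conftest import NOON


def night_series(make_epochs, quiet_slices, n_minutes=1440, loud=60.0, quiet=1.0):
    """A day of epochs starting at noon, quiet in the given minute slices."""
    c = np.full(n_minutes, loud)
    for sl in quiet_slices:
        c[sl] = quiet
    return make_epochs(c, start=NOON)


class TestSleepDetection:
    def test_single_night_window(self, make_epochs):
        # 23:00-07:00 quiet; the series starts at noon, so minutes 660..1140
        e = night_series(make_epochs, [slice(660, 1140)])
        periods = detect_sleep_periods(e)
        assert len(periods) == 1
        assert periods[0].duration_minutes() == 480

    def test_always_active_has_no_sleep(self, make_epochs):
        e = night_series(make_epochs, [])
        assert detect_sleep_periods(e) == []

    def test_longest_qualifying_run_wins(self, make_epochs):
        # two quiet runs in one night: 300 min and 420 min
        e = night_series(make_epochs, [slice(420, 720), slice(780, 1200)])
        periods = detect_sleep_periods(e)
        assert len(periods) == 1
        assert periods[0].duration_minutes() == 420

    def test_short_rest_is_not_sleep(self, make_epochs):
        e = night_series(make_epochs, [slice(700, 760)])  # only 60 min quiet
        assert detect_sleep_periods(e) == []

    def test_one_period_per_night(self, make_epochs):
        day = np.full(1440, 60.0)
        day[660:1140] = 0.0
        e = make_epochs(np.tile(day, 3), start=NOON)
        periods = detect_sleep_periods(e)
        assert [p.night_index for p in periods] == sorted(
            {p.night_index for p in periods})
        assert all(a.end_epoch <= b.start_epoch
                   for a, b in zip(periods, periods[1:]))


class TestPeaks:
    def test_hand_traced_example(self):
        peaks = extract_peaks(np.array([0, 3, 4, 0, 0, 1, 0], dtype=float))
        assert len(peaks) == 2
        first, second = peaks
        assert (first.width, first.height, first.gap_to_next) == (2, 4.0, 2)
        assert (second.width, second.height, second.gap_to_next) == (1, 1.0, None)

    def test_all_zero_gives_no_peaks(self):
        assert extract_peaks(np.zeros(50)) == []

    def test_partition_of_sleep_epochs(self):
        rng = np.random.default_rng(8)
        values = rng.choice([0, 0, 0, 1, 2, 5], size=400).astype(float)
        peaks = extract_peaks(values)
        covered = sum(p.width for p in peaks)
        assert covered == np.count_nonzero(values)
        gaps = sum(p.gap_to_next for p in peaks if p.gap_to_next is not None)
        leading = np.argmax(values > 0) if np.any(values > 0) else len(values)
        trailing = np.argmax(values[::-1] > 0)
        assert covered + gaps + leading + trailing == len(values)


def _peaks_from_heights(heights):
    """One-epoch peaks at fixed spacing (gap 1) for split-rule tests."""
    values = np.zeros(2 * len(heights) + 1)
    values[1::2] = heights
    return extract_peaks(values)


class TestSplits:
    def test_median_split_tie_rule(self):
        lower, upper = split_peaks(_peaks_from_heights([1, 2, 3, 4]), "median")
        assert sorted(p.height for p in lower) == [1, 2]
        assert sorted(p.height for p in upper) == [3, 4]

    def test_equal_heights_all_lower(self):
        lower, upper = split_peaks(_peaks_from_heights([2, 2, 2, 2]), "median")
        assert len(lower) == 4 and len(upper) == 0

    def test_quartile_split_discards_middle(self):
        lower, upper = split_peaks(
            _peaks_from_heights([1, 2, 3, 4, 5, 6, 7, 8]), "quartile")
        assert sorted(p.height for p in lower) == [1, 2]
        assert sorted(p.height for p in upper) == [7, 8]


def brute_force_family(peaks_by_period):
    """Independent recomputation of a few family statistics."""
    all_peaks = [p for per in peaks_by_period for p in per]
    med = np.median([p.height for p in all_peaks])
    upper = [p for p in all_peaks if p.height > med]
    out = {"min_bigger_values": min((p.height for p in upper), default=np.nan),
           "number_of_upper_humps": len(upper),
           "humps_width_max": max(p.width for p in all_peaks),
           "humps_avg_distance": np.mean([p.gap_to_next for p in all_peaks
                                          if p.gap_to_next is not None])}
    gaps = []
    for per in peaks_by_period:
        big = [p for p in per if p.height > med]
        gaps += [b.start_epoch - a.end_epoch for a, b in zip(big, big[1:])]
    out["avg_length_between_bigger"] = np.mean(gaps) if gaps else np.nan
    return out


class TestFamilyFeatures:
    def test_min_bigger_values_example(self):
        feats = peak_family_features([_peaks_from_heights([1, 2, 3, 4])])
        assert feats["min_bigger_values"] == 3.0
        assert feats["number_of_lower_humps"] == 2
        assert feats["number_of_upper_humps"] == 2
        assert feats["number_of_peaks"] == 4

    def test_family_order_invariants(self):
        rng = np.random.default_rng(5)
        values = rng.choice([0, 0, 1, 2, 3, 8], size=300).astype(float)
        feats = peak_family_features([extract_peaks(values)])
        for q in ("distance", "width", "height"):
            for prefix in ("humps", "lower_humps", "upper_humps"):
                name = (f"{prefix}_{{s}}_distance" if q == "distance"
                        else f"{prefix}_{q}_{{s}}")
                lo, med, hi = (feats[name.format(s=s)]
                               for s in ("min", "median", "max"))
                if not np.isnan(lo):
                    assert lo <= med <= hi

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(9)
        periods = [extract_peaks(rng.choice(
            [0, 0, 0, 0, 0, 1, 2, 3, 8], size=200).astype(float))
            for _ in range(3)]
        feats = peak_family_features(periods)
        expected = brute_force_family(periods)
        assert feats["number_of_upper_humps"] > 0  # both groups populated
        for k, v in expected.items():
            assert feats[k] == pytest.approx(v, nan_ok=True), k


class TestScalars:
    def test_zero_ratio(self, make_epochs):
        assert zero_ratio(make_epochs(np.zeros(10))) == 1.0
        assert zero_ratio(make_epochs(np.ones(10))) == 0.0
        c = np.concatenate([np.zeros(30), np.ones(30)])
        assert zero_ratio(make_epochs(c)) == 0.5

    def test_fragmentation_hand_count(self, make_epochs):
        c = np.zeros(100)
        c[40:50] = 9.0  # one 10-epoch mobile run above the threshold of 5
        raw = make_epochs(c)
        frg = fragmentation_index(raw, [SleepPeriod(0, 0, 100)], 5.0)
        assert frg == pytest.approx(0.1)

    def test_fragmentation_extremes(self, make_epochs):
        raw = make_epochs(np.full(50, 2.0))
        assert fragmentation_index(raw, [SleepPeriod(0, 0, 50)], 5.0) == 0.0
        raw = make_epochs(np.full(50, 9.0))
        assert fragmentation_index(raw, [SleepPeriod(0, 0, 50)], 5.0) == 1.0

    def test_fragmentation_requires_sleep(self, make_epochs):
        with pytest.raises(DegenerateInputError):
            fragmentation_index(make_epochs(np.ones(10)), [], 5.0)

    def test_sleep_length(self):
        assert sleep_length_minutes([SleepPeriod(0, 0, 480)]) == 480
        assert sleep_length_minutes([SleepPeriod(0, 0, 400),
                                     SleepPeriod(1, 1000, 1500)]) == 450
        assert np.isnan(sleep_length_minutes([]))
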