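"""Diurnal rest-activity features.

Nonparametric circadian metrics (M10, L5, RA, ADAT, IS, IV), clock-window
day-third summaries, and the Savitzky-Golay boundary (ceiling/floor envelope)
features. All operate on the smoothed epoch series.

IS and IV use the standard nonparametric definitions on hourly-binned
activity:

    IS = n * sum_h (xbar_h - xbar)^2 / (p * sum_i (x_i - xbar)^2)
    IV = n * sum_{i>=2} (x_i - x_{i-1})^2 / ((n - 1) * sum_i (x_i - xbar)^2)

with p = 24 clock-hour bins, xbar_h the mean over days at hour h, and n the
number of hourly samples. IS is 1 for a perfectly repeated daily pattern and
~1/days for structureless noise; IV is ~2 for white noise and near 0 for a
slow sinusoid.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .types import DegenerateInputError, EpochSeries

HOURS_PER_DAY = 24


def day_matrix(epochs: EpochSeries) -> np.ndarray:
    """Complete calendar days as a (n_days, epochs_per_day) matrix.

    The leading partial day (before the first midnight) and any trailing
    partial day are dropped.
    """
    per_day = 86400 // epochs.epoch_seconds
    clock = epochs.clock_minutes()
    at_midnight = np.flatnonzero(clock == 0)
    if len(at_midnight) == 0:
        raise DegenerateInputError("series does not contain a full calendar day")
    i0 = int(at_midnight[0])
    n_days = (len(epochs.counts) - i0) // per_day
    if n_days < 1:
        raise DegenerateInputError("series does not contain a full calendar day")
    return epochs.counts[i0:i0 + n_days * per_day].reshape(n_days, per_day)


def _circular_window_means(day: np.ndarray, width: int) -> np.ndarray:
    """Means of all `width`-epoch contiguous windows, wrapping across midnight."""
    ext = np.concatenate([day, day[:width - 1]])
    cum = np.concatenate(([0.0], np.cumsum(ext)))
    return (cum[width:width + len(day)] - cum[:len(day)]) / width


def nonparametric_profile(epochs: EpochSeries) -> dict[str, float]:
    """M10, L5, RA and ADAT from the smoothed epoch series.

    Per day, M10 (L5) is the mean activity of the maximising (minimising)
    contiguous 10 h (5 h) window, sliding in 1-epoch steps and wrapping
    across midnight within that day; the subject value is the mean over
    days. RA = (M10 - L5) / (M10 + L5); ADAT is the mean daily activity sum.
    """
    days = day_matrix(epochs)
    per_hour = 3600 // epochs.epoch_seconds
    w10, w5 = 10 * per_hour, 5 * per_hour
    m10 = float(np.mean([_circular_window_means(d, w10).max() for d in days]))
    l5 = float(np.mean([_circular_window_means(d, w5).min() for d in days]))
    ra = (m10 - l5) / (m10 + l5) if (m10 + l5) > 0 else 0.0
    adat = float(np.mean(days.sum(axis=1)))
    return {"M10": m10, "L5": l5, "RA": ra, "ADAT": adat}


def hourly_matrix(epochs: EpochSeries) -> np.ndarray:
    """Hourly mean activity of the complete days, shape (n_days, 24)."""
    days = day_matrix(epochs)
    per_hour = days.shape[1] // HOURS_PER_DAY
    return days.reshape(days.shape[0], HOURS_PER_DAY, per_hour).mean(axis=2)


def interdaily_stability_hourly(hourly: np.ndarray) -> float:
    """IS from a (n_days, 24) hourly activity matrix."""
    hourly = np.asarray(hourly, dtype=float)
    if hourly.ndim != 2 or hourly.shape[0] < 2:
        raise DegenerateInputError("IS needs at least 2 full days")
    n = hourly.size
    p = hourly.shape[1]
    xbar = hourly.mean()
    total = np.sum((hourly - xbar) ** 2)
    if total == 0:
        raise DegenerateInputError("IS undefined for a constant series")
    hour_means = hourly.mean(axis=0)
    return float(n * np.sum((hour_means - xbar) ** 2) / (p * total))


def intradaily_variability_hourly(values: np.ndarray) -> float:
    """IV from a 1-D hourly activity series in time order."""
    x = np.asarray(values, dtype=float).ravel()
    n = len(x)
    if n < 2:
        raise DegenerateInputError("IV needs at least 2 hourly samples")
    total = np.sum((x - x.mean()) ** 2)
    if total == 0:
        raise DegenerateInputError("IV undefined for a constant series")
    return float(n * np.sum(np.diff(x) ** 2) / ((n - 1) * total))


def interdaily_stability(epochs: EpochSeries) -> float:
    return interdaily_stability_hourly(hourly_matrix(epochs))


def intradaily_variability(epochs: EpochSeries) -> float:
    return intradaily_variability_hourly(hourly_matrix(epochs).ravel())


def thirds_and_daily(epochs: EpochSeries) -> dict[str, float]:
    """Mean activity in the clock thirds 00-08, 08-16, 16-24 (averaged over
    complete days) plus the mean/std of all epochs in the series."""
    days = day_matrix(epochs)
    per_day = days.shape[1]
    third = per_day // 3
    out = {
        "1_thrd": float(days[:, :third].mean()),
        "2_thrd": float(days[:, third:2 * third].mean()),
        "3_thrd": float(days[:, 2 * third:].mean()),
        "daily_activity_mean": float(epochs.counts.mean()),
        "daily_activity_stdev": float(epochs.counts.std()),
    }
    return out


def _strict_local_extrema(x: np.ndarray, halfwidth: int, kind: str) -> np.ndarray:
    """Indices where x is strictly greater (kind='max') or smaller ('min')
    than every other value within +/- halfwidth epochs.

    The first and last `halfwidth` samples never qualify: an envelope point
    needs a full two-sided neighborhood, and filter edge artifacts would
    otherwise masquerade as boundary values.
    """
    sign = 1.0 if kind == "max" else -1.0
    v = sign * np.asarray(x, dtype=float)
    win = np.lib.stride_tricks.sliding_window_view(v, 2 * halfwidth + 1)
    center = win[:, halfwidth]
    others = np.concatenate([win[:, :halfwidth], win[:, halfwidth + 1:]], axis=1)
    return np.flatnonzero(center > others.max(axis=1)) + halfwidth


def savgol_boundary_features(epochs: EpochSeries, window: int = 61,
                             polyorder: int = 3, halfwidth: int = 15
                             ) -> dict[str, float]:
    """Boundary features from the Savitzky-Golay smoothed activity curve.

    The ceiling curve is the sequence of strict local maxima of the smoothed
    series (over a +/- `halfwidth` epoch neighborhood) and the floor curve the
    strict local minima; the seven summaries describe the level and spread of
    those envelopes. Standard deviations are population (a singleton has
    sd 0). Raises on series with no extrema (monotone or constant input).
    """
    x = epochs.counts
    if len(x) <= window:
        raise DegenerateInputError("series shorter than the Savitzky-Golay window")
    sm = savgol_filter(x, window_length=window, polyorder=polyorder)
    ceil_idx = _strict_local_extrema(sm, halfwidth, "max")
    floor_idx = _strict_local_extrema(sm, halfwidth, "min")
    if len(ceil_idx) == 0 or len(floor_idx) == 0:
        raise DegenerateInputError("no boundary extrema found")
    ceiling = sm[ceil_idx]
    floor = sm[floor_idx]
    boundary = np.concatenate([ceiling, floor])
    return {
        "floor_sum_values": float(floor.sum()),
        "e_v_avg_value": float(boundary.mean()),
        "avg_ceiling_value": float(ceiling.mean()),
        "avg_floor_value": float(floor.mean()),
        "avg_ceiling_floor_diff": float(ceiling.mean() - floor.mean()),
        "std_avg": float(boundary.std()),
        "std_upper": float(ceiling.std()),
    }
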