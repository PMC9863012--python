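"""Morlet continuous wavelet structure statistics of nocturnal activity.

The smoothed ZCM epochs of (by default) five consecutive sleep periods are
concatenated into one 1-min-resolution series and correlated with a Morlet
mother wavelet (a single-frequency sinusoid in a Gaussian envelope,
center-frequency parameter omega0 = 6) over a linear grid of time-window
scales from 1 to 200 minutes. The per-scale squared sum of the (real)
correlation coefficients forms a structure curve whose integral over the
20-100 min band (structure_pm) and standard deviation over the 51-67 min
band (structure_pm_stdev) quantify how much organised bout structure sleep
contains at those time scales.

The transform follows the standard unit-energy convention: with scale ``s``
and angular frequencies ``w_k`` of the zero-padded series,

    What(s, w) = pi**-0.25 * sqrt(2*pi*s/dt) * exp(-(s*w - w0)**2 / 2),  w > 0

and the coefficient map is the inverse FFT of ``xhat * What``. The scale grid
is calibrated in equivalent Fourier period, period = 4*pi*s / (w0 +
sqrt(2 + w0**2)), so a sinusoid of period P peaks at grid value P.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .types import DegenerateInputError, EpochSeries, SleepPeriod

log = logging.getLogger(__name__)


@dataclass
class WaveletMap:
    """Real correlation coefficients per (scale, time).

    ``scales`` are equivalent Fourier periods in minutes; ``coefficients``
    has shape (n_scales, n_times).
    """

    scales: np.ndarray
    coefficients: np.ndarray


@dataclass
class StructureCurve:
    """Per-scale squared sum of wavelet coefficients."""

    scales: np.ndarray
    values: np.ndarray


def concatenate_sleep(smoothed: EpochSeries, periods: list[SleepPeriod],
                      nights: int = 5) -> np.ndarray:
    """Smoothed activity of the first `nights` sleep periods, concatenated in
    time order. Uses all available periods (with a warning) when fewer than
    requested; fewer than two is an error."""
    if len(periods) < 2:
        raise DegenerateInputError(
            f"need at least 2 sleep periods for the wavelet analysis, "
            f"found {len(periods)}")
    if len(periods) < nights:
        log.warning("only %d sleep periods available, %d requested; using all",
                    len(periods), nights)
    use = periods[:nights]
    return np.concatenate([smoothed.counts[p.start_epoch:p.end_epoch] for p in use])


def fourier_period_to_scale(period: np.ndarray | float, omega0: float = 6.0):
    """Invert the Morlet scale <-> Fourier period relation."""
    return np.asarray(period, dtype=float) * (omega0 + math.sqrt(2 + omega0 ** 2)) / (4 * math.pi)


def morlet_cwt(series: np.ndarray, scales_minutes: np.ndarray | None = None,
               dt: float = 1.0, omega0: float = 6.0) -> WaveletMap:
    """Continuous Morlet wavelet transform of a 1-min-resolution series.

    ``scales_minutes`` is the linear grid of equivalent Fourier periods
    (default 1..200 min in 1 min steps). The series is demeaned and
    zero-padded (plain summation over the full map; no cone-of-influence
    masking). If the series is shorter than twice the largest scale, the grid
    is truncated to the largest usable scale with a warning.
    """
    x = np.asarray(series, dtype=float).ravel()
    if scales_minutes is None:
        scales_minutes = np.arange(1.0, 201.0)
    scales_minutes = np.asarray(scales_minutes, dtype=float)
    n = len(x)
    if n < 2 * scales_minutes.min() / dt:
        raise DegenerateInputError("series too short for the smallest scale")
    usable = scales_minutes[scales_minutes <= n * dt / 2]
    if len(usable) < len(scales_minutes):
        log.warning("series of %d min supports scales up to %.0f min; "
                    "truncating the grid from %.0f min", int(n * dt),
                    usable.max(), scales_minutes.max())
    scales_minutes = usable

    n2 = int(2 ** np.ceil(np.log2(2 * n)))
    xhat = np.fft.fft(x - x.mean(), n2)
    omega = 2 * math.pi * np.fft.fftfreq(n2, d=dt)
    s = fourier_period_to_scale(scales_minutes, omega0)  # wavelet scales
    arg = s[:, None] * omega[None, :]
    psi_hat = (math.pi ** -0.25) * np.sqrt(2 * math.pi * s / dt)[:, None] \
        * np.exp(-0.5 * (arg - omega0) ** 2) * (omega[None, :] > 0)
    coeffs = np.fft.ifft(xhat[None, :] * psi_hat, axis=1)[:, :n]
    return WaveletMap(scales=scales_minutes, coefficients=np.real(coeffs))


def structure_curve(wmap: WaveletMap) -> StructureCurve:
    """value(s) = sum over time of coefficient(s, t)**2."""
    return StructureCurve(scales=wmap.scales,
                          values=np.sum(wmap.coefficients ** 2, axis=1))


def structure_pm(curve: StructureCurve, band: tuple[float, float] = (20.0, 100.0)
                 ) -> float:
    """Trapezoidal integral of the structure curve over the scale band."""
    lo, hi = band
    if curve.scales.min() > lo or curve.scales.max() < hi:
        raise DegenerateInputError(
            f"band [{lo}, {hi}] min outside curve domain "
            f"[{curve.scales.min()}, {curve.scales.max()}] min")
    mask = (curve.scales >= lo) & (curve.scales <= hi)
    return float(np.trapezoid(curve.values[mask], curve.scales[mask]))


def structure_pm_stdev(curve: StructureCurve,
                       band: tuple[float, float] = (51.0, 67.0)) -> float:
    """Population standard deviation of the curve values inside the band."""
    lo, hi = band
    if curve.scales.min() > lo or curve.scales.max() < hi:
        raise DegenerateInputError(
            f"band [{lo}, {hi}] min outside curve domain "
            f"[{curve.scales.min()}, {curve.scales.max()}] min")
    mask = (curve.scales >= lo) & (curve.scales <= hi)
    return float(np.std(curve.values[mask]))


def wavelet_features(smoothed: EpochSeries, periods: list[SleepPeriod],
                     config: RunConfig | None = None) -> dict[str, float]:
    """structure_pm and structure_pm_stdev for one recording."""
    cfg = config or RunConfig()
    series = concatenate_sleep(smoothed, periods, cfg.nights_concatenated)
    grid = np.arange(cfg.wavelet_scale_min, cfg.wavelet_scale_max + 1.0)
    wmap = morlet_cwt(series, grid, dt=smoothed.epoch_seconds / 60.0,
                      omega0=cfg.wavelet_omega0)
    curve = structure_curve(wmap)
    return {
        "structure_pm": structure_pm(curve, cfg.pm_band),
        "structure_pm_stdev": structure_pm_stdev(curve, cfg.pm_stdev_band),
    }
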