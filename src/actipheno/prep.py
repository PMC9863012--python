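"""Raw acceleration -> working signals.

Two signals are derived from a recording: the zero-phase Butterworth
band-passed axes (with their Euclidean magnitude), and the per-minute
zero-crossing (ZCM) activity counts, optionally smoothed with a centred
sliding-window mean.
"""

from __future__ import annotations

import logging
import math
from datetime import datetime, timedelta

import numpy as np
from scipy import signal

from .config import RunConfig
from .types import EpochSeries, FilteredSignal, RawRecording

log = logging.getLogger(__name__)


def butter_bandpass_sos(low: float, high: float, fs: float, order: int = 4) -> np.ndarray:
    """Second-order-sections of the maximally flat band-pass design."""
    if high >= fs / 2:
        raise ValueError(f"bandpass high corner {high} Hz >= Nyquist ({fs / 2} Hz)")
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(rec: RawRecording, config: RunConfig | None = None) -> FilteredSignal:
    """Zero-phase Butterworth band-pass of each axis plus the magnitude.

    The pass band (0.25-2.5 Hz by default) removes the gravity component and
    slow drift below and vibration noise above the voluntary-movement band.
    Applied forward-backward so epoch boundaries are not phase-shifted.
    """
    cfg = config or RunConfig()
    sos = butter_bandpass_sos(cfg.bandpass_low, cfg.bandpass_high,
                              rec.sampling_rate, cfg.filter_order)
    settle = int(3 * rec.sampling_rate / cfg.bandpass_low)
    if rec.n_samples < settle:
        raise ValueError(
            f"recording of {rec.n_samples} samples is shorter than 3x the filter "
            f"settling length ({settle} samples)")
    x = signal.sosfiltfilt(sos, rec.x).astype(np.float32)
    y = signal.sosfiltfilt(sos, rec.y).astype(np.float32)
    z = signal.sosfiltfilt(sos, rec.z).astype(np.float32)
    mag = np.sqrt(x * x + y * y + z * z)
    return FilteredSignal(x=x, y=y, z=z, magnitude=mag,
                          sampling_rate=rec.sampling_rate, start_time=rec.start_time)


def _epoch_grid(start_time: datetime, n_samples: int, fs: float,
                epoch_seconds: int) -> tuple[int, int, datetime]:
    """First sample index, number of whole epochs, and first epoch start.

    Epochs are anchored to the first whole clock minute >= start_time so that
    all clock-of-day logic (day thirds, nights) lines up with wall time.
    """
    first_minute = start_time.replace(second=0, microsecond=0)
    if first_minute < start_time:
        first_minute += timedelta(minutes=1)
    offset = int(round((first_minute - start_time).total_seconds() * fs))
    per_epoch = int(round(epoch_seconds * fs))
    n_epochs = max(0, (n_samples - offset) // per_epoch)
    return offset, n_epochs, first_minute


def _upward_crossings(values: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean mask (aligned to sample i+1) of upward threshold crossings."""
    below = values[:-1] < threshold
    at_or_above = values[1:] >= threshold
    out = np.zeros(len(values), dtype=bool)
    out[1:] = below & at_or_above
    return out


def zcm_epochs(sig: FilteredSignal, config: RunConfig | None = None) -> EpochSeries:
    """Zero-crossing-method activity counts per 60 s epoch.

    Per axis, an event is an upward crossing of +threshold (sample below the
    threshold followed by a sample at or above it); events on the three axes
    are summed within whole clock-aligned epochs. A trailing partial epoch is
    dropped.
    """
    cfg = config or RunConfig()
    fs = sig.sampling_rate
    offset, n_epochs, first_minute = _epoch_grid(
        sig.start_time, len(sig.x), fs, cfg.epoch_seconds)
    per_epoch = int(round(cfg.epoch_seconds * fs))
    counts = np.zeros(n_epochs, dtype=float)
    for axis in (sig.x, sig.y, sig.z):
        ev = _upward_crossings(np.asarray(axis, dtype=np.float32), cfg.zcm_threshold)
        usable = ev[offset:offset + n_epochs * per_epoch]
        counts += usable.reshape(n_epochs, per_epoch).sum(axis=1)
    return EpochSeries(counts=counts, start_time=first_minute,
                       epoch_seconds=cfg.epoch_seconds)


def smooth_epochs(epochs: EpochSeries, before: int = 5, after: int = 5) -> EpochSeries:
    """Sliding-window mean over up to `before` predecessors and `after`
    successors of each epoch; the window truncates at the series boundaries."""
    c = epochs.counts
    n = len(c)
    cum = np.concatenate(([0.0], np.cumsum(c)))
    idx = np.arange(n)
    lo = np.maximum(idx - before, 0)
    hi = np.minimum(idx + after + 1, n)
    smoothed = (cum[hi] - cum[lo]) / (hi - lo)
    return EpochSeries(counts=smoothed, start_time=epochs.start_time,
                       epoch_seconds=epochs.epoch_seconds)


def validity_filter(rec: RawRecording, min_days: float = 2.0
                    ) -> tuple[bool, RawRecording]:
    """Accept a recording iff its continuous duration is >= min_days (inclusive);
    the returned recording is trimmed to a whole number of minutes."""
    accepted = rec.duration_seconds >= min_days * 86400.0
    per_minute = int(round(60 * rec.sampling_rate))
    n_keep = (rec.n_samples // per_minute) * per_minute
    trimmed = RawRecording(
        subject_id=rec.subject_id, group_label=rec.group_label,
        start_time=rec.start_time, sampling_rate=rec.sampling_rate,
        x=rec.x[:n_keep], y=rec.y[:n_keep], z=rec.z[:n_keep])
    if not accepted:
        log.info("recording %s rejected: %.1f h < %.0f h required",
                 rec.subject_id, rec.duration_seconds / 3600, min_days * 24)
    return accepted, trimmed


def preprocess_recording(rec: RawRecording, config: RunConfig | None = None
                         ) -> tuple[EpochSeries, EpochSeries]:
    """Full preparation chain: band-pass -> ZCM epochs -> 5+5 smoothing.

    Returns ``(raw_epochs, smoothed_epochs)``.
    """
    cfg = config or RunConfig()
    sig = bandpass_filter(rec, cfg)
    raw = zcm_epochs(sig, cfg)
    smoothed = smooth_epochs(raw, cfg.smooth_before, cfg.smooth_after)
    return raw, smoothed
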