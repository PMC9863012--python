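"""Nightly sleep detection and nocturnal movement-bout ("hump") features.

Sleep is detected on the smoothed ZCM series: within each night window
(18:00 to noon the next day by default) the longest contiguous run of epochs
with smoothed ZCM <= 5 is that night's sleep period, provided it lasts at
least two hours. Peaks are maximal runs of positive smoothed activity inside
a sleep period, separated by zero-valued epochs; the fragmentation index is
computed on the *raw* ZCM counts inside the detected periods (the smoothed
counts are <= 5 there by construction, so brief raw movement bursts are what
"mobile time" can see).
"""

from __future__ import annotations

import logging
from datetime import datetime, time, timedelta

import numpy as np

from .config import RunConfig
from .registry import STATS
from .types import DegenerateInputError, EpochSeries, Peak, SleepPeriod

log = logging.getLogger(__name__)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True in a boolean array."""
    if len(mask) == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def night_windows(epochs: EpochSeries, night_start_hour: int = 18,
                  night_end_hour: int = 12) -> list[tuple[int, int]]:
    """Epoch-index windows [start, end) for every night overlapping the series."""
    t0 = epochs.start_time
    n = len(epochs.counts)
    step = epochs.epoch_seconds
    end_time = t0 + timedelta(seconds=n * step)
    windows = []
    # the window anchored on date d spans d@night_start -> (d+1)@night_end
    d = (t0 - timedelta(hours=24 - night_end_hour)).date()
    while True:
        ws = datetime.combine(d, time(night_start_hour))
        we = datetime.combine(d + timedelta(days=1), time(night_end_hour))
        if ws >= end_time:
            break
        i0 = max(0, int(np.ceil((ws - t0).total_seconds() / step)))
        i1 = min(n, int(np.ceil((we - t0).total_seconds() / step)))
        if i1 > i0:
            windows.append((i0, i1))
        d += timedelta(days=1)
    return windows


def detect_sleep_periods(smoothed: EpochSeries, config: RunConfig | None = None
                         ) -> list[SleepPeriod]:
    """The longest low-activity run per night, if it lasts >= min_sleep_minutes."""
    cfg = config or RunConfig()
    min_epochs = int(np.ceil(cfg.min_sleep_minutes * 60 / smoothed.epoch_seconds))
    periods: list[SleepPeriod] = []
    for night, (i0, i1) in enumerate(
            night_windows(smoothed, cfg.night_start_hour, cfg.night_end_hour)):
        quiet = smoothed.counts[i0:i1] <= cfg.sleep_zcm_max
        runs = _runs(quiet)
        if not runs:
            continue
        start, end = max(runs, key=lambda r: r[1] - r[0])
        if end - start >= min_epochs:
            periods.append(SleepPeriod(night_index=night,
                                       start_epoch=i0 + start, end_epoch=i0 + end))
    return periods


def extract_peaks(values: np.ndarray) -> list[Peak]:
    """Maximal runs of positive activity in a sleep-period slice.

    Indices are relative to the slice; ``gap_to_next`` is the number of
    zero-valued epochs before the next peak (None for the last one).
    """
    values = np.asarray(values, dtype=float)
    runs = _runs(values > 0)
    peaks = [Peak(start_epoch=s, end_epoch=e, height=float(values[s:e].max()))
             for s, e in runs]
    for a, b in zip(peaks, peaks[1:]):
        a.gap_to_next = b.start_epoch - a.end_epoch
    return peaks


def collect_peaks(smoothed: EpochSeries, periods: list[SleepPeriod]
                  ) -> list[list[Peak]]:
    """Peaks per sleep period, with epoch indices shifted to the full series."""
    out = []
    for p in periods:
        peaks = extract_peaks(smoothed.counts[p.start_epoch:p.end_epoch])
        for pk in peaks:
            pk.start_epoch += p.start_epoch
            pk.end_epoch += p.start_epoch
        out.append(peaks)
    return out


def _stats(values: list[float]) -> dict[str, float]:
    if len(values) == 0:
        return {s: np.nan for s in STATS}
    arr = np.asarray(values, dtype=float)
    return {"min": float(arr.min()), "max": float(arr.max()),
            "avg": float(arr.mean()), "median": float(np.median(arr))}


def _quantity_values(peaks: list[Peak]) -> dict[str, list[float]]:
    return {
        "distance": [float(p.gap_to_next) for p in peaks if p.gap_to_next is not None],
        "width": [float(p.width) for p in peaks],
        "height": [p.height for p in peaks],
    }


def split_peaks(peaks: list[Peak], split: str) -> tuple[list[Peak], list[Peak]]:
    """Partition peaks into (lower, upper) by height.

    Median split: lower holds heights <= median, upper the rest (equal-height
    peak sets therefore all land in the lower group). Quartile split: lower is
    height <= Q1, upper is height >= Q3, the interquartile middle belongs to
    neither group.
    """
    heights = np.asarray([p.height for p in peaks], dtype=float)
    if len(peaks) == 0:
        return [], []
    if split == "median":
        med = float(np.median(heights))
        lower = [p for p in peaks if p.height <= med]
        upper = [p for p in peaks if p.height > med]
    elif split == "quartile":
        q1, q3 = np.quantile(heights, [0.25, 0.75])
        lower = [p for p in peaks if p.height <= q1]
        upper = [p for p in peaks if p.height >= q3]
    else:
        raise ValueError("split must be 'median' or 'quartile'")
    return lower, upper


def _named(prefix: str, quantity: str, stat: str, suffix: str = "") -> str:
    if quantity == "distance":
        return f"{prefix}_{stat}_distance{suffix}"
    return f"{prefix}_{quantity}_{stat}{suffix}"


def peak_family_features(peaks_by_period: list[list[Peak]]) -> dict[str, float]:
    """All 73 nocturnal peak features: the grouped families under the median
    and quartile splits, the all-peak statistics, the peak counts, and the
    'bigger' (upper median-split) gap/height families."""
    all_peaks = [p for period in peaks_by_period for p in period]
    feats: dict[str, float] = {}

    groups: dict[str, tuple[list[Peak], list[Peak]]] = {}
    for split, suffix in (("median", ""), ("quartile", "_qrt")):
        lower, upper = split_peaks(all_peaks, split)
        groups[split] = (lower, upper)
        for gname, members in (("lower", lower), ("upper", upper)):
            qv = _quantity_values(members)
            for quantity, values in qv.items():
                for stat, val in _stats(values).items():
                    feats[_named(f"{gname}_humps", quantity, stat, suffix)] = val

    for quantity, values in _quantity_values(all_peaks).items():
        for stat, val in _stats(values).items():
            feats[_named("humps", quantity, stat)] = val

    med_lower, med_upper = groups["median"]
    qrt_lower, qrt_upper = groups["quartile"]
    feats["number_of_lower_humps"] = float(len(med_lower))
    feats["number_of_upper_humps"] = float(len(med_upper))
    feats["number_of_lower_humps_qrt"] = float(len(qrt_lower))
    feats["number_of_upper_humps_qrt"] = float(len(qrt_upper))
    feats["number_of_peaks"] = float(len(all_peaks))

    # gaps between consecutive bigger peaks within the same night
    bigger_ids = {id(p) for p in med_upper}
    gaps: list[float] = []
    for period in peaks_by_period:
        big = [p for p in period if id(p) in bigger_ids]
        gaps += [float(b.start_epoch - a.end_epoch) for a, b in zip(big, big[1:])]
    for stat, val in _stats(gaps).items():
        feats[f"{stat}_length_between_bigger"] = val
    for stat, val in _stats([p.height for p in med_upper]).items():
        feats[f"{stat}_bigger_values"] = val
    return feats


def zero_ratio(epochs: EpochSeries) -> float:
    """Fraction of epochs with activity exactly zero, over the whole series."""
    if len(epochs.counts) == 0:
        raise DegenerateInputError("empty epoch series")
    return float(np.mean(epochs.counts == 0))


def fragmentation_index(raw: EpochSeries, periods: list[SleepPeriod],
                        activity_threshold: float = 5.0) -> float:
    """Mean nightly ratio of mobile time to total sleep time.

    Mobile time is the count of sleep epochs whose raw ZCM exceeds the
    threshold, plus epochs inside immobile runs shorter than one minute
    (vacuous at the default 60 s epoch length, where every immobile run is
    at least one minute long).
    """
    if not periods:
        raise DegenerateInputError("no sleep periods")
    sec = raw.epoch_seconds
    ratios = []
    for p in periods:
        seg = raw.counts[p.start_epoch:p.end_epoch]
        mobile = seg > activity_threshold
        if sec < 60:
            for s, e in _runs(~mobile):
                if (e - s) * sec < 60:
                    mobile[s:e] = True
        ratios.append(float(mobile.sum()) / len(seg))
    return float(np.mean(ratios))


def sleep_length_minutes(periods: list[SleepPeriod], epoch_seconds: int = 60
                         ) -> float:
    """Mean nightly sleep duration in minutes (NaN when no sleep detected)."""
    if not periods:
        return float("nan")
    return float(np.mean([p.duration_minutes(epoch_seconds) for p in periods]))
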