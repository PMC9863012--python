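"""Per-recording feature extraction against the 96-entry registry manifest.

Every extractor failure on a degenerate input (no sleep detected, constant
series, too little data for a family) is converted into missing values for
that family and logged, so a cohort table always has the full registry
column set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import registry, rhythm, sleep, wavelet
from .config import RunConfig
from .prep import preprocess_recording, validity_filter
from .types import DegenerateInputError, EpochSeries, FeatureTable, RawRecording

log = logging.getLogger(__name__)


def baseline_features(smoothed: EpochSeries) -> dict[str, float]:
    """The 3-feature baseline: ZCM mean, ZCM standard deviation (population)
    and ZCM null-ratio of the smoothed series."""
    c = smoothed.counts
    if len(c) == 0:
        raise DegenerateInputError("empty epoch series")
    return {"zcm_mean": float(c.mean()), "zcm_stdev": float(c.std()),
            "zcm_zero_ratio": float(np.mean(c == 0))}


def extract_features_from_epochs(raw: EpochSeries, smoothed: EpochSeries,
                                 config: RunConfig | None = None
                                 ) -> dict[str, float]:
    """All 96 registry features from a prepared (raw, smoothed) epoch pair."""
    cfg = config or RunConfig()
    feats: dict[str, float] = {name: np.nan for name in registry.feature_names()}

    def _fill(family: str, fn):
        try:
            feats.update(fn())
        except DegenerateInputError as e:
            log.warning("%s features undefined: %s", family, e)

    _fill("circadian", lambda: rhythm.nonparametric_profile(smoothed))
    _fill("IS", lambda: {"IS": rhythm.interdaily_stability(smoothed)})
    _fill("IV", lambda: {"IV": rhythm.intradaily_variability(smoothed)})
    _fill("thirds", lambda: rhythm.thirds_and_daily(smoothed))
    _fill("boundary", lambda: rhythm.savgol_boundary_features(
        smoothed, cfg.savgol_window, cfg.savgol_polyorder, cfg.extremum_halfwidth))
    _fill("zero_ratio", lambda: {"zero_ratio": sleep.zero_ratio(smoothed)})

    periods = sleep.detect_sleep_periods(smoothed, cfg)
    feats["length_of_sleep_in_minutes"] = sleep.sleep_length_minutes(
        periods, smoothed.epoch_seconds)
    if periods:
        _fill("fragmentation", lambda: {"frg_index": sleep.fragmentation_index(
            raw, periods, cfg.sleep_zcm_max)})
        peaks_by_period = sleep.collect_peaks(smoothed, periods)
        feats.update(sleep.peak_family_features(peaks_by_period))
        _fill("wavelet", lambda: wavelet.wavelet_features(smoothed, periods, cfg))
    else:
        log.warning("no sleep periods detected; nocturnal features missing")
    return feats


def extract_features(rec: RawRecording, config: RunConfig | None = None
                     ) -> dict[str, float]:
    """Preprocess one raw recording and extract the full registry."""
    cfg = config or RunConfig()
    cfg.validate(rec.sampling_rate)
    raw, smoothed = preprocess_recording(rec, cfg)
    return extract_features_from_epochs(raw, smoothed, cfg)


def extract_cohort_features(recordings,
                            config: RunConfig | None = None
                            ) -> tuple[FeatureTable, FeatureTable]:
    """Feature tables for a cohort: (96-feature registry table, 3-feature
    baseline table). ``recordings`` may be any iterable of RawRecording
    (a generator keeps memory flat on large cohorts). Recordings failing
    the >=2-day validity rule are dropped with a log entry."""
    cfg = config or RunConfig()
    rows, base_rows, ids, labels = [], [], [], []
    n_rejected = 0
    for rec in recordings:
        accepted, trimmed = validity_filter(rec, cfg.min_valid_days)
        if not accepted:
            n_rejected += 1
            continue
        raw, smoothed = preprocess_recording(trimmed, cfg)
        rows.append(extract_features_from_epochs(raw, smoothed, cfg))
        base_rows.append(baseline_features(smoothed))
        ids.append(rec.subject_id)
        labels.append(rec.group_label)
    log.info("extracted features for %d subjects (%d rejected by the "
             "%.0f-day validity rule)", len(ids), n_rejected, cfg.min_valid_days)
    frame = pd.DataFrame(rows, index=ids, columns=registry.feature_names())
    base = pd.DataFrame(base_rows, index=ids)
    label_series = pd.Series(labels, index=ids, name="group")
    return (FeatureTable(frame, label_series, registry.REGISTRY_VERSION),
            FeatureTable(base, label_series.copy(), "baseline-3"))
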