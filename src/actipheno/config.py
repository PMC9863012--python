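"""Pipeline configuration: every tunable constant in one validated place."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields


@dataclass
class RunConfig:
    """All pipeline constants with their defaults.

    Signal preparation
    ------------------
    bandpass_low, bandpass_high : Hz
        Butterworth band-pass corner frequencies removing gravity/drift below
        and vibration noise above the human voluntary-movement band.
    filter_order : int
        Butterworth design order (applied forward-backward, zero phase).
    zcm_threshold : g
        Zero-crossing threshold, slightly above the sensor noise floor.
    epoch_seconds : s
        Activity-count aggregation window.
    smooth_before, smooth_after : epochs
        Sliding-window mean extent around each epoch.
    min_valid_days : days
        Minimum continuous recording length for a subject to be analysed.

    Feature extraction
    ------------------
    sleep_zcm_max : counts
        Smoothed-ZCM ceiling defining candidate sleep epochs (0..5).
    night_start_hour / night_end_hour : clock hours
        Window searched for the nightly sleep period (18:00 -> noon).
    min_sleep_minutes : min
        Shortest run accepted as a night's sleep.
    savgol_window, savgol_polyorder, extremum_halfwidth : epochs
        Savitzky-Golay smoothing and the neighborhood for boundary extrema.
    wavelet_* : min
        Morlet CWT scale grid (equivalent Fourier period) and the two bands
        summarised into structure_pm (integral) and structure_pm_stdev (sd).
    nights_concatenated : nights
        Sleep periods concatenated before the wavelet analysis.

    Selection / modelling
    ---------------------
    welch_alpha, corr_edge_threshold, min_clique_size, n_combinations
        The selection funnel: lenient Welch screen, low-correlation graph,
        minimum clique size, and number of sampled feature combinations.
    cv_folds, rf_n_estimators, gbm_max_iter, gbm_max_depth, lgr_c
        Cross-validation and fixed (never tuned) model hyperparameters.
    """

    # signal prep
    bandpass_low: float = 0.25
    bandpass_high: float = 2.5
    filter_order: int = 4
    zcm_threshold: float = 0.05
    epoch_seconds: int = 60
    smooth_before: int = 5
    smooth_after: int = 5
    min_valid_days: float = 2.0

    # sleep / nocturnal features
    sleep_zcm_max: float = 5.0
    night_start_hour: int = 18
    night_end_hour: int = 12
    min_sleep_minutes: float = 120.0
    savgol_window: int = 61
    savgol_polyorder: int = 3
    extremum_halfwidth: int = 15

    # wavelet structure features
    wavelet_scale_min: float = 1.0
    wavelet_scale_max: float = 200.0
    wavelet_omega0: float = 6.0
    pm_band: tuple[float, float] = (20.0, 100.0)
    pm_stdev_band: tuple[float, float] = (51.0, 67.0)
    nights_concatenated: int = 5

    # selection
    welch_alpha: float = 0.3
    corr_edge_threshold: float = 0.3
    min_clique_size: int = 8
    n_combinations: int = 1600

    # modelling
    cv_folds: int = 10
    rf_n_estimators: int = 500
    gbm_max_iter: int = 100
    gbm_max_depth: int = 3
    gbm_min_samples_leaf: int = 5
    lgr_c: float = 1.0
    shap_exact_max_features: int = 12
    shap_background_size: int | None = None  # None = all training rows
    direction_corr_cut: float = 0.3

    rng_seed: int = 0

    def validate(self, sampling_rate: float | None = None) -> None:
        if not (0 < self.bandpass_low < self.bandpass_high):
            raise ValueError("need 0 < bandpass_low < bandpass_high")
        if sampling_rate is not None and self.bandpass_high >= sampling_rate / 2:
            raise ValueError("bandpass_high must lie below the Nyquist frequency")
        lo, hi = self.pm_band
        lo2, hi2 = self.pm_stdev_band
        if not (self.wavelet_scale_min <= lo < hi <= self.wavelet_scale_max):
            raise ValueError("pm_band must lie inside the wavelet scale range")
        if not (self.wavelet_scale_min <= lo2 < hi2 <= self.wavelet_scale_max):
            raise ValueError("pm_stdev_band must lie inside the wavelet scale range")
        for name in ("epoch_seconds", "smooth_before", "smooth_after", "min_valid_days",
                     "min_clique_size", "n_combinations", "cv_folds", "filter_order",
                     "nights_concatenated", "rf_n_estimators", "gbm_max_iter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.zcm_threshold <= 0:
            raise ValueError("zcm_threshold must be positive")
        if not 0 < self.welch_alpha <= 1:
            raise ValueError("welch_alpha must be in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})
        return cfg
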