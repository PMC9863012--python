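"""Synthetic labeled cohorts of raw wrist-accelerometer recordings.

The generator emulates the envelope of the real deposited data — 10 Hz
triaxial sampling in the +/-8 g interval, a 24 h rest-activity cycle with a
nightly low-activity window, sparse nocturnal movement bouts, a constant 1 g
gravity offset on z, and wide-band sensor noise — as a piecewise-stationary
process: a per-minute intensity drive lambda(clock time) modulates the
standard deviation of band-limited (0.5-3 Hz) Gaussian burst noise, so the
injected activity survives the 0.25-2.5 Hz analysis band-pass.

Daytime drive mixes a fixed daily template with day-specific per-hour noise
(convex weight = ``interdaily_jitter``; more jitter means lower interdaily
stability) and multiplies in minute-scale lognormal variation. During the
sleep window the drive is zero except inside Poisson-placed movement bouts
with exponential durations and a fixed burst amplitude.

Group contrasts are carried only by the profile parameters. The defaults
encode the direction targets the downstream analysis must recover: relative
to controls, the cyclothymia-factor profile has more and stronger nocturnal
bouts (higher L5 and fragmentation) and larger day-to-day jitter (lower IS);
the positive-schizotypy profile has weaker daytime drive with longer, quieter
sleep (higher zero ratio, lower L5) and smaller jitter (higher IS).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime

import numpy as np
from scipy import signal

from .types import ACCEL_RANGE_G, Group, RawRecording

#: intensity 1.0 corresponds to this burst-noise standard deviation (g)
DAY_BURST_SCALE_G = 0.1
#: band of the movement burst noise (Hz); inside the analysis pass band
BURST_BAND_HZ = (0.5, 3.0)
#: spread of the day-specific per-hour profile noise (lognormal sigma)
DAY_PROFILE_SIGMA = 0.75

DEFAULT_START = datetime(2019, 3, 4, 12, 0)


@dataclass
class GroupProfile:
    """Generative parameters of one cohort group."""

    group: Group
    day_mean_intensity: float = 1.0        # dimensionless activity drive
    day_intensity_sd: float = 0.3          # minute-scale lognormal spread
    sleep_onset_hour: float = 23.0         # clock hour
    sleep_duration_h: float = 8.0
    nocturnal_bout_rate: float = 1.5       # bouts per hour of sleep
    nocturnal_bout_duration_mean: float = 2.0   # minutes
    nocturnal_bout_amplitude: float = 0.018     # burst-noise sd during a bout (g)
    interdaily_jitter: float = 0.55        # 0 = identical days, 1 = pure day noise
    noise_floor_sd: float = 0.01           # wide-band sensor noise (g)
    evening_boost: float = 1.0             # multiplier on 16:00-24:00 intensity
    # realism knobs, identical across the default groups: sedentary daytime
    # rest episodes, night-to-night sleep-onset jitter, and per-bout
    # amplitude variability decorrelate the feature families the way real
    # cohorts do
    daytime_rest_rate: float = 2.0         # rest episodes per day
    daytime_rest_duration_mean: float = 45.0  # minutes
    onset_jitter_sd_min: float = 20.0      # nightly onset jitter (minutes)
    bout_amplitude_sigma: float = 0.10     # per-bout lognormal spread
    # movement bouts concentrate toward waking (REM-dominant late sleep):
    # bout placement density ~ exp(gradient * (t/sleep_len - 1/2))
    bout_morning_gradient: float = 1.5

    def __post_init__(self) -> None:
        if not 0 <= self.interdaily_jitter <= 1:
            raise ValueError("interdaily_jitter must lie in [0, 1]")
        for name in ("day_mean_intensity", "day_intensity_sd", "nocturnal_bout_rate",
                     "nocturnal_bout_duration_mean", "nocturnal_bout_amplitude",
                     "noise_floor_sd", "sleep_duration_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.sleep_duration_h > 24:
            raise ValueError("sleep window must fit inside 24 h")


# The premorbid contrasts are deliberately subtle: effect sizes are
# calibrated so the 3-feature baseline classifiers score in the published
# 0.53-0.75 accuracy range rather than saturating, while every injected
# direction stays Welch-detectable at lenient alpha.
DEFAULT_PROFILES: dict[Group, GroupProfile] = {
    Group.C: GroupProfile(group=Group.C),
    Group.CTF: GroupProfile(
        group=Group.CTF,
        nocturnal_bout_rate=2.2, nocturnal_bout_duration_mean=2.2,
        nocturnal_bout_amplitude=0.019, interdaily_jitter=0.75),
    Group.PSF: GroupProfile(
        group=Group.PSF, sleep_duration_h=8.5,
        nocturnal_bout_rate=1.0, nocturnal_bout_duration_mean=1.75,
        nocturnal_bout_amplitude=0.016, interdaily_jitter=0.10),
}


@dataclass
class CohortSpec:
    """How many subjects per group, how long, and the group profiles."""

    n_per_group: dict[Group, int] = field(
        default_factory=lambda: {Group.C: 25, Group.CTF: 22, Group.PSF: 22})
    days_per_subject: int = 7
    sampling_rate: float = 10.0
    seed: int = 0
    profiles: dict[Group, GroupProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES))
    start_time: datetime = DEFAULT_START

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_per_group.values()):
            raise ValueError("n_per_group entries must be >= 1")
        if self.days_per_subject < 2:
            raise ValueError("days_per_subject must be >= the 2-day validity rule")


#: between-subject spread of the profile parameters (lognormal sigma for the
#: multiplicative ones, additive sd for the clock/jitter ones). Without this
#: heterogeneity every subject of a group would be statistically identical
#: and even the 3-feature baseline would separate the groups perfectly.
SUBJECT_SPREAD = {
    "day_mean_intensity": 0.10,
    "day_intensity_sd": 0.30,
    "evening_boost": 0.10,
    "nocturnal_bout_rate": 0.40,
    "nocturnal_bout_duration_mean": 0.30,
    "nocturnal_bout_amplitude": 0.08,
    "daytime_rest_rate": 0.50,
    "sleep_onset_hour": 0.75,   # hours, additive
    "sleep_duration_h": 0.60,   # hours, additive
    "interdaily_jitter": 0.08,  # additive, clipped to [0, 1]
    "bout_morning_gradient": 0.80,  # additive
}


def perturb_profile(profile: GroupProfile, rng: np.random.Generator
                    ) -> GroupProfile:
    """A subject-level draw around a group profile."""
    def logn(s):
        return rng.lognormal(-s ** 2 / 2, s)

    return replace(
        profile,
        day_mean_intensity=profile.day_mean_intensity * logn(
            SUBJECT_SPREAD["day_mean_intensity"]),
        day_intensity_sd=profile.day_intensity_sd * logn(
            SUBJECT_SPREAD["day_intensity_sd"]),
        evening_boost=profile.evening_boost * logn(SUBJECT_SPREAD["evening_boost"]),
        daytime_rest_rate=profile.daytime_rest_rate * logn(
            SUBJECT_SPREAD["daytime_rest_rate"]),
        nocturnal_bout_rate=profile.nocturnal_bout_rate * logn(
            SUBJECT_SPREAD["nocturnal_bout_rate"]),
        nocturnal_bout_duration_mean=profile.nocturnal_bout_duration_mean * logn(
            SUBJECT_SPREAD["nocturnal_bout_duration_mean"]),
        nocturnal_bout_amplitude=profile.nocturnal_bout_amplitude * logn(
            SUBJECT_SPREAD["nocturnal_bout_amplitude"]),
        sleep_onset_hour=(profile.sleep_onset_hour + rng.normal(
            0, SUBJECT_SPREAD["sleep_onset_hour"])) % 24,
        sleep_duration_h=float(np.clip(profile.sleep_duration_h + rng.normal(
            0, SUBJECT_SPREAD["sleep_duration_h"]), 5.0, 11.0)),
        interdaily_jitter=float(np.clip(profile.interdaily_jitter + rng.normal(
            0, SUBJECT_SPREAD["interdaily_jitter"]), 0.0, 1.0)),
        bout_morning_gradient=profile.bout_morning_gradient + rng.normal(
            0, SUBJECT_SPREAD["bout_morning_gradient"]),
    )


def _burst_sos_and_gain(fs: float) -> tuple[np.ndarray, float]:
    """Band-limiting filter for the burst noise plus its white-noise power gain,
    so the filtered noise can be rescaled to unit standard deviation."""
    sos = signal.butter(2, BURST_BAND_HZ, btype="bandpass", fs=fs, output="sos")
    w, h = signal.sosfreqz(sos, worN=2048, fs=fs)
    gain = float(np.sqrt(np.mean(np.abs(h) ** 2)))
    return sos, gain


def _minute_envelope(profile: GroupProfile, days: int, start_time: datetime,
                     rng: np.random.Generator) -> np.ndarray:
    """Burst-noise standard deviation (g) for every minute of the recording."""
    n_min = days * 1440
    start_abs = start_time.hour * 60 + start_time.minute
    abs_min = start_abs + np.arange(n_min)
    clock = abs_min % 1440
    day_idx = abs_min // 1440
    n_days_abs = int(day_idx.max()) + 1

    # sleep windows night by night, with night-to-night onset jitter
    onset = profile.sleep_onset_hour * 60.0
    sleep_len = profile.sleep_duration_h * 60.0
    asleep = np.zeros(n_min, dtype=bool)
    night_starts = []
    for d in range(-1, days + 1):
        o = onset + rng.normal(0, profile.onset_jitter_sd_min)
        night_start = d * 1440 + o - start_abs  # minutes from recording start
        night_starts.append(night_start)
        a = max(int(np.floor(night_start)), 0)
        b = min(int(np.ceil(night_start + sleep_len)), n_min)
        if b > a:
            asleep[a:b] = True

    # daytime drive: convex mix of the flat template with day-specific
    # per-hour lognormal noise, times minute-scale lognormal variation
    j = profile.interdaily_jitter
    sig_u = DAY_PROFILE_SIGMA
    day_noise = rng.lognormal(-sig_u ** 2 / 2, sig_u, size=(n_days_abs, 24))
    mix = (1 - j) + j * day_noise[day_idx, clock // 60]
    sig_m = np.sqrt(np.log1p(profile.day_intensity_sd ** 2))
    minute_noise = rng.lognormal(-sig_m ** 2 / 2, sig_m, size=n_min)
    lam = profile.day_mean_intensity * mix * minute_noise
    lam[clock >= 960] *= profile.evening_boost  # 16:00-24:00

    # sedentary daytime rest episodes: near-quiet windows in the waking day
    for d in range(days + 1):
        for _ in range(rng.poisson(profile.daytime_rest_rate)):
            s = d * 1440 + rng.uniform(0, 1440) - start_abs
            du = rng.exponential(profile.daytime_rest_duration_mean)
            a, b = max(int(np.floor(s)), 0), min(int(np.ceil(s + du)), n_min)
            if b > a:
                lam[a:b] *= 0.05

    env = np.where(asleep, 0.0, DAY_BURST_SCALE_G * lam)

    # nocturnal bouts: Poisson-placed, exponential durations, lognormal
    # per-bout amplitude around the profile level
    sig_a = profile.bout_amplitude_sigma
    g = profile.bout_morning_gradient
    for night_start in night_starts:
        n_bouts = rng.poisson(profile.nocturnal_bout_rate * profile.sleep_duration_h)
        u = rng.uniform(0, 1, size=n_bouts)
        if abs(g) > 1e-9:  # inverse-CDF of the exp(g * t) placement density
            u = np.log1p(u * np.expm1(g)) / g
        starts = np.sort(u * sleep_len)
        durs = rng.exponential(profile.nocturnal_bout_duration_mean, size=n_bouts)
        amps = profile.nocturnal_bout_amplitude * rng.lognormal(
            -sig_a ** 2 / 2, sig_a, size=n_bouts)
        for s, du, amp in zip(starts, durs, amps):
            a = int(np.floor(night_start + s))
            b = int(np.ceil(night_start + min(s + du, sleep_len)))
            a, b = max(a, 0), min(b, n_min)
            if b > a:
                env[a:b] = amp
    return env


def simulate_recording(profile: GroupProfile, days: int, sampling_rate: float = 10.0,
                       seed: int | np.random.SeedSequence = 0,
                       start_time: datetime = DEFAULT_START,
                       subject_id: str = "S000") -> RawRecording:
    """One fully reproducible synthetic recording.

    Per-sample acceleration = 1 g gravity on z + wide-band Gaussian floor
    noise + band-limited burst noise scaled by the minute envelope, clipped
    to the +/-8 g measurement interval.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(seed)
    env_min = _minute_envelope(profile, days, start_time, rng)
    spm = int(round(60 * sampling_rate))
    env = np.repeat(env_min, spm).astype(np.float32)
    n = len(env)

    sos, gain = _burst_sos_and_gain(sampling_rate)
    axes = []
    for _ in range(3):
        burst = rng.standard_normal(n, dtype=np.float32)
        burst = signal.sosfilt(sos, burst).astype(np.float32) / gain
        axis = burst * env
        if profile.noise_floor_sd > 0:
            axis += profile.noise_floor_sd * rng.standard_normal(n, dtype=np.float32)
        axes.append(axis)
    x, y, z = axes
    z = z + 1.0  # gravity on +z; removed by the analysis band-pass anyway
    x = np.clip(x, -ACCEL_RANGE_G, ACCEL_RANGE_G)
    y = np.clip(y, -ACCEL_RANGE_G, ACCEL_RANGE_G)
    z = np.clip(z, -ACCEL_RANGE_G, ACCEL_RANGE_G)
    return RawRecording(subject_id=subject_id, group_label=profile.group,
                        start_time=start_time, sampling_rate=sampling_rate,
                        x=x, y=y, z=z)


def iter_cohort(spec: CohortSpec, truth: dict | None = None):
    """Yield the cohort's recordings one at a time (constant memory).

    Per-subject seeds are spawned deterministically from ``spec.seed``. If a
    dict is passed as ``truth`` it is filled with each subject's group and
    realized (perturbed) profile.
    """
    root = np.random.SeedSequence(spec.seed)
    total = sum(spec.n_per_group.values())
    children = root.spawn(total)
    if truth is not None:
        truth["seed"] = spec.seed
        truth.setdefault("subjects", {})
    i = 0
    for group in (Group.C, Group.CTF, Group.PSF):
        if group not in spec.n_per_group:
            continue
        profile = spec.profiles[group]
        for k in range(spec.n_per_group[group]):
            sid = f"{group.value}{k:03d}"
            seq = children[i]
            subj_profile = perturb_profile(profile, np.random.default_rng(seq))
            rec = simulate_recording(subj_profile, spec.days_per_subject,
                                     spec.sampling_rate, seq.spawn(1)[0],
                                     spec.start_time, subject_id=sid)
            if truth is not None:
                truth["subjects"][sid] = {"group": group.value,
                                          "profile": subj_profile.__dict__.copy()}
            i += 1
            yield rec


def simulate_cohort(spec: CohortSpec) -> tuple[list[RawRecording], dict]:
    """All recordings of a cohort plus the retained ground truth.

    Materializes every recording; for large cohorts prefer :func:`iter_cohort`
    (a week of 10 Hz triaxial data is ~70 MB per subject).
    """
    truth: dict = {}
    recordings = list(iter_cohort(spec, truth))
    return recordings, truth
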