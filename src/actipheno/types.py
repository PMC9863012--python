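"""Core domain containers shared by every pipeline stage.

A recording is a wrist-worn triaxial accelerometer trace in g units; the two
working signals derived from it are the band-passed per-axis acceleration
(plus its Euclidean magnitude) and the per-minute zero-crossing activity
counts (raw and sliding-window smoothed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from enum import Enum

import numpy as np
import pandas as pd

ACCEL_RANGE_G = 8.0  #: sensor measurement interval is +/- 8 g


class Group(str, Enum):
    """Cohort labels: control, cyclothymia factor, positive schizotypy factor."""

    C = "C"
    CTF = "CTF"
    PSF = "PSF"
    UNKNOWN = "UNKNOWN"


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as a recording."""


class DegenerateInputError(ValueError):
    """Raised when a feature is undefined for the given input (e.g. constant series)."""


@dataclass
class RawRecording:
    """Timestamped triaxial acceleration trace for one subject.

    ``x``, ``y``, ``z`` are equal-length arrays of acceleration in g,
    sampled uniformly at ``sampling_rate`` Hz starting at ``start_time``.
    """

    subject_id: str
    start_time: datetime
    sampling_rate: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    group_label: Group = Group.UNKNOWN

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float32)
        self.y = np.asarray(self.y, dtype=np.float32)
        self.z = np.asarray(self.z, dtype=np.float32)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ValueError("axis arrays must have equal length")
        if len(self.x) < 1:
            raise ValueError("recording must contain at least one sample")

    @property
    def n_samples(self) -> int:
        return len(self.x)

    @property
    def duration_seconds(self) -> float:
        return self.n_samples / self.sampling_rate

    def validate_range(self) -> None:
        for name, arr in (("x", self.x), ("y", self.y), ("z", self.z)):
            if np.any(np.abs(arr) > ACCEL_RANGE_G):
                raise ValueError(f"axis {name} has samples outside +/-{ACCEL_RANGE_G} g")


@dataclass
class FilteredSignal:
    """Band-passed axes and their per-sample Euclidean magnitude (g)."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    magnitude: np.ndarray
    sampling_rate: float
    start_time: datetime


@dataclass
class EpochSeries:
    """Per-epoch ZCM activity counts aligned to clock time.

    The first epoch starts at ``start_time`` (always a whole minute); raw
    series hold nonnegative integers, smoothed series nonnegative reals.
    """

    counts: np.ndarray
    start_time: datetime
    epoch_seconds: int = 60

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("epoch counts must be nonnegative")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start_time, periods=len(self.counts),
            freq=pd.Timedelta(seconds=self.epoch_seconds),
        )

    def clock_minutes(self) -> np.ndarray:
        """Minute-of-day (0..1439) of every epoch start."""
        first = self.start_time.hour * 60 + self.start_time.minute
        step = self.epoch_seconds / 60.0
        return (first + np.arange(len(self.counts)) * step) % 1440


@dataclass
class SleepPeriod:
    """One detected nightly sleep interval, as epoch indices [start, end)."""

    night_index: int
    start_epoch: int
    end_epoch: int

    @property
    def duration_epochs(self) -> int:
        return self.end_epoch - self.start_epoch

    def duration_minutes(self, epoch_seconds: int = 60) -> float:
        return self.duration_epochs * epoch_seconds / 60.0


@dataclass
class Peak:
    """A nocturnal movement bout: a maximal run of positive activity.

    ``gap_to_next`` is the number of zero-valued epochs separating this peak
    from the next one in the same sleep period (None for the last peak).
    """

    start_epoch: int
    end_epoch: int
    height: float
    gap_to_next: int | None = None

    @property
    def width(self) -> int:
        return self.end_epoch - self.start_epoch


@dataclass
class FeatureTable:
    """Subjects x named-features matrix plus group labels.

    ``frame`` is indexed by subject id with feature-name columns; ``labels``
    is a per-subject :class:`Group` series sharing the index.
    """

    frame: pd.DataFrame
    labels: pd.Series
    registry_version: str = ""

    def __post_init__(self) -> None:
        if not self.frame.index.equals(self.labels.index):
            raise ValueError("labels index must match frame index")
        if self.frame.columns.duplicated().any():
            raise ValueError("duplicated feature columns")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns)

    def subset(self, features: list[str]) -> "FeatureTable":
        return FeatureTable(self.frame[list(features)].copy(), self.labels.copy(),
                            self.registry_version)
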