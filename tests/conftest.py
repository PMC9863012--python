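import numpy as np
import pytest
from datetime import datetime

from actipheno.types import EpochSeries, FilteredSignal, RawRecording

MIDNIGHT = datetime(2019, 3, 4, 0, 0)
NOON = datetime(2019, 3, 4, 12, 0)


@pytest.fixture
def make_epochs():
    """Factory for minute-epoch series starting at a whole clock minute."""
    def _make(counts, start=MIDNIGHT):
        return EpochSeries(counts=np.asarray(counts, dtype=float), start_time=start)
    return _make


@pytest.fixture
def make_signal():
    """Factory wrapping per-axis arrays as an (already filtered) signal."""
    def _make(x, y=None, z=None, fs=10.0, start=MIDNIGHT):
        x = np.asarray(x, dtype=float)
        y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
        z = np.zeros_like(x) if z is None else np.asarray(z, dtype=float)
        mag = np.sqrt(x * x + y * y + z * z)
        return FilteredSignal(x=x, y=y, z=z, magnitude=mag, sampling_rate=fs,
                              start_time=start)
    return _make


@pytest.fixture
def make_recording():
    def _make(x, y=None, z=None, fs=10.0, start=MIDNIGHT, subject="T000"):
        x = np.asarray(x, dtype=float)
        y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
        z = np.zeros_like(x) if z is None else np.asarray(z, dtype=float)
        return RawRecording(subject_id=subject, start_time=start,
                            sampling_rate=fs, x=x, y=y, z=z)
    return _make
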