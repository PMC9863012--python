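"""Reading and writing the package's plain-text interchange formats.

The canonical recording format is delimited text with columns time (seconds,
or a sample index), x, y, z in g; comma, tab and semicolon dialects are
auto-detected and a header row is optional. Feature tables are TSV with
subject_id and group_label first, then the features in registry order.
"""

from __future__ import annotations

import csv
import logging
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ACCEL_RANGE_G, FeatureTable, FormatError, Group, RawRecording

log = logging.getLogger(__name__)

_DIALECTS = ",\t;"


def _sniff_sep(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=_DIALECTS).delimiter
    except csv.Error:
        counts = {d: sample.count(d) for d in _DIALECTS}
        sep = max(counts, key=counts.get)
        if counts[sep] == 0:
            raise FormatError("could not detect a delimiter (comma/tab/semicolon)")
        return sep


def read_raw_recording(path: str | Path, subject_id: str = "",
                       group_label: Group = Group.UNKNOWN,
                       start_time: datetime | None = None,
                       sampling_rate: float | None = None) -> RawRecording:
    """Parse a delimited t,x,y,z file into a validated recording.

    The time column may be seconds or a sample index; if ``sampling_rate`` is
    not given it is inferred from the first two time values (an index column
    implies the rate cannot be inferred and raises). Values outside the
    +/-8 g measurement interval are clipped, with a count in the log.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty file")
    sep = _sniff_sep(text[:4096])
    first = text.splitlines()[0].split(sep)
    has_header = not all(_is_number(tok) for tok in first)
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    if df.shape[1] < 4:
        raise FormatError(f"{path}: expected 4 columns (t, x, y, z), "
                          f"found {df.shape[1]} on line 1")
    if has_header:
        df.columns = [str(c).strip().lower() for c in df.columns]
        for want in ("x", "y", "z"):
            if want not in df.columns:
                raise FormatError(f"{path}: missing column {want!r} in header")
        time_cols = [c for c in df.columns if c not in ("x", "y", "z")]
        t = df[time_cols[0]].to_numpy(dtype=float) if time_cols \
            else np.arange(len(df), dtype=float)
        x, y, z = (df[c].to_numpy(dtype=float) for c in ("x", "y", "z"))
    else:
        arr = df.to_numpy(dtype=float)
        t, x, y, z = arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]
    if len(t) == 0:
        raise FormatError(f"{path}: no data rows")
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.flatnonzero(dt <= 0)[0]) + 2 + (1 if has_header else 0)
        raise FormatError(f"{path}: non-monotonic time at line {bad}")
    if sampling_rate is None:
        if len(t) < 2 or dt[0] == 0:
            raise FormatError(f"{path}: cannot infer sampling rate")
        sampling_rate = 1.0 / float(np.median(dt))
    n_clipped = int(np.sum((np.abs(x) > ACCEL_RANGE_G) |
                           (np.abs(y) > ACCEL_RANGE_G) |
                           (np.abs(z) > ACCEL_RANGE_G)))
    if n_clipped:
        log.warning("%s: clipped %d samples to +/-%.0f g", path, n_clipped,
                    ACCEL_RANGE_G)
        x = np.clip(x, -ACCEL_RANGE_G, ACCEL_RANGE_G)
        y = np.clip(y, -ACCEL_RANGE_G, ACCEL_RANGE_G)
        z = np.clip(z, -ACCEL_RANGE_G, ACCEL_RANGE_G)
    return RawRecording(subject_id=subject_id or path.stem,
                        group_label=group_label,
                        start_time=start_time or datetime(2019, 1, 1, 0, 0),
                        sampling_rate=float(sampling_rate), x=x, y=y, z=z)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_raw_recording(rec: RawRecording, path: str | Path) -> None:
    """Write a recording as CSV (t in seconds, x, y, z in g, 6 decimals)."""
    t = np.arange(rec.n_samples) / rec.sampling_rate
    df = pd.DataFrame({"t": t, "x": rec.x, "y": rec.y, "z": rec.z})
    df.to_csv(path, index=False, float_format="%.6f")


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """TSV: subject_id, group_label, then features in registry order, full
    float precision. An empty table yields a header-only file."""
    df = table.frame.copy()
    df.insert(0, "group_label", [g.value if isinstance(g, Group) else str(g)
                                 for g in table.labels])
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_feature_table(path: str | Path,
                       registry_version: str = "") -> FeatureTable:
    df = pd.read_csv(path, sep="\t", index_col="subject_id")
    df.index.name = None
    if "group_label" not in df.columns:
        raise FormatError(f"{path}: missing group_label column")
    labels = df.pop("group_label").map(lambda s: Group(s))
    return FeatureTable(df, labels, registry_version)
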