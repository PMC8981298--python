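"""Recording storage: CSV time series + JSON sidecar, and calendar-day segmentation.

Axis convention follows the sensor mounting on the lower back: column ``ax_g``
is vertical, ``ay_g`` mediolateral, ``az_g`` anteroposterior, all in g.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DAY_S = 86400.0
RANGE_G = 8.0
COLUMNS = ["time_s", "ax_g", "ay_g", "az_g"]


@dataclass
class AccelRecording:
    """Uniformly sampled tri-axial acceleration, in g.

    ``data`` has shape (n, 3): vertical, mediolateral, anteroposterior.
    ``t0`` is the time of the first sample in seconds since session start
    (for real-world sessions: since midnight of day 0).
    """

    data: np.ndarray
    fs: float
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 3:
            raise ValueError("data must have shape (n, 3)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    @property
    def vertical(self) -> np.ndarray:
        return self.data[:, 0]

    def day_index(self) -> int:
        return int(self.t0 // DAY_S)

    def slice_time(self, start: float, end: float) -> "AccelRecording":
        i0 = max(0, int(np.ceil((start - self.t0) * self.fs)))
        i1 = min(self.n, int(np.floor((end - self.t0) * self.fs)) + 1)
        return AccelRecording(self.data[i0:i1], self.fs,
                              t0=self.t0 + i0 / self.fs, meta=self.meta)


def write_recording(rec: AccelRecording, csv_path: str | Path,
                    meta: dict | None = None) -> None:
    """Write the CSV (6 decimals — below the sensor noise floor) and sidecar."""
    csv_path = Path(csv_path)
    t = rec.times
    df = pd.DataFrame({"time_s": t, "ax_g": rec.data[:, 0],
                       "ay_g": rec.data[:, 1], "az_g": rec.data[:, 2]})
    df.to_csv(csv_path, index=False, float_format="%.6f")
    meta = dict(meta or rec.meta)
    meta.setdefault("fs_hz", rec.fs)
    with open(csv_path.with_suffix(".json"), "w") as f:
        json.dump(meta, f, indent=1)


def read_recording(path: str | Path, validate: bool = True) -> AccelRecording:
    """Read a recording CSV with its JSON sidecar, validating the invariants.

    Raises on a missing sidecar, NaN samples, values outside the +/-8 g
    sensor range, or gaps in the time column larger than 1.5 sample periods.
    """
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    with open(sidecar) as f:
        meta = json.load(f)
    fs = float(meta["fs_hz"])
    df = pd.read_csv(path)
    return recording_from_table(df, fs, meta, validate=validate)


def recording_from_table(df: pd.DataFrame, fs: float, meta: dict | None = None,
                         validate: bool = True) -> AccelRecording:
    """Loader hook: accept any table holding the four named columns."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"table lacks required columns {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    data = df[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float)
    if validate:
        if len(t) == 0:
            raise ValueError("empty recording")
        if np.any(~np.isfinite(data)) or np.any(~np.isfinite(t)):
            raise ValueError("non-finite samples in recording")
        if np.any(np.abs(data) > RANGE_G + 1e-9):
            raise ValueError(f"acceleration outside the +/-{RANGE_G:g} g sensor range")
        dt = np.diff(t)
        if len(dt) and (np.any(dt <= 0)):
            raise ValueError("time column must be strictly increasing")
        if len(dt) and np.any(dt > 1.5 / fs):
            raise ValueError("gap in time column exceeds 1.5 sample periods")
    return AccelRecording(data=data, fs=fs, t0=float(t[0]) if len(t) else 0.0,
                          meta=dict(meta or {}))


def segment_by_day(rec: AccelRecording) -> list[AccelRecording]:
    """Split a real-world recording at calendar-day boundaries (24 h blocks).

    Concatenating the segments reproduces the input sample-for-sample; a
    recording contained in a single day is returned as-is.
    """
    t = rec.times
    day = np.floor(t / DAY_S).astype(int)
    if day[0] == day[-1]:
        return [rec]
    out = []
    for d in np.unique(day):
        idx = np.nonzero(day == d)[0]
        seg = AccelRecording(rec.data[idx[0]:idx[-1] + 1], rec.fs,
                             t0=float(t[idx[0]]), meta=dict(rec.meta))
        out.append(seg)
    return out
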