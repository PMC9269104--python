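"""Motion-table file I/O.

A motion table stores time series of named channels (joint angles, pelvis
pose) in a self-describing tab-separated dialect compatible with common
biomechanics motion-storage conventions:

    # skitrack motion v1
    # rate_hz: 50
    # units: degrees
    time<TAB>hip_flexion_r<TAB>...
    0.00<TAB>51.3<TAB>...

Header lines start with ``#``; the ``units`` flag applies to angle channels
(``degrees`` are converted to radians on load; translations, identified by a
``pelvis_t`` prefix, are always meters).  Time must be strictly increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import ModelError
from .tracking import TrackingData

__all__ = ["MotionTable", "MotionFormatError", "read_motion", "write_motion"]

_MAGIC = "# skitrack motion v1"


class MotionFormatError(ModelError):
    """Malformed motion file (message carries the offending line number)."""


def _is_angle(name: str) -> bool:
    return not name.startswith("pelvis_t")


@dataclass
class MotionTable:
    """Named channel time series with units metadata (angles in radians)."""

    time: np.ndarray
    channels: dict
    rate_hz: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        if np.any(np.diff(self.time) <= 0):
            k = int(np.argmax(np.diff(self.time) <= 0)) + 2
            raise MotionFormatError(f"non-monotone time at data row {k}")
        if not self.rate_hz:
            self.rate_hz = 1.0 / float(np.mean(np.diff(self.time)))
        for name, v in self.channels.items():
            v = np.asarray(v, float)
            if v.shape != self.time.shape:
                raise MotionFormatError(f"channel {name!r}: length mismatch")
            self.channels[name] = v

    def to_tracking_data(self, weights: dict | None = None) -> TrackingData:
        return TrackingData(self.time, dict(self.channels), dict(weights or {}))

    @classmethod
    def from_solution(cls, solution, system) -> "MotionTable":
        ch = {}
        for name in system.model.coord_names:
            ch[name] = solution.states[:, system.state_index(name)]
        return cls(np.asarray(solution.times), ch)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, **self.channels})


def write_motion(table: MotionTable, path, units: str = "degrees") -> None:
    """Write a motion table (angles converted to ``units`` on disk)."""
    if units not in ("degrees", "radians"):
        raise MotionFormatError(f"unknown units {units!r}")
    df = table.to_frame().copy()
    if units == "degrees":
        for name in table.channels:
            if _is_angle(name):
                df[name] = np.rad2deg(df[name])
    with open(path, "w") as fh:
        fh.write(f"{_MAGIC}\n# rate_hz: {table.rate_hz:g}\n# units: {units}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_motion(path) -> MotionTable:
    """Read a motion table; angle channels are converted to radians."""
    header = {}
    n_header = 0
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines:
        if not line.startswith("#"):
            break
        n_header += 1
        body = line[1:].strip()
        if ":" in body:
            key, _, val = body.partition(":")
            header[key.strip()] = val.strip()
    units = header.get("units", "radians")
    if units not in ("degrees", "radians"):
        raise MotionFormatError(f"line {n_header}: unknown units {units!r}")
    ncols = None
    for i, line in enumerate(lines[n_header:], start=n_header + 1):
        if not line.strip():
            continue
        n = len(line.rstrip("\n").split("\t"))
        if ncols is None:
            ncols = n
        elif n != ncols:
            raise MotionFormatError(f"line {i}: expected {ncols} columns, got {n}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as err:
        raise MotionFormatError(f"cannot parse {path}: {err}") from err
    if "time" not in df.columns:
        raise MotionFormatError(f"line {n_header + 1}: missing 'time' column")
    time = df["time"].to_numpy(float)
    bad = np.nonzero(np.diff(time) <= 0)[0]
    if bad.size:
        raise MotionFormatError(
            f"line {n_header + 2 + int(bad[0]) + 1}: non-monotone time stamp"
        )
    channels = {}
    for name in df.columns:
        if name == "time":
            continue
        v = df[name].to_numpy(float)
        if units == "degrees" and _is_angle(name):
            v = np.deg2rad(v)
        channels[name] = v
    rate = float(header.get("rate_hz", 0) or 0)
    return MotionTable(time, channels, rate, meta=dict(header))
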