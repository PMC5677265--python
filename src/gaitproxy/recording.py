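"""Synchronized multichannel gait recordings and their CSV representation.

A :class:`TimeSeriesRecording` holds the three accelerometer channels of a
single trunk-mounted sensor plus (optionally) the bilateral vertical ground
reaction forces measured by pressure insoles, all sampled at a common rate.
The on-disk format is a plain CSV with header ``k,ax,ay,az,grf_left,grf_right``
(force columns optional), one sample per row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ParseError, StructuralError

ACCEL_CHANNELS = ("ax", "ay", "az")
GRF_CHANNELS = ("grf_left", "grf_right")


@dataclass
class TimeSeriesRecording:
    """Synchronized acceleration and (optional) bilateral vGRF time series.

    Parameters
    ----------
    sampling_rate : float
        Samples per second (Hz), strictly positive.
    ax, ay, az : ndarray
        Acceleration channels in sensor-frame coordinates (m/s^2).
    grf_left, grf_right : ndarray, optional
        Reference vertical ground reaction forces (N), nonnegative.
    """

    sampling_rate: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    grf_left: Optional[np.ndarray] = None
    grf_right: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise StructuralError("sampling_rate must be positive")
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        n = len(self.ax)
        for name in ("ay", "az"):
            if len(getattr(self, name)) != n:
                raise StructuralError(f"channel {name} has length "
                                      f"{len(getattr(self, name))}, expected {n}")
        for name in GRF_CHANNELS:
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if len(v) != n:
                    raise StructuralError(f"channel {name} has length {len(v)},"
                                          f" expected {n}")
                if np.any(v < 0):
                    raise StructuralError(f"{name} contains negative forces")
                setattr(self, name, v)

    @property
    def n_samples(self) -> int:
        return len(self.ax)

    @property
    def has_grf(self) -> bool:
        return self.grf_left is not None and self.grf_right is not None

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def slice(self, start: int, stop: int) -> "TimeSeriesRecording":
        """Contiguous sub-recording over sample indices ``[start, stop)``."""
        def cut(v):
            return None if v is None else v[start:stop].copy()

        return TimeSeriesRecording(
            sampling_rate=self.sampling_rate,
            ax=self.ax[start:stop].copy(),
            ay=self.ay[start:stop].copy(),
            az=self.az[start:stop].copy(),
            grf_left=cut(self.grf_left),
            grf_right=cut(self.grf_right),
            metadata=dict(self.metadata),
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"k": np.arange(self.n_samples, dtype=int),
                "ax": self.ax, "ay": self.ay, "az": self.az}
        if self.grf_left is not None:
            data["grf_left"] = self.grf_left
        if self.grf_right is not None:
            data["grf_right"] = self.grf_right
        return pd.DataFrame(data)


def write_recording(path, recording: TimeSeriesRecording) -> None:
    """Write a recording as CSV; full float precision is preserved."""
    df = recording.to_frame()
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate={recording.sampling_rate!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_recording(path, sampling_rate: Optional[float] = None) -> TimeSeriesRecording:
    """Read a recording CSV written by :func:`write_recording`.

    The sampling rate is taken from the ``# sampling_rate=`` comment line if
    present, else from the ``sampling_rate`` argument.
    """
    fs = sampling_rate
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        if "sampling_rate=" in first:
            try:
                fs = float(first.split("sampling_rate=")[1].strip())
            except ValueError as exc:
                raise ParseError(f"bad sampling_rate comment in {path}", line=1) from exc
    if fs is None:
        raise ParseError(f"{path}: no sampling rate in file and none supplied")
    try:
        df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        # pandas reports the offending line in its message
        raise ParseError(f"malformed CSV {path}: {exc}") from exc
    required = {"ax", "ay", "az"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}", line=1 + skip)
    known = {"k", *ACCEL_CHANNELS, *GRF_CHANNELS}
    unknown = set(df.columns) - known
    if unknown:
        raise ParseError(f"{path}: unknown channel columns {sorted(unknown)}", line=1 + skip)
    if df[list(required)].isna().any().any():
        bad = int(df[list(required)].isna().any(axis=1).idxmax())
        raise ParseError(f"{path}: ragged or non-numeric row", line=bad + 2 + skip)
    return TimeSeriesRecording(
        sampling_rate=fs,
        ax=df["ax"].to_numpy(),
        ay=df["ay"].to_numpy(),
        az=df["az"].to_numpy(),
        grf_left=df["grf_left"].to_numpy() if "grf_left" in df else None,
        grf_right=df["grf_right"].to_numpy() if "grf_right" in df else None,
    )
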