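"""Raw IMU record I/O.

A record is a comma-separated file with one header row and one row per
sample: columns ``t, ax, ay, az, gx, gy, gz`` (seconds, m/s², rad/s) plus an
optional integer ``label`` column (1 = walking, 0 = not walking).  Other
column layouts can be accommodated with a ``column_map``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ImuSeries", "ImuFormatError", "RateReport", "read_imu_csv", "write_imu_csv", "validate_rate"]

REQUIRED_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")


class ImuFormatError(ValueError):
    """Raised for malformed or empty IMU record files."""


@dataclass
class ImuSeries:
    """Timestamped 6-axis inertial record at a nominal sampling rate.

    t: sample times in seconds, monotone non-decreasing.
    a: (n, 3) accelerometer, m/s².
    omega: (n, 3) gyroscope, rad/s.
    rate_hz: nominal sampling frequency (100 for the target platform).
    labels: optional per-sample 0/1 walking labels.
    meta: free-form provenance (e.g. simulator ground truth).
    """

    t: np.ndarray
    a: np.ndarray
    omega: np.ndarray
    rate_hz: float = 100.0
    labels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.a = np.atleast_2d(np.asarray(self.a, dtype=float))
        self.omega = np.atleast_2d(np.asarray(self.omega, dtype=float))
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
        n = len(self.t)
        if n < 1:
            raise ValueError("ImuSeries must contain at least one sample")
        if self.a.shape != (n, 3) or self.omega.shape != (n, 3):
            raise ValueError(
                f"shape mismatch: t has {n} samples, a {self.a.shape}, omega {self.omega.shape}"
            )
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("label track length differs from series length")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if n > 1 and np.any(np.diff(self.t) < 0):
            raise ValueError("timestamps must be monotone non-decreasing")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class RateReport:
    """Outcome of a sampling-rate sanity check (report only, never raises)."""

    median_dt: float
    nominal_dt: float
    n_deviant: int
    deviant_fraction: float
    degenerate: bool = False


def read_imu_csv(path, rate_hz: float = 100.0, column_map: dict | None = None) -> ImuSeries:
    """Parse an IMU record CSV into an ImuSeries (labels attached if present).

    ``column_map`` renames file columns onto the canonical names, e.g.
    ``{"time": "t", "acc_x": "ax", ...}`` for foreign layouts.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ImuFormatError(f"{path}: empty file") from exc
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ImuFormatError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise ImuFormatError(f"{path}: no data rows")
    cols = list(REQUIRED_COLUMNS) + (["label"] if "label" in df.columns else [])
    for c in cols:
        numeric = pd.to_numeric(df[c], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise ImuFormatError(f"{path}: non-numeric value in column {c!r} at data row {row}")
        df[c] = numeric
    labels = df["label"].to_numpy(dtype=int) if "label" in df.columns else None
    return ImuSeries(
        t=df["t"].to_numpy(),
        a=df[["ax", "ay", "az"]].to_numpy(),
        omega=df[["gx", "gy", "gz"]].to_numpy(),
        rate_hz=rate_hz,
        labels=labels,
    )


def write_imu_csv(series: ImuSeries, path, labels=None, decimals: int = 6) -> None:
    """Write a record readable by :func:`read_imu_csv`, one row per sample."""
    if len(series) == 0:
        raise ImuFormatError("refusing to write an empty record")
    data = {
        "t": series.t,
        "ax": series.a[:, 0],
        "ay": series.a[:, 1],
        "az": series.a[:, 2],
        "gx": series.omega[:, 0],
        "gy": series.omega[:, 1],
        "gz": series.omega[:, 2],
    }
    if labels is None:
        labels = series.labels
    if labels is not None:
        data["label"] = np.asarray(labels, dtype=int)
    df = pd.DataFrame(data)
    df.to_csv(path, index=False, float_format=f"%.{decimals}g")


def validate_rate(series: ImuSeries, tolerance: float = 0.05) -> RateReport:
    """Report the median inter-sample interval and gaps deviating from nominal.

    A gap is deviant when it differs from 1/rate_hz by more than
    ``tolerance`` as a fraction of the nominal interval.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 samples to validate the rate")
    dts = np.diff(series.t)
    nominal = 1.0 / series.rate_hz
    median_dt = float(np.median(dts))
    deviant = np.abs(dts - nominal) > tolerance * nominal
    return RateReport(
        median_dt=median_dt,
        nominal_dt=nominal,
        n_deviant=int(deviant.sum()),
        deviant_fraction=float(deviant.mean()),
        degenerate=bool(median_dt <= 0),
    )
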