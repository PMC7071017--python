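"""Signal conditioning and windowing.

The classifier input is a 9-dimensional signal per sample — sensor-frame
acceleration ``a``, Earth-frame (projected) acceleration ``a_E`` and angular
rate ``ω`` — low-pass filtered (10th-order Butterworth, 3 Hz cut-off at
100 Hz) and DC-centered by subtracting a trailing moving average of the
previous N = 250 samples.  Predictions are made on sliding windows of 250
samples with 50% overlap, i.e. every 1.25 s at 100 Hz.  Windows straddling a
start/stop of walking are discarded unless one class covers at least 75% of
their samples.

Also provides the classic pedometer peak-valley step detector used as a
baseline; it counts any peak-then-valley excursion and therefore fires on
gesticulation too, which is exactly the failure mode the classifiers fix.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import signal as _sig

from .attitude import MadgwickConfig, estimate_attitude, project_acceleration

__all__ = [
    "WindowLabel",
    "ProcessedSeries",
    "LabeledWindow",
    "lowpass",
    "dc_center",
    "build_processed",
    "make_windows",
    "label_window",
    "find_peaks_strict",
    "peak_valley_steps",
]

WINDOW_N = 250
CHANNEL_NAMES = ("ax", "ay", "az", "aEx", "aEy", "aEz", "gx", "gy", "gz")


class WindowLabel(Enum):
    NOT_WALKING = 0
    WALKING = 1
    DISCARDED = -1


@dataclass
class ProcessedSeries:
    """Filtered, centered 9-channel signal; shape (n, 9), columns CHANNEL_NAMES."""

    values: np.ndarray
    rate_hz: float
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 9:
            raise ValueError(f"expected (n, 9) values, got {self.values.shape}")

    def __len__(self) -> int:
        return len(self.values)

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, CHANNEL_NAMES.index(name)]


@dataclass
class LabeledWindow:
    """A 250×9 slice of a ProcessedSeries with its class label."""

    values: np.ndarray
    start_index: int
    label: WindowLabel
    rate_hz: float = 100.0

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, CHANNEL_NAMES.index(name)]


def lowpass(channel, order: int = 10, cutoff_hz: float = 3.0, rate_hz: float = 100.0,
            zero_phase: bool = False):
    """Causal Butterworth low-pass (second-order sections for stability).

    ``zero_phase=True`` switches to forward-backward filtering for offline
    analysis; the default is causal, matching real-time prediction.
    """
    nyq = rate_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist {nyq} Hz")
    sos = _sig.butter(order, cutoff_hz / nyq, btype="low", output="sos")
    x = np.asarray(channel, dtype=float)
    if zero_phase:
        return _sig.sosfiltfilt(sos, x, axis=0)
    return _sig.sosfilt(sos, x, axis=0)


def dc_center(channel, window_n: int = WINDOW_N):
    """Subtract the trailing mean of the previous ``window_n`` samples.

    At index t the mean runs over samples t−1 … t−window_n (strictly before
    t); during warm-up (t < window_n) the mean of all available preceding
    samples is used, and the first sample is passed through unchanged.
    """
    if window_n < 1:
        raise ValueError("window_n must be >= 1")
    x = np.asarray(channel, dtype=float)
    n = len(x)
    zero = np.zeros((1,) + x.shape[1:])
    csum = np.concatenate([zero, np.cumsum(x, axis=0)], axis=0)
    t = np.arange(n)
    lo = np.maximum(t - window_n, 0)
    counts = t - lo
    means = np.zeros_like(x)
    nz = counts > 0
    if x.ndim == 1:
        means[nz] = (csum[t[nz]] - csum[lo[nz]]) / counts[nz]
    else:
        means[nz] = (csum[t[nz]] - csum[lo[nz]]) / counts[nz, None]
    return x - means


def build_processed(series, track=None, cfg: MadgwickConfig | None = None,
                    order: int = 10, cutoff_hz: float = 3.0,
                    window_n: int = WINDOW_N, zero_phase: bool = False) -> ProcessedSeries:
    """Assemble ``s = (a, a_E, ω)`` then low-pass filter and DC-center it.

    Computes the attitude track if not supplied.
    """
    if track is None:
        track = estimate_attitude(series, cfg)
    a_e = project_acceleration(series, track)
    s = np.concatenate([series.a, a_e, series.omega], axis=1)
    s = lowpass(s, order=order, cutoff_hz=cutoff_hz, rate_hz=series.rate_hz,
                zero_phase=zero_phase)
    s = dc_center(s, window_n=window_n)
    return ProcessedSeries(values=s, rate_hz=series.rate_hz, labels=series.labels)


def label_window(window_labels, purity: float = 0.75) -> WindowLabel:
    """Majority class if its share reaches ``purity``, else DISCARDED."""
    labels = np.asarray(window_labels)
    frac_walk = float(np.mean(labels == 1))
    if frac_walk >= purity:
        return WindowLabel.WALKING
    if 1.0 - frac_walk >= purity:
        return WindowLabel.NOT_WALKING
    return WindowLabel.DISCARDED


def make_windows(series: ProcessedSeries, labels=None, n: int = WINDOW_N,
                 overlap: float = 0.5, purity: float = 0.75) -> list[LabeledWindow]:
    """Cut sliding windows of ``n`` samples with the given fractional overlap.

    Stride is ``n·(1−overlap)`` samples; at 100 Hz and the defaults a new
    window (prediction) occurs every 1.25 s.  Returns an empty list when the
    series is shorter than one window.
    """
    if labels is None:
        labels = series.labels
    stride = int(round(n * (1.0 - overlap)))
    if stride < 1:
        raise ValueError("overlap too large: stride would be < 1 sample")
    out: list[LabeledWindow] = []
    total = len(series)
    for start in range(0, total - n + 1, stride):
        sl = series.values[start:start + n]
        if labels is not None:
            lab = label_window(labels[start:start + n], purity=purity)
        else:
            lab = WindowLabel.DISCARDED
        out.append(LabeledWindow(values=sl, start_index=start, label=lab,
                                 rate_hz=series.rate_hz))
    return out


def find_peaks_strict(x, min_prominence: float = 0.0) -> np.ndarray:
    """Indices of strict local maxima over a 3-sample neighborhood."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        return np.array([], dtype=int)
    idx = np.nonzero((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:]))[0] + 1
    if min_prominence > 0 and len(idx):
        prom = _sig.peak_prominences(x, idx)[0]
        idx = idx[prom >= min_prominence]
    return idx


def peak_valley_steps(vertical, peak_thresh: float, valley_thresh: float):
    """Count steps as peak-then-valley event pairs, scanning left to right.

    A step is a strict local maximum above ``peak_thresh`` followed by a
    strict local minimum below ``valley_thresh``; each extremum is consumed
    by at most one event.  Returns ``(count, peak_indices)``.
    """
    if not peak_thresh > valley_thresh:
        raise ValueError("peak_thresh must exceed valley_thresh")
    x = np.asarray(vertical, dtype=float)
    peaks = [i for i in find_peaks_strict(x) if x[i] > peak_thresh]
    valleys = [i for i in find_peaks_strict(-x) if x[i] < valley_thresh]
    steps: list[int] = []
    vi = 0
    for p in peaks:
        while vi < len(valleys) and valleys[vi] <= p:
            vi += 1
        if vi < len(valleys):
            steps.append(p)
            vi += 1
    return len(steps), np.array(steps, dtype=int)
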