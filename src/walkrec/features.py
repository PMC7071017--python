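"""Per-window time- and frequency-domain features.

Each 250-sample window of the processed 9-channel signal is summarized by
21 features.  Time domain: the mean ("energy") of the vertical projected
acceleration and of the gyro norm, the variance of the gyro norm, per-axis
standard deviations of the raw and projected acceleration, the
zero-crossing rate and peak count of the acceleration norm, the peak count
of the vertical projected acceleration, and skewness/kurtosis statistics.
Frequency domain: statistics of the one-sided FFT magnitude spectra of the
acceleration norm (``f``) and of the vertical projected acceleration
(``f_E``), computed over a rectangular (untapered) window with the DC bin
excluded — the signal is already centered.

Skewness and kurtosis use the Joanes–Gill "type 3" sample estimators

    b1 = g1 · ((n−1)/n)^{3/2}
    b2 = (g2 + 3) · ((n−1)/n)² − 3

where g1, g2 are the plain moment-ratio estimators.
"""

from __future__ import annotations

import numpy as np

from .preprocess import LabeledWindow, find_peaks_strict

__all__ = [
    "FEATURE_NAMES",
    "DegenerateWindowError",
    "energy_mean",
    "zcr",
    "peak_count",
    "skewness_t3",
    "kurtosis_t3",
    "spectrum",
    "spectral_features",
    "extract_features",
    "feature_matrix",
]

FEATURE_NAMES = (
    "E_aEz", "E_w", "var_w",
    "sd_ax", "sd_ay", "sd_az",
    "sd_aEx", "sd_aEy", "sd_aEz",
    "ZCR_a", "P_a", "P_aEz",
    "skew_aEz", "skew_w", "kurt_aEz",
    "mean_fE", "sd_fE", "med_fE", "mode_fE", "mode_f", "kurt_fE",
)


class DegenerateWindowError(ValueError):
    """A window whose statistics are undefined (e.g. zero variance)."""


def energy_mean(channel) -> float:
    """Arithmetic mean of the channel (the window 'energy' statistic).

    For the gyro the input is the per-sample norm ‖ω‖.  A conventional
    sum-of-squares energy is available via ``energy_squared=True`` in
    :func:`extract_features`.
    """
    return float(np.mean(np.asarray(channel, dtype=float)))


def _sign01(x):
    # 1 for x >= 0, 0 for x < 0
    return (np.asarray(x) >= 0).astype(float)


def zcr(channel) -> float:
    """Zero-crossing rate ``0.5/N · Σ |sign(x[n+1]) − sign(x[n])|``.

    The sign convention maps x ≥ 0 to 1 and x < 0 to 0, so each adjacent
    sign flip contributes 1 to the sum; the maximum over N samples is
    0.5·(N−1)/N.
    """
    x = np.asarray(channel, dtype=float)
    s = _sign01(x)
    return 0.5 * float(np.sum(np.abs(np.diff(s)))) / len(x)


def peak_count(channel, min_prominence: float = 0.0) -> int:
    """Number of strict local maxima in the window."""
    return int(len(find_peaks_strict(channel, min_prominence=min_prominence)))


def _moments(x):
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise DegenerateWindowError("need at least 3 samples for shape statistics")
    m = x - x.mean()
    m2 = float(np.mean(m ** 2))
    if m2 == 0.0:
        raise DegenerateWindowError("zero variance: skewness/kurtosis undefined")
    return n, m, m2


def skewness_t3(x) -> float:
    n, m, m2 = _moments(x)
    g1 = float(np.mean(m ** 3)) / m2 ** 1.5
    return g1 * ((n - 1) / n) ** 1.5


def kurtosis_t3(x) -> float:
    n, m, m2 = _moments(x)
    g2 = float(np.mean(m ** 4)) / m2 ** 2 - 3.0
    return (g2 + 3.0) * ((n - 1) / n) ** 2 - 3.0


def spectrum(channel, rate_hz: float = 100.0):
    """One-sided FFT magnitude spectrum, DC bin excluded.

    Returns ``(freqs, amps)``; bin width is ``rate_hz / N`` (0.4 Hz for the
    standard 250-sample window at 100 Hz).
    """
    x = np.asarray(channel, dtype=float)
    n = len(x)
    amps = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    return freqs[1:], amps[1:]


def spectral_features(freqs, amps):
    """(mean, sd, median, modal frequency, spectral kurtosis) of a spectrum.

    Mean and sd are amplitude-weighted moments of frequency; the median is
    the first frequency where cumulative amplitude reaches half the total;
    the mode is the argmax bin (ties broken toward the lower frequency);
    the kurtosis is the type-3 kurtosis of the amplitude sequence itself.
    """
    amps = np.asarray(amps, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    total = float(amps.sum())
    if total == 0.0:
        raise DegenerateWindowError("all-zero spectrum: spectral features undefined")
    w = amps / total
    mu = float(np.sum(w * freqs))
    sd = float(np.sqrt(np.sum(w * (freqs - mu) ** 2)))
    med = float(freqs[np.searchsorted(np.cumsum(amps), total / 2.0)])
    mode = float(freqs[int(np.argmax(amps))])  # argmax takes the first (lowest) max
    kurt = kurtosis_t3(amps)
    return mu, sd, med, mode, kurt


def extract_features(window: LabeledWindow, energy_squared: bool = False,
                     min_prominence: float = 0.0) -> dict[str, float]:
    """All 21 features of a window, keyed by FEATURE_NAMES.

    Raises :class:`DegenerateWindowError` listing the failing statistics on
    flat windows.
    """
    a = window.values[:, 0:3]
    a_e = window.values[:, 3:6]
    w = window.values[:, 6:9]
    a_norm = np.linalg.norm(a, axis=1)
    a_norm_c = a_norm - a_norm.mean()  # center the non-negative norm channel
    w_norm = np.linalg.norm(w, axis=1)
    aez = window.values[:, 5]

    failures = []
    out: dict[str, float] = {}

    def _try(name, fn):
        try:
            out[name] = float(fn())
        except DegenerateWindowError:
            failures.append(name)

    if energy_squared:
        out["E_aEz"] = float(np.mean(aez ** 2))
        out["E_w"] = float(np.mean(w_norm ** 2))
    else:
        out["E_aEz"] = energy_mean(aez)
        out["E_w"] = energy_mean(w_norm)
    out["var_w"] = float(np.var(w_norm, ddof=1))
    for name, col in zip(("sd_ax", "sd_ay", "sd_az"), a.T):
        out[name] = float(np.std(col, ddof=1))
    for name, col in zip(("sd_aEx", "sd_aEy", "sd_aEz"), a_e.T):
        out[name] = float(np.std(col, ddof=1))
    out["ZCR_a"] = zcr(a_norm_c)
    out["P_a"] = peak_count(a_norm, min_prominence)
    out["P_aEz"] = peak_count(aez, min_prominence)
    _try("skew_aEz", lambda: skewness_t3(aez))
    _try("skew_w", lambda: skewness_t3(w_norm))
    _try("kurt_aEz", lambda: kurtosis_t3(aez))

    f_e, amps_e = spectrum(aez, window.rate_hz)
    f_a, amps_a = spectrum(a_norm_c, window.rate_hz)
    try:
        mu, sd, med, mode, kurt = spectral_features(f_e, amps_e)
        out.update(mean_fE=mu, sd_fE=sd, med_fE=med, mode_fE=mode, kurt_fE=kurt)
    except DegenerateWindowError:
        failures.extend(["mean_fE", "sd_fE", "med_fE", "mode_fE", "kurt_fE"])
    try:
        out["mode_f"] = spectral_features(f_a, amps_a)[3]
    except DegenerateWindowError:
        failures.append("mode_f")

    if failures:
        raise DegenerateWindowError(f"degenerate window; undefined features: {failures}")
    return {name: out[name] for name in FEATURE_NAMES}


def feature_matrix(windows, **kwargs):
    """Feature table + labels for a list of windows (discarded ones skipped).

    Returns ``(X, y, kept_windows)`` with X of shape (n_kept, 21).
    """
    from .preprocess import WindowLabel

    rows, ys, kept = [], [], []
    for wdw in windows:
        if wdw.label == WindowLabel.DISCARDED:
            continue
        rows.append([extract_features(wdw, **kwargs)[n] for n in FEATURE_NAMES])
        ys.append(wdw.label.value)
        kept.append(wdw)
    return np.asarray(rows, dtype=float), np.asarray(ys, dtype=int), kept
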