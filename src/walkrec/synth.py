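"""Synthetic labeled IMU records for end-to-end pipeline testing.

The generator produces the signal structure the pipeline assumes, fully
seeded:

* **walking** — vertical Earth-frame acceleration built as a harmonic
  series at the step frequency (1.5–2.5 Hz) with phase-aligned impulse
  sharpening emulating heel strikes, plus horizontal sway at half the step
  frequency; the Earth-frame signal (gravity included) is rotated into a
  slowly drifting device frame, and the gyroscope output is the true
  angular rate of that drift, so attitude estimation faces a solvable,
  kinematically consistent problem.
* **gesture** — smoothed random sub-3 Hz accelerations of walking-like
  magnitude but with no sustained periodic impact train (the classic
  false-positive hazard for peak-valley step counters).
* **static** — the device at rest in a random fixed orientation.

Records for a dataset concatenate walking / gesture / static segments with
stop-and-go transitions, so the ≥75% window-purity rule is exercised.
Ground truth (step times, true orientation quaternions, segment layout) is
kept in ``ImuSeries.meta``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as _sig

from .imu_io import ImuSeries, write_imu_csv

__all__ = ["GaitParams", "gen_static", "gen_walking", "gen_gesture", "gen_record", "gen_dataset"]

GRAVITY = 9.81


@dataclass
class GaitParams:
    """Simulator conditions.

    step_freq_hz: step rate; ``None`` draws uniformly from 1.5–2.5 Hz.
    impact_amp: heel-strike vertical amplitude, m/s²; ``None`` draws 2–6.
    harmonics: number of harmonics in the gait comb (3).
    orient_drift_deg_s: RMS angular rate of the slow device re-orientation.
    noise_sd: white accelerometer/gyro noise, m/s² and rad/s.
    rate_hz: sampling frequency (100).
    """

    step_freq_hz: float | None = None
    impact_amp: float | None = None
    harmonics: int = 3
    orient_drift_deg_s: float = 10.0
    noise_sd: float = 0.3
    gravity: float = GRAVITY
    rate_hz: float = 100.0


def _random_unit_quat(rng) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def _quat_rotmat_t(q):
    """R(q)ᵀ rows as arrays; maps Earth-frame vectors into the device frame."""
    q0, q1, q2, q3 = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    r = np.empty(q.shape[:1] + (3, 3))
    r[:, 0, 0] = 1 - 2 * (q2 ** 2 + q3 ** 2)
    r[:, 0, 1] = 2 * (q1 * q2 - q0 * q3)
    r[:, 0, 2] = 2 * (q1 * q3 + q0 * q2)
    r[:, 1, 0] = 2 * (q1 * q2 + q0 * q3)
    r[:, 1, 1] = 1 - 2 * (q1 ** 2 + q3 ** 2)
    r[:, 1, 2] = 2 * (q2 * q3 - q0 * q1)
    r[:, 2, 0] = 2 * (q1 * q3 - q0 * q2)
    r[:, 2, 1] = 2 * (q2 * q3 + q0 * q1)
    r[:, 2, 2] = 1 - 2 * (q1 ** 2 + q2 ** 2)
    return np.transpose(r, (0, 2, 1))


def _drifting_orientation(n, dt, rng, drift_deg_s, q0=None):
    """Orientation trajectory q(t) (device→Earth) and its body angular rate.

    The body rate is a band-limited random walk; quaternions are integrated
    with the exact exponential map, so the returned (q, ω) pair is
    self-consistent to machine precision at the sample times.
    """
    drift = np.deg2rad(drift_deg_s)
    w = rng.normal(0.0, 1.0, size=(n, 3))
    # smooth to sub-1 Hz wander
    sos = _sig.butter(2, min(0.5 * dt * 2, 0.99), btype="low", output="sos")
    w = _sig.sosfilt(sos, w, axis=0)
    rms = np.sqrt(np.mean(w ** 2)) or 1.0
    w *= drift / rms
    q = np.empty((n, 4))
    q[0] = _random_unit_quat(rng) if q0 is None else q0
    for t in range(1, n):
        ang = w[t] * dt
        theta = np.linalg.norm(ang)
        if theta < 1e-12:
            dq = np.array([1.0, 0.0, 0.0, 0.0])
        else:
            axis = ang / theta
            dq = np.concatenate([[np.cos(theta / 2)], np.sin(theta / 2) * axis])
        p, r = q[t - 1], dq
        q[t] = np.array([
            p[0] * r[0] - p[1] * r[1] - p[2] * r[2] - p[3] * r[3],
            p[0] * r[1] + p[1] * r[0] + p[2] * r[3] - p[3] * r[2],
            p[0] * r[2] - p[1] * r[3] + p[2] * r[0] + p[3] * r[1],
            p[0] * r[3] + p[1] * r[2] - p[2] * r[1] + p[3] * r[0],
        ])
        q[t] /= np.linalg.norm(q[t])
    return q, w


def _assemble(accel_earth, q, params, rng, labels, meta):
    """Rotate Earth-frame specific force into the device frame; add noise."""
    n = len(accel_earth)
    dt = 1.0 / params.rate_hz
    g = np.array([0.0, 0.0, params.gravity])
    specific = accel_earth + g  # accelerometer measures a_lin + g (ENU, +g face up)
    rt = _quat_rotmat_t(q)
    a_dev = np.einsum("tij,tj->ti", rt, specific)
    a_dev += rng.normal(0.0, params.noise_sd, size=a_dev.shape)
    omega = meta.pop("_omega")
    omega = omega + rng.normal(0.0, params.noise_sd / 10.0, size=omega.shape)
    t = np.arange(n) * dt
    meta = dict(meta, true_quat=q)
    return ImuSeries(t=t, a=a_dev, omega=omega, rate_hz=params.rate_hz,
                     labels=labels, meta=meta)


def gen_static(duration_s: float, params: GaitParams | None = None, seed: int = 0) -> ImuSeries:
    """Device at rest in a random fixed orientation; labels all not-walking."""
    params = params or GaitParams()
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * params.rate_hz))
    q = np.tile(_random_unit_quat(rng), (n, 1))
    meta = {"_omega": np.zeros((n, 3)), "kind": "static"}
    return _assemble(np.zeros((n, 3)), q, params, rng, np.zeros(n, dtype=int), meta)


def gen_walking(duration_s: float, params: GaitParams | None = None, seed: int = 0) -> ImuSeries:
    """Walking trace with heel-strike comb; labels all walking.

    True step times (one per step cycle) are stored in
    ``meta["step_times"]``; the true step frequency in
    ``meta["step_freq_hz"]``.
    """
    params = params or GaitParams()
    if duration_s < 2.5:
        raise ValueError("walking segments must last at least one window (2.5 s)")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * params.rate_hz))
    dt = 1.0 / params.rate_hz
    t = np.arange(n) * dt
    f = params.step_freq_hz if params.step_freq_hz is not None else rng.uniform(1.5, 2.5)
    amp = params.impact_amp if params.impact_amp is not None else rng.uniform(2.0, 6.0)
    phase = rng.uniform(0, 2 * np.pi)
    # harmonic comb with decaying weights; raising the fundamental-aligned
    # cosine train sharpens the peaks into heel-strike-like impacts
    vert = np.zeros(n)
    for h in range(1, params.harmonics + 1):
        vert += (1.0 / h) * np.cos(2 * np.pi * h * f * t + h * phase)
    vert *= amp / np.max(np.abs(vert))
    sway_x = 0.25 * amp * np.sin(2 * np.pi * (f / 2.0) * t + phase)
    sway_y = 0.25 * amp * np.cos(2 * np.pi * (f / 2.0) * t + 1.3 * phase)
    accel_earth = np.stack([sway_x, sway_y, vert], axis=1)
    q, w = _drifting_orientation(n, dt, rng, params.orient_drift_deg_s)
    # gait also shakes the device: add a small periodic rate on top of drift
    w = w + 0.1 * np.stack([np.sin(2 * np.pi * f * t + phase)] * 3, axis=1)
    q, w = _integrate_given_rate(n, dt, w, q[0])
    step_phase = (f * t + phase / (2 * np.pi)) % 1.0
    step_times = t[1:][np.diff(step_phase) < 0]
    meta = {"_omega": w, "kind": "walking", "step_freq_hz": float(f),
            "step_times": step_times, "vertical_truth": vert}
    return _assemble(accel_earth, q, params, rng, np.ones(n, dtype=int), meta)


def _integrate_given_rate(n, dt, w, q0):
    q = np.empty((n, 4))
    q[0] = q0
    for t in range(1, n):
        ang = w[t] * dt
        theta = np.linalg.norm(ang)
        if theta < 1e-12:
            q[t] = q[t - 1]
            continue
        axis = ang / theta
        dq = np.concatenate([[np.cos(theta / 2)], np.sin(theta / 2) * axis])
        p, r = q[t - 1], dq
        q[t] = np.array([
            p[0] * r[0] - p[1] * r[1] - p[2] * r[2] - p[3] * r[3],
            p[0] * r[1] + p[1] * r[0] + p[2] * r[3] - p[3] * r[2],
            p[0] * r[2] - p[1] * r[3] + p[2] * r[0] + p[3] * r[1],
            p[0] * r[3] + p[1] * r[2] - p[2] * r[1] + p[3] * r[0],
        ])
        q[t] /= np.linalg.norm(q[t])
    return q, w


def gen_gesture(duration_s: float, params: GaitParams | None = None, seed: int = 0) -> ImuSeries:
    """Gesticulation: smooth aperiodic sub-3 Hz accelerations, labels 0."""
    params = params or GaitParams()
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * params.rate_hz))
    dt = 1.0 / params.rate_hz
    amp = params.impact_amp if params.impact_amp is not None else rng.uniform(2.0, 6.0)
    raw = rng.normal(0.0, 1.0, size=(n, 3))
    sos = _sig.butter(4, 3.0 / (params.rate_hz / 2.0), btype="low", output="sos")
    smooth = _sig.sosfilt(sos, raw, axis=0)
    rms = np.sqrt(np.mean(smooth ** 2))
    accel_earth = smooth * (0.5 * amp / (rms if rms > 0 else 1.0))
    q, w = _drifting_orientation(n, dt, rng, 3.0 * params.orient_drift_deg_s)
    meta = {"_omega": w, "kind": "gesture"}
    return _assemble(accel_earth, q, params, rng, np.zeros(n, dtype=int), meta)


_SEGMENT_GENS = {"walking": gen_walking, "gesture": gen_gesture, "static": gen_static}


def gen_record(seed: int = 0, duration_s: float | None = None,
               params: GaitParams | None = None, segments=None) -> ImuSeries:
    """One record: concatenated walking / gesture / static segments.

    ``segments`` may give an explicit list of ``(kind, seconds)``;
    otherwise 2–4 segments alternating walking and non-walking are drawn,
    5–15 s each (stop-and-go, so transition windows exist).  A fixed
    ``duration_s`` produces a single walking segment of that length.
    """
    params = params or GaitParams()
    rng = np.random.default_rng(seed)
    if segments is None:
        if duration_s is not None:
            segments = [("walking" if duration_s >= 2.5 else "static", duration_s)]
        else:
            kinds = ["walking", str(rng.choice(["gesture", "static"]))]
            if rng.random() < 0.5:
                kinds.append("walking")
            rng.shuffle(kinds)
            segments = [(k, float(rng.uniform(5.0, 15.0))) for k in kinds]
    parts, layout = [], []
    for i, (kind, dur) in enumerate(segments):
        parts.append(_SEGMENT_GENS[kind](dur, params,
                                         seed=int(seed * 1000 + i + 1) % (2 ** 31)))
        layout.append({"kind": kind, "duration_s": len(parts[-1]) / params.rate_hz})
    dt = 1.0 / params.rate_hz
    t = np.arange(sum(len(p) for p in parts)) * dt
    return ImuSeries(
        t=t,
        a=np.concatenate([p.a for p in parts]),
        omega=np.concatenate([p.omega for p in parts]),
        rate_hz=params.rate_hz,
        labels=np.concatenate([p.labels for p in parts]),
        meta={"segments": layout,
              "step_freqs": [p.meta.get("step_freq_hz") for p in parts]},
    )


def gen_dataset(out_dir, n_records: int = 10, params: GaitParams | None = None,
                seed: int = 0) -> dict:
    """Write ``n_records`` record CSVs plus a manifest.json of segment truth."""
    if n_records < 1:
        raise ValueError("need at least one record")
    params = params or GaitParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "n_records": n_records, "records": []}
    for i in range(n_records):
        rec = gen_record(seed=seed * 10007 + i, params=params)
        name = f"record_{i:03d}.csv"
        write_imu_csv(rec, out / name)
        manifest["records"].append({
            "file": name,
            "n_samples": len(rec),
            "duration_s": len(rec) / params.rate_hz,
            "segments": rec.meta["segments"],
        })
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
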