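"""Device attitude estimation from gyroscope and accelerometer readings.

The orientation of the phone relative to an ENU Earth frame (z up, gravity
reads +g on a face-up resting device) is tracked with a unit quaternion
``q = (q0, q1, q2, q3)`` that rotates sensor-frame vectors into the Earth
frame: ``v_E = q ⊗ v_S ⊗ q*``.

Two information sources are fused, magnetometer-free:

* gyroscope integration — ``q_t = q_{t-1} + ½ q_{t-1} ⊗ ω_t Δt`` with the
  angular rate embedded as the pure quaternion ``(0, ωx, ωy, ωz)``;
* a gravity-alignment correction — one normalized gradient-descent step on
  the misalignment between the gravity direction predicted from the current
  attitude and the (normalized) accelerometer reading.

The two are blended convexly with weight ``gamma``:

    q_t = q_{t-1} + γ (−μ ∇f / ‖∇f‖) + (1 − γ) ½ q_{t-1} ⊗ ω_t Δt

followed by renormalization.  With ``γ = 0`` the update is pure gyro
integration; with ``γ = 1`` it is pure gradient descent on the gravity
objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MadgwickConfig",
    "quat_product",
    "quat_conjugate",
    "quat_normalize",
    "quat_rotate",
    "quat_angle",
    "gradient_gravity_objective",
    "madgwick_step",
    "estimate_attitude",
    "project_acceleration",
]

IDENTITY_QUAT = np.array([1.0, 0.0, 0.0, 0.0])


def quat_product(p, q):
    """Hamilton product ``p ⊗ q`` of two 4-vectors.

    Inputs need not be unit quaternions; pure quaternions such as
    ``(0, ωx, ωy, ωz)`` are allowed.  The norm is multiplicative.
    """
    p0, p1, p2, p3 = p
    q0, q1, q2, q3 = q
    return np.array(
        [
            p0 * q0 - p1 * q1 - p2 * q2 - p3 * q3,
            p0 * q1 + p1 * q0 + p2 * q3 - p3 * q2,
            p0 * q2 - p1 * q3 + p2 * q0 + p3 * q1,
            p0 * q3 + p1 * q2 - p2 * q1 + p3 * q0,
        ]
    )


def quat_conjugate(q):
    """Conjugate ``q* = (q0, −q1, −q2, −q3)``."""
    q = np.asarray(q, dtype=float)
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_normalize(q):
    n = float(np.linalg.norm(q))
    if n == 0.0:
        raise ValueError("cannot normalize the zero quaternion")
    return np.asarray(q, dtype=float) / n


def quat_rotate(q, v):
    """Rotate 3-vector ``v`` by unit quaternion ``q``: ``q ⊗ (0,v) ⊗ q*``."""
    p = quat_product(quat_product(q, np.array([0.0, v[0], v[1], v[2]])), quat_conjugate(q))
    return p[1:]


def quat_angle(p, q):
    """Angle in radians between the rotations represented by p and q."""
    d = abs(float(np.dot(quat_normalize(p), quat_normalize(q))))
    return 2.0 * np.arccos(min(d, 1.0))


@dataclass
class MadgwickConfig:
    """Tunables of the attitude filter.

    gamma: convex blending weight of the gravity correction, in [0, 1].
    mu: gradient step size (> 0).  ``None`` selects an adaptive step
        ``max(Δt·‖ω‖, mu_floor)`` so the correction keeps pace with the
        angular rate but never stalls on a static device.
    dt: sampling period in seconds (0.01 at the nominal 100 Hz).
    q_init: initial orientation; ``"identity"`` or ``"accel"`` (bootstrap
        from the first accelerometer sample) or an explicit 4-vector.
    """

    gamma: float = 0.05
    mu: float | None = None
    mu_floor: float = 0.01
    dt: float = 0.01
    q_init: object = "identity"

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.mu is not None and self.mu <= 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")


def gradient_gravity_objective(q, a):
    """Gradient ∇f of the gravity-misalignment objective at quaternion q.

    The objective compares the gravity direction predicted in the sensor
    frame, ``q* ⊗ ĝ_E ⊗ q`` with ``ĝ_E = (0, 0, 0, 1)``, against the
    normalized accelerometer reading.  For a unit quaternion the predicted
    direction is the third row of the rotation matrix of q, giving the
    residual

        f(q) = [2(q1 q3 − q0 q2), 2(q0 q1 + q2 q3), 1 − 2(q1² + q2²)] − â

    and the returned 4-vector is Jᵀ f, the analytic gradient used by the
    filter's descent step.  Returns the zero vector at the minimum.
    """
    a = np.asarray(a, dtype=float)
    na = float(np.linalg.norm(a))
    if na == 0.0:
        raise ValueError("accelerometer reading has zero norm; gradient undefined")
    ax, ay, az = a / na
    q0, q1, q2, q3 = q
    f = np.array(
        [
            2.0 * (q1 * q3 - q0 * q2) - ax,
            2.0 * (q0 * q1 + q2 * q3) - ay,
            1.0 - 2.0 * (q1 * q1 + q2 * q2) - az,
        ]
    )
    jt = np.array(
        [
            [-2.0 * q2, 2.0 * q1, 0.0],
            [2.0 * q3, 2.0 * q0, -4.0 * q1],
            [-2.0 * q0, 2.0 * q3, -4.0 * q2],
            [2.0 * q1, 2.0 * q2, 0.0],
        ]
    )
    return jt @ f


def _step_mu(cfg: MadgwickConfig, omega) -> float:
    if cfg.mu is not None:
        return cfg.mu
    return max(cfg.dt * float(np.linalg.norm(omega)), cfg.mu_floor)


def madgwick_step(q_prev, omega, accel, cfg: MadgwickConfig):
    """One blended attitude update; returns a renormalized quaternion.

    When the gradient vanishes (device already aligned, or zero accel with
    ``γ > 0``) the correction term is skipped rather than dividing by zero.
    """
    q_prev = np.asarray(q_prev, dtype=float)
    omega = np.asarray(omega, dtype=float)
    integ = 0.5 * quat_product(q_prev, np.array([0.0, omega[0], omega[1], omega[2]])) * cfg.dt
    q = q_prev + (1.0 - cfg.gamma) * integ
    if cfg.gamma > 0.0:
        try:
            grad = gradient_gravity_objective(q_prev, accel)
        except ValueError:
            grad = np.zeros(4)
        ng = float(np.linalg.norm(grad))
        if ng > 1e-12:
            q = q + cfg.gamma * (-_step_mu(cfg, omega) * grad / ng)
    return quat_normalize(q)


def _initial_quaternion(cfg: MadgwickConfig, first_accel):
    if isinstance(cfg.q_init, str):
        if cfg.q_init == "identity":
            return IDENTITY_QUAT.copy()
        if cfg.q_init == "accel":
            return _accel_bootstrap(first_accel)
        raise ValueError(f"unknown q_init {cfg.q_init!r}")
    return quat_normalize(np.asarray(cfg.q_init, dtype=float))


def _accel_bootstrap(a):
    """Quaternion aligning the first accelerometer sample with Earth +z."""
    a = np.asarray(a, dtype=float)
    n = float(np.linalg.norm(a))
    if n == 0.0:
        return IDENTITY_QUAT.copy()
    v = a / n
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(v, z))
    axis = np.cross(v, z)
    s = float(np.linalg.norm(axis))
    if s < 1e-12:
        if c > 0:
            return IDENTITY_QUAT.copy()
        return np.array([0.0, 1.0, 0.0, 0.0])  # 180° about x
    axis = axis / s
    half = 0.5 * np.arctan2(s, c)
    return np.array(
        [np.cos(half), np.sin(half) * axis[0], np.sin(half) * axis[1], np.sin(half) * axis[2]]
    )


def estimate_attitude(series, cfg: MadgwickConfig | None = None) -> np.ndarray:
    """Per-sample attitude track for an ImuSeries; shape (n, 4), unit rows."""
    if cfg is None:
        cfg = MadgwickConfig()
    a = np.asarray(series.a, dtype=float)
    w = np.asarray(series.omega, dtype=float)
    n = len(a)
    track = np.empty((n, 4))
    q = _initial_quaternion(cfg, a[0])
    track[0] = q
    for t in range(1, n):
        q = madgwick_step(q, w[t], a[t], cfg)
        track[t] = q
    return track


def project_acceleration(series, track) -> np.ndarray:
    """Earth-frame acceleration ``a_E,t = q_t ⊗ a_t ⊗ q_t*`` per sample.

    Uses the rotation-matrix form of the sandwich product, vectorized over
    samples; per-sample norm is preserved exactly up to roundoff.
    """
    a = np.asarray(series.a, dtype=float)
    q = np.asarray(track, dtype=float)
    if len(a) != len(q):
        raise ValueError(f"series length {len(a)} != track length {len(q)}")
    q0, q1, q2, q3 = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    # rows of R(q): v_E = R v_S
    r00 = 1 - 2 * (q2 * q2 + q3 * q3)
    r01 = 2 * (q1 * q2 - q0 * q3)
    r02 = 2 * (q1 * q3 + q0 * q2)
    r10 = 2 * (q1 * q2 + q0 * q3)
    r11 = 1 - 2 * (q1 * q1 + q3 * q3)
    r12 = 2 * (q2 * q3 - q0 * q1)
    r20 = 2 * (q1 * q3 - q0 * q2)
    r21 = 2 * (q2 * q3 + q0 * q1)
    r22 = 1 - 2 * (q1 * q1 + q2 * q2)
    ax, ay, az = a[:, 0], a[:, 1], a[:, 2]
    return np.stack(
        [
            r00 * ax + r01 * ay + r02 * az,
            r10 * ax + r11 * ay + r12 * az,
            r20 * ax + r21 * ay + r22 * az,
        ],
        axis=1,
    )
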