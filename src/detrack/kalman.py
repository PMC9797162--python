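"""Constant-acceleration Kalman filter for ground-truth trajectory estimation.

On clinical projections the true tumor position is unknown, so an
estimated ground truth is obtained by filtering the tracked positions
with a Kalman filter whose per-axis state is [position, velocity,
acceleration].  Prediction uses ``x_kp = F x_{k-1} + G u`` and
``P_kp = F P_{k-1} F' + Q``; the correction is the standard gain /
state / covariance sequence ``K = P_kp H' (H P_kp H' + R)^-1``,
``x = x_kp + K (z - H x_kp)``, ``P = (I - K H) P_kp``.  Missing frames
receive prediction-only updates.

The process noise follows a white-jerk model with spectral density
``q`` (mm^2/s^5).  The default ``q = 1000`` is matched to respiratory
kinematics: a 10 mm / 4 s breathing cycle carries jerk of roughly
``A (2 pi / T)^3 ~ 40 mm/s^3``, and a white-jerk density of order
``jerk^2 x correlation time ~ 1.5e3`` lets the filter follow the
turning points instead of lagging them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import GroundTruthTrajectory

__all__ = ["KFConfig", "KFState", "kf_predict", "kf_update", "estimate_ground_truth"]


def _ca_transition(dt: float) -> np.ndarray:
    return np.array([[1.0, dt, dt * dt / 2.0], [0.0, 1.0, dt], [0.0, 0.0, 1.0]])


def _white_jerk_q(dt: float, q: float) -> np.ndarray:
    return q * np.array(
        [
            [dt**5 / 20.0, dt**4 / 8.0, dt**3 / 6.0],
            [dt**4 / 8.0, dt**3 / 3.0, dt**2 / 2.0],
            [dt**3 / 6.0, dt**2 / 2.0, dt],
        ]
    )


def _block_diag(a: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((a.shape[0] * n, a.shape[1] * n))
    for i in range(n):
        out[i * a.shape[0] : (i + 1) * a.shape[0], i * a.shape[1] : (i + 1) * a.shape[1]] = a
    return out


@dataclass
class KFConfig:
    """Filter matrices for a 2-axis [p, v, a] state (6 total states).

    Any matrix left as None is built from ``dt``, ``q`` (white-jerk
    spectral density, mm^2/s^5), ``r_var`` (observation noise variance,
    mm^2) and ``p0`` (initial covariance diagonal).  ``u``/``G`` model a
    dynamics input and default to zero.
    """

    dt: float = 1.0 / 15.0
    q: float = 1000.0
    r_var: float = 1.0
    p0: float = 1.0e4
    n_axes: int = 2
    F: np.ndarray | None = None
    G: np.ndarray | None = None
    u: np.ndarray | None = None
    Q: np.ndarray | None = None
    H: np.ndarray | None = None
    R: np.ndarray | None = None
    P0: np.ndarray | None = None
    joseph: bool = False  # numerically robust covariance update, off by default

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        n = self.n_axes
        custom_f = self.F is not None
        if self.F is None:
            self.F = _block_diag(_ca_transition(self.dt), n)
        if self.Q is None:
            if custom_f:
                raise ValueError("provide Q explicitly when F is customized")
            self.Q = _block_diag(_white_jerk_q(self.dt, self.q), n)
        self.F = np.asarray(self.F, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        dim = self.F.shape[0]
        if self.G is None:
            self.G = np.zeros((dim, 1))
        if self.u is None:
            self.u = np.zeros(self.G.shape[1])
        if self.H is None:
            H = np.zeros((n, dim))
            for ax in range(n):
                H[ax, ax * (dim // n)] = 1.0
            self.H = H
        if self.R is None:
            self.R = self.r_var * np.eye(self.H.shape[0])
        if self.P0 is None:
            self.P0 = self.p0 * np.eye(dim)
        for name in ("Q", "R", "P0"):
            m = getattr(self, name)
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
            if np.min(np.linalg.eigvalsh(m)) < -1e-10:
                raise ValueError(f"{name} must be positive semi-definite")


@dataclass
class KFState:
    x: np.ndarray
    P: np.ndarray
    k: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.P))):
            raise ValueError("KF state must be finite")


def kf_predict(state: KFState, cfg: KFConfig) -> tuple[np.ndarray, np.ndarray]:
    """One prediction step: ``x_kp = F x + G u``, ``P_kp = F P F' + Q``."""
    x_kp = cfg.F @ state.x + cfg.G @ cfg.u
    P_kp = cfg.F @ state.P @ cfg.F.T + cfg.Q
    return x_kp, P_kp


def kf_update(x_kp: np.ndarray, P_kp: np.ndarray, z_k, cfg: KFConfig, k: int = 0) -> KFState:
    """Measurement correction: gain, then state, then covariance."""
    z_k = np.atleast_1d(np.asarray(z_k, dtype=float))
    H, R = cfg.H, cfg.R
    S = H @ P_kp @ H.T + R
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > 1e14:
        raise np.linalg.LinAlgError("singular innovation covariance")
    K = P_kp @ H.T @ np.linalg.inv(S)
    x = x_kp + K @ (z_k - H @ x_kp)
    I = np.eye(P_kp.shape[0])
    if cfg.joseph:
        P = (I - K @ H) @ P_kp @ (I - K @ H).T + K @ R @ K.T
    else:
        P = (I - K @ H) @ P_kp
    P = 0.5 * (P + P.T)  # keep symmetric against roundoff
    return KFState(x=x, P=P, k=k)


def _measurements_from(track) -> np.ndarray:
    """(n, 2) measurement array with NaN marking missing frames."""
    if hasattr(track, "positions"):
        z = np.asarray(track.positions(), dtype=float)
        if hasattr(track, "missing"):
            z = z.copy()
            z[np.asarray(track.missing, dtype=bool)] = np.nan
        return z
    return np.asarray(track, dtype=float)


def estimate_ground_truth(track, cfg: KFConfig | None = None) -> GroundTruthTrajectory:
    """Forward-filter tracked positions into an estimated ground truth.

    ``track`` is a :class:`~detrack.tracking.TrackResult` or an (n, 2)
    array with NaN rows for missing frames.  The filter initializes at
    the first valid measurement (zero velocity and acceleration, broad
    prior); missing frames get prediction-only updates.  Frames before
    the first valid measurement repeat it.
    """
    cfg = cfg or KFConfig()
    z = _measurements_from(track)
    if z.ndim != 2 or z.shape[1] != cfg.n_axes:
        raise ValueError(f"expected (n, {cfg.n_axes}) measurements, got {z.shape}")
    valid = np.all(np.isfinite(z), axis=1)
    if not np.any(valid):
        raise ValueError("all frames missing: cannot estimate ground truth")
    n = len(z)
    first = int(np.argmax(valid))
    dim = cfg.F.shape[0]
    block = dim // cfg.n_axes
    x0 = np.zeros(dim)
    for ax in range(cfg.n_axes):
        x0[ax * block] = z[first, ax]
    state = KFState(x=x0, P=cfg.P0.copy(), k=first)
    est = np.empty((n, cfg.n_axes))
    est[: first + 1] = z[first]
    for k in range(first + 1, n):
        x_kp, P_kp = kf_predict(state, cfg)
        if valid[k]:
            state = kf_update(x_kp, P_kp, z[k], cfg, k=k)
        else:
            state = KFState(x=x_kp, P=0.5 * (P_kp + P_kp.T), k=k)
        est[k] = cfg.H @ state.x
    times = np.asarray(getattr(track, "frame_index", np.arange(n)), dtype=float) * cfg.dt
    angles = np.asarray(getattr(track, "angle_deg", np.full(n, np.nan)), dtype=float)
    return GroundTruthTrajectory(times, angles, est[:, 0], est[:, 1])
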