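"""Streaming Kalman filter for per-sample smoothing of digitized biosignals.

The default model is a scalar random walk observed in white noise
(A = 1, B = 0, C = 1), the simplest state-space model consistent with the
predict/update recursion:

    x̂ₖ⁻ = A·x̂ₖ₋₁ + B·uₖ₋₁            (prediction)
    Pₖ⁻ = A·Pₖ₋₁·Aᵀ + Q               (predicted covariance)
    Kₖ  = Pₖ⁻·Cᵀ·(C·Pₖ⁻·Cᵀ + R)⁻¹     (gain)
    x̂ₖ  = x̂ₖ⁻ + Kₖ·(zₖ − C·x̂ₖ⁻)      (innovation update)
    Pₖ  = Pₖ⁻ − Kₖ·C·Pₖ⁻              (posterior covariance)

Q defaults to 1 μV² and R to 225 μV² (the square of the generator's default
white-noise sd), trading tracking speed against smoothing.  Scalars and
matrices are both accepted; scalars take a fast path used by the per-trace
filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np


@dataclass
class KalmanModel:
    """State-space matrices/scalars plus initial conditions.

    ``x0=None`` seeds the estimate with the first sample; ``p0=None`` uses R.
    """

    a: float | np.ndarray = 1.0
    b: float | np.ndarray = 0.0
    c: float | np.ndarray = 1.0
    q: float | np.ndarray = 1.0
    r: float | np.ndarray = 225.0
    x0: float | np.ndarray | None = None
    p0: float | np.ndarray | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if np.ndim(self.q) == 0:
            if self.q < 0:
                raise ValueError("Q must be >= 0")
            if np.ndim(self.r) == 0 and self.r <= 0:
                raise ValueError("R must be > 0")
            if self.p0 is not None and np.ndim(self.p0) == 0 and self.p0 < 0:
                raise ValueError("P0 must be >= 0")
        else:
            for name in ("q", "p0"):
                m = getattr(self, name)
                if m is None:
                    continue
                m = np.atleast_2d(m)
                if np.any(np.linalg.eigvalsh((m + m.T) / 2) < -1e-12):
                    raise ValueError(f"{name.upper()} must be positive semidefinite")


def _is_scalar(*xs) -> bool:
    return all(np.ndim(x) == 0 for x in xs)


def kalman_predict(model: KalmanModel, x_prev, p_prev,
                   u=0.0) -> Tuple[np.ndarray | float, np.ndarray | float]:
    """One prediction step: x⁻ = A·x + B·u, P⁻ = A·P·Aᵀ + Q."""
    a, b, q = model.a, model.b, model.q
    if _is_scalar(a, b, q, x_prev, p_prev, u):
        return a * x_prev + b * u, a * p_prev * a + q
    a_m = np.atleast_2d(a)
    b_m = np.atleast_2d(b)
    x = np.atleast_1d(x_prev)
    u_v = np.atleast_1d(u)
    p = np.atleast_2d(p_prev)
    q_m = np.atleast_2d(q)
    if a_m.shape[1] != x.shape[0] or p.shape != (x.shape[0], x.shape[0]):
        raise ValueError("inconsistent shapes in kalman_predict")
    x_pred = a_m @ x + b_m @ u_v
    p_pred = a_m @ p @ a_m.T + q_m
    return x_pred, p_pred


def kalman_update(model: KalmanModel, x_pred, p_pred,
                  z) -> Tuple[np.ndarray | float, np.ndarray | float,
                              np.ndarray | float]:
    """One innovation update; returns (x_post, P_post, gain).

    For a scalar model with C = 1 the gain lies in [0, 1].  A numerically
    singular innovation covariance is rejected.
    """
    c, r = model.c, model.r
    if _is_scalar(c, r, x_pred, p_pred, z):
        s = c * p_pred * c + r
        if s <= 0 or not np.isfinite(s):
            raise ValueError("singular innovation covariance")
        k = p_pred * c / s
        x_post = x_pred + k * (z - c * x_pred)
        p_post = p_pred - k * c * p_pred
        return x_post, p_post, k
    c_m = np.atleast_2d(c)
    x = np.atleast_1d(x_pred)
    p = np.atleast_2d(p_pred)
    z_v = np.atleast_1d(z)
    r_m = np.atleast_2d(r)
    s = c_m @ p @ c_m.T + r_m
    if np.linalg.cond(s) > 1e12:
        raise ValueError("singular innovation covariance")
    k = p @ c_m.T @ np.linalg.inv(s)
    x_post = x + k @ (z_v - c_m @ x)
    p_post = p - k @ c_m @ p
    return x_post, p_post, k


def kalman_filter_trace(series: np.ndarray, model: KalmanModel) -> np.ndarray:
    """Filter a 1-D series with one predict–update cycle per sample.

    Output has the same length as the input.  The scalar fast path
    precomputes nothing: the covariance recursion is data-independent but the
    loop is cheap at trial lengths of a few thousand samples.
    """
    z = np.asarray(series, dtype=float)
    if z.ndim != 1 or z.size == 0:
        raise ValueError("input series must be non-empty and 1-D")
    model.validate()
    if not _is_scalar(model.a, model.b, model.c, model.q, model.r):
        raise ValueError("kalman_filter_trace supports scalar models; use "
                         "kalman_predict/kalman_update directly for matrix models")
    a, c, q, r = model.a, model.c, model.q, model.r
    x = float(z[0]) if model.x0 is None else float(model.x0)
    p = float(r) if model.p0 is None else float(model.p0)
    out = np.empty_like(z)
    for i in range(z.size):
        x_pred = a * x
        p_pred = a * p * a + q
        s = c * p_pred * c + r
        k = p_pred * c / s
        x = x_pred + k * (z[i] - c * x_pred)
        p = p_pred - k * c * p_pred
        out[i] = x
    return out
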