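"""Vectorized unit-quaternion helpers.

Quaternions are stored scalar-first, ``q = (w, x, y, z)``, and represent
head-to-earth rotations: ``v_earth = q * v_head * q^-1``.  These routines are
kept free of scipy so that the particle-filter inner loop (which rotates an
ensemble of a few hundred quaternions every 10 ms step) stays cheap.
"""

from __future__ import annotations

import numpy as np


def qmul(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product, broadcasting over leading axes."""
    w1, x1, y1, z1 = np.moveaxis(q1, -1, 0)
    w2, x2, y2, z2 = np.moveaxis(q2, -1, 0)
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def qconj(q: np.ndarray) -> np.ndarray:
    out = np.array(q, copy=True)
    out[..., 1:] *= -1.0
    return out


def qnormalize(q: np.ndarray) -> np.ndarray:
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def qrotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) ``v`` by quaternion(s) ``q`` (head -> earth)."""
    qv = q[..., 1:]
    w = q[..., :1]
    t = 2.0 * np.cross(qv, v)
    return v + w * t + np.cross(qv, t)


def qrotate_inv(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate by the inverse of ``q`` (earth -> head)."""
    return qrotate(qconj(q), v)


def from_rotvec(rv: np.ndarray) -> np.ndarray:
    """Quaternion of a rotation vector (axis * angle, rad)."""
    rv = np.asarray(rv, dtype=float)
    angle = np.linalg.norm(rv, axis=-1, keepdims=True)
    half = 0.5 * angle
    # sin(x)/x with a series fallback near zero
    small = angle < 1e-8
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(small, 0.5 - angle**2 / 48.0, np.sin(half) / np.where(angle == 0, 1.0, angle))
    return np.concatenate([np.cos(half), k * rv], axis=-1)


def identity(shape: tuple[int, ...] = ()) -> np.ndarray:
    q = np.zeros(shape + (4,))
    q[..., 0] = 1.0
    return q


def qderiv(q: np.ndarray, omega_head: np.ndarray) -> np.ndarray:
    """dq/dt for head->earth quaternion with body angular velocity (head frame)."""
    omega_q = np.concatenate([np.zeros(omega_head.shape[:-1] + (1,)), omega_head], axis=-1)
    return 0.5 * qmul(q, omega_q)
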