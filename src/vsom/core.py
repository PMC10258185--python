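"""Shared containers for stimuli, perception traces and conflict traces.

Conventions used throughout the package
---------------------------------------
* Head frame: right-handed, x naso-occipital (forward), y to the left,
  z up through the crown.
* Earth gravity is ``(0, 0, -G)`` with ``G = 9.81 m s^-2``; specific force is
  ``f = a - g``, so an upright stationary head senses ``+G`` on head z.
* All time series are uniformly sampled, ``3 x N`` arrays on a shared grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: standard gravity magnitude, m s^-2
G = 9.81

#: default integration step, s
DEFAULT_DT = 0.01

#: default session length, s
DEFAULT_DURATION = 200.0


def _check_grid(t: np.ndarray) -> float:
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time grid must be 1-D with at least two samples")
    dt = np.diff(t)
    if not np.all(dt > 0):
        raise ValueError("time grid must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
        raise ValueError("time grid must be uniform")
    return float(dt[0])


@dataclass
class MotionStimulus:
    """Head-frame vestibular input for one motion paradigm.

    Attributes
    ----------
    t : (N,) seconds, uniform grid.
    f_h : (3, N) specific force in the head frame, m s^-2.
    omega_h : (3, N) angular velocity in the head frame, rad s^-1.
    paradigm : label of the generating paradigm.
    params : parameter record of the paradigm (for provenance).
    """

    t: np.ndarray
    f_h: np.ndarray
    omega_h: np.ndarray
    paradigm: str = "custom"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f_h = np.asarray(self.f_h, dtype=float)
        self.omega_h = np.asarray(self.omega_h, dtype=float)
        self.dt = _check_grid(self.t)
        n = self.t.size
        if self.f_h.shape != (3, n) or self.omega_h.shape != (3, n):
            raise ValueError("f_h and omega_h must be 3 x N on the time grid")
        if not (np.isfinite(self.f_h).all() and np.isfinite(self.omega_h).all()):
            raise ValueError("stimulus contains non-finite samples")

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class PerceptionTrace:
    """Model state estimates on the stimulus grid.

    ``g_hat`` follows the sensed-vertical convention of the stimulus: at
    upright rest it equals ``(0, 0, +9.81)``.  ``theta_hat`` is the estimated
    head-to-earth orientation as scalar-first unit quaternions, ``(4, N)``.
    """

    t: np.ndarray
    g_hat: np.ndarray
    a_hat: np.ndarray
    v_hat: np.ndarray
    w_hat: np.ndarray
    theta_hat: np.ndarray

    def roll_percept(self) -> np.ndarray:
        """Perceived roll (tilt of the subjective vertical about head x), rad."""
        return np.arctan2(self.g_hat[1], self.g_hat[2])

    def tilt_percept(self) -> np.ndarray:
        """Perceived tilt of the subjective vertical from the head z axis, rad."""
        gxy = np.hypot(self.g_hat[0], self.g_hat[1])
        return np.arctan2(gxy, self.g_hat[2])

    def yaw_velocity_percept(self) -> np.ndarray:
        """Perceived yaw velocity (head z component of w_hat), rad s^-1."""
        return self.w_hat[2]


@dataclass
class ConflictTrace:
    """Named sensory-conflict series, one ``(3, N)`` array per conflict type."""

    t: np.ndarray
    conflicts: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        n = np.asarray(self.t).size
        for key, series in self.conflicts.items():
            if np.shape(series) != (3, n):
                raise ValueError(f"conflict {key!r} must be 3 x N")

    def norms(self) -> dict[str, np.ndarray]:
        """Per-sample Euclidean norm of each conflict type."""
        return {k: np.linalg.norm(v, axis=0) for k, v in self.conflicts.items()}

    def keys(self):
        return self.conflicts.keys()

    def __getitem__(self, key: str) -> np.ndarray:
        return self.conflicts[key]
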