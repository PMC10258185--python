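"""Subjective Vertical Model (SVM).

The SVM resolves the gravito-inertial ambiguity by frequency segregation: the
sensed specific force is low-pass filtered into a sensed gravity vector
(Mayne equation) and the remainder is the sensed acceleration.  A sensing
stage A, a conflict/feedback gain stage B and a structurally identical
internal tracking stage C form the model:

* stage A -- semicircular canals as a first-order high-pass
  ``s tau_ssc / (1 + s tau_ssc)`` applied to head angular velocity, and the
  Mayne equation

      d g_hs / dt = (f_h - g_hs) / tau_lp  -  omega_hs x g_hs

  with the sensed acceleration ``a_hs = f_h - g_hs``;
* conflicts -- ``c_g = g_hs - g_hat``, ``c_a = a_hs - a_hat`` and
  ``c_w = omega_hs - omega_hs_hat``;
* stage B -- integral gains ``K_gc / s`` and ``K_ac / s`` on the gravity and
  acceleration conflicts produce the internally estimated specific force
  ``f_hat``; the angular-velocity conflict is fed back proportionally
  (velocity storage): ``omega_hat = omega_hs + K_wc * c_w``;
* stage C -- an internal copy of stage A driven by ``f_hat`` and
  ``omega_hat``.

For constant-rate yaw the model yields an exponentially decaying yaw-velocity
percept with time constant ``tau_ssc * (1 + K_wc)``; for translational input
the conflicts follow the band-pass/high-pass transfer functions returned by
:func:`svm_conflict_tf`.

The low-pass time constants and conflict gains may differ between the
horizontal plane (xy) and the vertical axis (z); the split is applied
component-wise in the head frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import G, ConflictTrace, MotionStimulus, PerceptionTrace
from .presets import preset_dict


@dataclass
class SVMParams:
    """SVM parameter set (see Table of published presets in data/presets.yaml)."""

    tau_ssc: float = 5.7
    tau_lp_xy: float = 1.23
    tau_lp_z: float = 1.23
    K_ac_xy: float = 0.005
    K_ac_z: float = 0.005
    K_gc_xy: float = 1.88
    K_gc_z: float = 1.88
    K_wc: float = 2.28

    def __post_init__(self) -> None:
        if self.tau_ssc <= 0 or self.tau_lp_xy <= 0 or self.tau_lp_z <= 0:
            raise ValueError("time constants must be positive")
        for gain in (self.K_ac_xy, self.K_ac_z, self.K_gc_xy, self.K_gc_z, self.K_wc):
            if not np.isfinite(gain):
                raise ValueError("gains must be finite")

    @classmethod
    def preset(cls, name: str) -> "SVMParams":
        return cls(**preset_dict("svm", name))

    @property
    def tau_lp(self) -> np.ndarray:
        return np.array([self.tau_lp_xy, self.tau_lp_xy, self.tau_lp_z])

    @property
    def K_ac(self) -> np.ndarray:
        return np.array([self.K_ac_xy, self.K_ac_xy, self.K_ac_z])

    @property
    def K_gc(self) -> np.ndarray:
        return np.array([self.K_gc_xy, self.K_gc_xy, self.K_gc_z])


# state layout: [z_c(3), g_hs(3), z_ci(3), f_hat(3), g_hat(3), v_hat(3), q(4)]
_NSTATE = 22


def _initial_state() -> np.ndarray:
    x = np.zeros(_NSTATE)
    x[3:6] = (0.0, 0.0, G)   # sensed gravity
    x[9:12] = (0.0, 0.0, G)  # internally estimated specific force
    x[12:15] = (0.0, 0.0, G)  # internally estimated gravity
    x[18] = 1.0              # identity orientation quaternion
    return x


def svm_simulate(stim: MotionStimulus, p: SVMParams) -> tuple[PerceptionTrace, ConflictTrace]:
    """Integrate the SVM over a stimulus (RK4 at the stimulus step, inputs
    interpolated linearly at the half steps).

    The initial internal state is upright rest: sensed and estimated gravity
    at ``(0, 0, 9.81)`` in the head frame, all other states zero.
    """
    from ._kernels import svm_rk4

    t = stim.t
    f = np.ascontiguousarray(stim.f_h.T)
    w = np.ascontiguousarray(stim.omega_h.T)
    n = t.size
    dt = stim.dt

    xs = svm_rk4(
        f, w, dt, p.tau_ssc, p.tau_lp, p.K_ac, p.K_gc, p.K_wc / (1.0 + p.K_wc),
        _initial_state(),
    )
    if xs.shape[0] < n:
        raise FloatingPointError(
            f"SVM state became non-finite at t={t[xs.shape[0]]:.3f} s"
        )

    z_c = xs[:, 0:3]
    g_hs = xs[:, 3:6]
    z_ci = xs[:, 6:9]
    f_hat = xs[:, 9:12]
    g_hat = xs[:, 12:15]
    v_hat = xs[:, 15:18]
    q = xs[:, 18:22]

    w_hs = w - z_c
    w_hat = w_hs + (p.K_wc / (1.0 + p.K_wc)) * z_ci
    w_hs_hat = w_hat - z_ci
    a_hs = f - g_hs
    a_hat = f_hat - g_hat

    percept = PerceptionTrace(
        t=t,
        g_hat=g_hat.T,
        a_hat=a_hat.T,
        v_hat=v_hat.T,
        w_hat=w_hat.T,
        theta_hat=q.T,
    )
    conflicts = ConflictTrace(
        t=t,
        conflicts={
            "c_g": (g_hs - g_hat).T,
            "c_a": (a_hs - a_hat).T,
            "c_w": (w_hs - w_hs_hat).T,
        },
    )
    return percept, conflicts


def svm_conflict_tf(
    p: SVMParams, which: str = "c_g", axis: str = "xy"
) -> tuple[np.ndarray, np.ndarray]:
    """Linearized conflict transfer function for translational input.

    Returns ``(num, den)`` polynomial coefficients in ``s`` (highest power
    first) of

        c_g / f = s / (tau_lp s^2 + (1 + K_ac tau_lp) s + K_gc)
        c_a / f = tau_lp s^2 / (same denominator)
    """
    if which not in ("c_g", "c_a"):
        raise ValueError("which must be 'c_g' or 'c_a'")
    if axis not in ("xy", "z"):
        raise ValueError("axis must be 'xy' or 'z'")
    tau = p.tau_lp_xy if axis == "xy" else p.tau_lp_z
    k_a = p.K_ac_xy if axis == "xy" else p.K_ac_z
    k_g = p.K_gc_xy if axis == "xy" else p.K_gc_z
    den = np.array([tau, 1.0 + k_a * tau, k_g])
    num = np.array([1.0, 0.0]) if which == "c_g" else np.array([tau, 0.0, 0.0])
    return num, den


def svm_evar_time_constant(
    p: SVMParams,
    rate: float = 30.0,
    duration: float = 120.0,
    dt: float = 0.01,
    fit_window: tuple[float, float] = (2.0, 100.0),
    ramp: float = 1.0,
) -> float:
    """Fitted decay time constant (s) of the yaw-velocity percept under EVAR.

    Simulates a constant-rate earth-vertical yaw step, fits a decaying
    exponential to the yaw percept from shortly after the rotation onset and
    returns the fitted time constant.  Raises ``RuntimeError`` for a
    non-decaying percept.
    """
    from .analysis import fit_time_constant
    from .stimuli import make_paradigm

    stim = make_paradigm("EVAR", duration=duration, dt=dt, rate=rate, ramp=ramp)
    percept, _ = svm_simulate(stim, p)
    y = percept.yaw_velocity_percept()
    lo = ramp + fit_window[0]
    hi = min(ramp + fit_window[1], duration)
    fit = fit_time_constant(stim.t, y, form="decay", window=(lo, hi))
    return 1.0 / fit.b
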