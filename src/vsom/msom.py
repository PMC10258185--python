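"""Multi-Sensory Observer Model (MSOM).

A classical observer: sensory afferents (otoliths as unity transfer
functions, semicircular canals as a first-order high-pass) are compared with
the output of an internal model of those sensors, and the resulting conflicts
drive the state estimates.

Conflicts
---------
* ``c_o``  -- otolith magnitude conflict, ``f_h - f_hat_h`` (m s^-2);
* ``c_oa`` -- otolith angle conflict, the normalized cross product of the
  predicted and sensed specific force (sine of the angle between them, rad);
* ``c_w``  -- angular velocity conflict, sensed minus internally predicted
  canal output (rad s^-1).

Structure
---------
The estimated acceleration is algebraic in the magnitude conflict,
``a_hat = K_a c_o``; the angle conflict feeds the angular-velocity estimate
through ``K_fw`` and the gravity rotation through ``K_f``; the
angular-velocity conflict feeds the angular-velocity estimate through
``K_w``.  The estimated gravity has fixed magnitude ``9.81 m s^-2`` and is
updated by rotation only:

    omega_hat = (K_w (c_w) + K_fw c_oa is resolved algebraically)
    d g_hat / dt = (K_f c_oa - K_1 omega_hat) x g_hat,
    K_1 = (K_wf K_w + 1) / K_w

The coupling factor ``K_1`` exactly compensates the steady-state gain
``K_w / (1 + K_w)`` of the conflict loop when ``K_wf = 1``, so the gravity
estimate is rotated with unit gain by a sustained real rotation -- this is
what lets the observer discriminate a roll signal from an acceleration in
every tuning.  With ``K_fw = 0`` the lateral linearization reduces to

    c_o / f  = s / (s (1 - K_a) + K_f)
    c_oa / f = -(c_o / f) / |g|

and for vertical input the conflict gain is the frequency-invariant
``1 / (1 - K_a)``.  These closed forms are the authoritative behavioural
constraints the state-space reconstruction is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import G, ConflictTrace, MotionStimulus, PerceptionTrace
from .presets import preset_dict


@dataclass
class MSOMParams:
    tau_ssc: float = 5.7
    K_a: float = -3.2
    K_f: float = 15.4
    K_fw: float = 0.0
    K_w: float = 2.28
    K_wf: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_ssc <= 0:
            raise ValueError("tau_ssc must be positive")
        if self.K_w == 0:
            raise ValueError("K_w must be non-zero (K_1 undefined)")
        if self.K_a == 1.0:
            raise ValueError("K_a = 1 makes the otolith loop singular")

    @classmethod
    def preset(cls, name: str) -> "MSOMParams":
        return cls(**preset_dict("msom", name))

    @property
    def K_1(self) -> float:
        return (self.K_wf * self.K_w + 1.0) / self.K_w


# state layout: [z_c(3), z_ci(3), g_hat(3), v_hat(3), q(4)]
_NSTATE = 16


def _initial_state() -> np.ndarray:
    x = np.zeros(_NSTATE)
    x[6:9] = (0.0, 0.0, G)
    x[12] = 1.0
    return x


def msom_simulate(stim: MotionStimulus, p: MSOMParams) -> tuple[PerceptionTrace, ConflictTrace]:
    """Integrate the MSOM over a stimulus (RK4 at the stimulus step).

    ``|g_hat| = 9.81`` is enforced exactly at every stored sample (the update
    is a pure rotation; the residual RK4 norm drift is projected out each
    step).  A vanishing sensed or predicted specific force makes the otolith
    angle conflict undefined and aborts the run.
    """
    from ._kernels import msom_rk4

    t = stim.t
    f = np.ascontiguousarray(stim.f_h.T)
    w = np.ascontiguousarray(stim.omega_h.T)
    n = t.size
    dt = stim.dt

    xs = msom_rk4(
        f, w, dt, p.tau_ssc, p.K_a, p.K_f, p.K_fw, p.K_w, p.K_1, _initial_state()
    )
    if xs.shape[0] < n:
        raise FloatingPointError(
            f"MSOM state became non-finite or geometry degenerate at "
            f"t={t[xs.shape[0]]:.3f} s"
        )

    # recompute algebraic signals on the stored trajectory (vectorized)
    z_c = xs[:, 0:3]
    z_ci = xs[:, 3:6]
    g_hat = xs[:, 6:9]
    v_hat = xs[:, 9:12]
    q = xs[:, 12:16]

    w_hs = w - z_c
    c_o = (f - g_hat) / (1.0 - p.K_a)
    a_hat = p.K_a * c_o
    f_hat = f - c_o
    fn = np.linalg.norm(f, axis=1, keepdims=True)
    fhn = np.linalg.norm(f_hat, axis=1, keepdims=True)
    c_oa = np.cross(f_hat, f) / (fn * fhn)
    w_hat = (p.K_w * (w_hs + z_ci) + p.K_fw * c_oa) / (1.0 + p.K_w)
    w_hs_hat = w_hat - z_ci

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
            "c_o": c_o.T,
            "c_oa": c_oa.T,
            "c_w": (w_hs - w_hs_hat).T,
        },
    )
    return percept, conflicts


def msom_vertical_gain(p: MSOMParams) -> float:
    """Frequency-invariant vertical otolith-magnitude conflict gain,
    ``1 / (1 - K_a)``."""
    return 1.0 / (1.0 - p.K_a)


def msom_lateral_tf(p: MSOMParams) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Linearized lateral conflict transfer functions (valid for ``K_fw = 0``).

    Returns ``{"c_o": (num, den), "c_oa": (num, den)}`` with polynomial
    coefficients in ``s``:

        c_o / f  = s / (s (1 - K_a) + K_f)
        c_oa / f = -(c_o / f) / |g|
    """
    den = np.array([1.0 - p.K_a, p.K_f])
    return {
        "c_o": (np.array([1.0, 0.0]), den),
        "c_oa": (np.array([-1.0 / G, 0.0]), den),
    }
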