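"""Vestibular stimulus generation.

Motion paradigms are modelled as a hypothetical three-joint motion platform
(yaw / tilt / roll with translational offsets, standard serial-chain
kinematics).  Forward kinematics give the head position and orientation over
time; the head-frame specific force and angular velocity follow by
differentiation.  Seven paradigms from the motion-perception and
motion-sickness literature are provided:

====== =====================================================================
EVAR   earth-vertical axis rotation: upright, step to constant yaw
OVAR   off-vertical axis rotation: body axis tilted, constant spin about it
CENTRIFUGE  upright at a radius from the rotation centre, constant yaw
CCCP   cross-coupled Coriolis: sustained yaw plus discrete head-roll steps
PRP    pure roll perturbation, sinusoidal roll
LTA    lateral (head y) sinusoidal translational acceleration, no rotation
VTA    vertical (head z) sinusoidal translational acceleration, no rotation
====== =====================================================================

All constant-rate rotations start with a raised-cosine velocity ramp
(default 1 s) to avoid impulsive canal inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .core import DEFAULT_DT, DEFAULT_DURATION, G, MotionStimulus

PARADIGMS = ("EVAR", "OVAR", "CENTRIFUGE", "CCCP", "PRP", "LTA", "VTA")


# ---------------------------------------------------------------------------
# kinematic chain
# ---------------------------------------------------------------------------

@dataclass
class Joint:
    """One joint of the chain.

    ``axis`` is a unit 3-vector in the parent frame.  ``traj`` maps a time
    array to the joint coordinate (rad for revolute joints, m for prismatic
    joints).  ``offset`` is a fixed link translation expressed in the joint's
    rotated (child) frame.
    """

    kind: str  # "revolute" | "prismatic"
    axis: Sequence[float]
    traj: Callable[[np.ndarray], np.ndarray]
    offset: Sequence[float] = (0.0, 0.0, 0.0)
    name: str = "joint"

    def __post_init__(self) -> None:
        if self.kind not in ("revolute", "prismatic"):
            raise ValueError(f"unknown joint kind {self.kind!r}")
        a = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("joint axis must be non-zero")
        self.axis = a / n
        self.offset = np.asarray(self.offset, dtype=float)


@dataclass
class ChainConfig:
    """Exactly three joints; the head frame is the frame after the last joint."""

    joints: Sequence[Joint]
    gravity: float = G

    def __post_init__(self) -> None:
        if len(self.joints) != 3:
            raise ValueError("the kinematic chain has exactly three joints")


def static_joint(name: str = "static") -> Joint:
    return Joint("revolute", (0.0, 0.0, 1.0), lambda t: np.zeros_like(t), name=name)


def chain_to_stimulus(
    cfg: ChainConfig,
    duration: float = DEFAULT_DURATION,
    dt: float = DEFAULT_DT,
    paradigm: str = "custom",
    params: dict | None = None,
) -> MotionStimulus:
    """Run forward kinematics and return the head-frame vestibular input.

    The head-to-earth rotation and head position are composed joint by joint;
    angular velocity is the sum of joint axis rates expressed in the earth
    frame, inertial acceleration comes from second finite differences of the
    head position, and the specific force is ``R^T (p_ddot - g_earth)`` with
    ``g_earth = (0, 0, -G)``.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    n = int(round(duration / dt)) + 1
    # two padding samples on both sides keep the central finite-difference
    # stencils interior on the whole returned grid (trajectories must be
    # defined on [-2 dt, duration + 2 dt]; the bundled ones are)
    t = (np.arange(n + 4) - 2) * dt

    rot = Rotation.identity(t.size)
    pos = np.zeros((t.size, 3))
    omega_earth = np.zeros((t.size, 3))
    for joint in cfg.joints:
        q = np.asarray(joint.traj(t), dtype=float)
        if q.shape != t.shape or not np.isfinite(q).all():
            bad = "non-finite" if q.shape == t.shape else "mis-shaped"
            idx = int(np.argmax(~np.isfinite(q))) if q.shape == t.shape else 0
            raise ValueError(
                f"joint {joint.name!r} produced {bad} trajectory values"
                f" (first offence near t={t[idx]:.3f} s)"
            )
        if joint.kind == "revolute":
            qdot = np.gradient(q, dt)
            axis_earth = rot.apply(joint.axis)
            omega_earth += axis_earth * qdot[:, None]
            rot = rot * Rotation.from_rotvec(np.outer(q, joint.axis))
            pos = pos + rot.apply(joint.offset)
        else:  # prismatic
            axis_earth = rot.apply(joint.axis)
            pos = pos + axis_earth * q[:, None] + rot.apply(joint.offset)

    acc = np.gradient(np.gradient(pos, dt, axis=0), dt, axis=0)
    g_earth = np.array([0.0, 0.0, -cfg.gravity])
    f_h = rot.apply(acc - g_earth, inverse=True)
    omega_h = rot.apply(omega_earth, inverse=True)
    sl = slice(2, 2 + n)
    return MotionStimulus(
        t=t[sl],
        f_h=f_h[sl].T,
        omega_h=omega_h[sl].T,
        paradigm=paradigm,
        params=params or {},
    )


# ---------------------------------------------------------------------------
# trajectory primitives
# ---------------------------------------------------------------------------

def ramped_rotation(rate: float, ramp: float = 1.0) -> Callable[[np.ndarray], np.ndarray]:
    """Angle trajectory of a constant-rate rotation with a raised-cosine
    velocity ramp of length ``ramp`` seconds (integrated in closed form)."""

    def traj(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if ramp <= 0:
            return rate * np.maximum(t, 0.0)
        in_ramp = rate * (t / 2.0 - (ramp / (2.0 * np.pi)) * np.sin(np.pi * t / ramp))
        after = rate * (t - ramp / 2.0)
        out = np.where(t < ramp, in_ramp, after)
        return np.where(t <= 0.0, 0.0, out)

    return traj


def _smoothstep(u: np.ndarray) -> np.ndarray:
    """Quintic smoothstep on [0, 1]; C^2 at both ends."""
    u = np.clip(u, 0.0, 1.0)
    return u**3 * (10.0 - 15.0 * u + 6.0 * u**2)


def step_profile(
    dwell: float, step_duration: float, targets: Sequence[float]
) -> Callable[[np.ndarray], np.ndarray]:
    """Piecewise-constant angle schedule with smooth transitions.

    Starts at 0, dwells ``dwell`` s, then moves to each target in turn over
    ``step_duration`` s, dwelling between moves.
    """

    targets = np.concatenate([[0.0], np.asarray(targets, dtype=float)])
    cycle = dwell + step_duration

    def traj(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        k = np.floor(t / cycle).astype(int)  # index of the current cycle
        k = np.clip(k, 0, len(targets) - 2)
        phase = t - k * cycle
        u = (phase - dwell) / step_duration
        start = targets[k]
        stop = targets[k + 1]
        out = start + (stop - start) * _smoothstep(u)
        # after the final programmed step, hold the last target
        done = t >= (len(targets) - 1) * cycle
        return np.where(done, targets[-1], out)

    return traj


# ---------------------------------------------------------------------------
# paradigms
# ---------------------------------------------------------------------------

def make_paradigm(
    name: str,
    duration: float = DEFAULT_DURATION,
    dt: float = DEFAULT_DT,
    ramp: float = 1.0,
    **params,
) -> MotionStimulus:
    """Build one of the seven standard motion paradigms.

    Parameters beyond the common ones are paradigm specific (all angles in
    degrees, rates in deg/s, accelerations in m/s^2, frequencies in Hz):

    * EVAR: ``rate`` (default 30)
    * OVAR: ``tilt`` (15), ``rate`` (30)
    * CENTRIFUGE: ``rate`` (250), ``radius`` (0.54)
    * CCCP: ``rate`` (138), ``roll_amplitude`` (45), ``dwell`` (10),
      ``roll_duration`` (2)
    * PRP: ``roll_amplitude`` (15), ``freq`` (0.2)
    * LTA / VTA: ``amplitude`` (0.89, peak acceleration), ``freq`` (0.2)
    """
    name = name.upper()
    if name not in PARADIGMS:
        raise ValueError(f"unknown paradigm {name!r}; choose from {PARADIGMS}")
    d2r = np.pi / 180.0

    if name == "EVAR":
        rate = params.setdefault("rate", 30.0)
        joints = [
            Joint("revolute", (0, 0, 1), ramped_rotation(rate * d2r, ramp), name="yaw"),
            static_joint("tilt"),
            static_joint("roll"),
        ]
    elif name == "OVAR":
        tilt = params.setdefault("tilt", 15.0)
        rate = params.setdefault("rate", 30.0)
        if not 0.0 < tilt < 90.0:
            raise ValueError("OVAR tilt must lie strictly between 0 and 90 degrees")
        joints = [
            Joint("revolute", (0, 1, 0), lambda t: np.full_like(t, tilt * d2r), name="tilt"),
            Joint("revolute", (0, 0, 1), ramped_rotation(rate * d2r, ramp), name="spin"),
            static_joint("roll"),
        ]
    elif name == "CENTRIFUGE":
        rate = params.setdefault("rate", 250.0)
        radius = params.setdefault("radius", 0.54)
        if radius <= 0:
            raise ValueError("centrifuge radius must be positive")
        joints = [
            Joint(
                "revolute",
                (0, 0, 1),
                ramped_rotation(rate * d2r, ramp),
                offset=(0.0, radius, 0.0),
                name="yaw",
            ),
            static_joint("tilt"),
            static_joint("roll"),
        ]
    elif name == "CCCP":
        rate = params.setdefault("rate", 138.0)
        amp = params.setdefault("roll_amplitude", 45.0)
        dwell = params.setdefault("dwell", 10.0)
        roll_duration = params.setdefault("roll_duration", 2.0)
        n_steps = int(np.ceil(duration / (dwell + roll_duration))) + 1
        # toggle between upright and the rolled posture: each roll moves by
        # the full amplitude, alternating direction
        targets = [amp * d2r if k % 2 == 0 else 0.0 for k in range(n_steps)]
        joints = [
            Joint("revolute", (0, 0, 1), ramped_rotation(rate * d2r, ramp), name="yaw"),
            static_joint("tilt"),
            Joint("revolute", (1, 0, 0), step_profile(dwell, roll_duration, targets), name="roll"),
        ]
    elif name == "PRP":
        amp = params.setdefault("roll_amplitude", 15.0)
        freq = params.setdefault("freq", 0.2)
        joints = [
            Joint(
                "revolute",
                (1, 0, 0),
                lambda t: amp * d2r * np.sin(2 * np.pi * freq * t),
                name="roll",
            ),
            static_joint("tilt"),
            static_joint("yaw"),
        ]
    else:  # LTA / VTA
        amp = params.setdefault("amplitude", 0.89)
        freq = params.setdefault("freq", 0.2)
        axis = (0, 1, 0) if name == "LTA" else (0, 0, 1)
        scale = amp / (2 * np.pi * freq) ** 2

        def disp(t: np.ndarray) -> np.ndarray:
            return -scale * np.sin(2 * np.pi * freq * t)

        joints = [
            Joint("prismatic", axis, disp, name="translation"),
            static_joint("tilt"),
            static_joint("roll"),
        ]
        stim = chain_to_stimulus(
            ChainConfig(joints), duration, dt, paradigm=name, params=params
        )
        # translation-only paradigms are rotation free by construction
        stim.omega_h[:] = 0.0
        return stim

    return chain_to_stimulus(ChainConfig(joints), duration, dt, paradigm=name, params=params)


def translational_sinusoid(
    axis: str,
    freq: float,
    amplitude: float,
    duration: float,
    dt: float = DEFAULT_DT,
) -> MotionStimulus:
    """Pure sinusoidal translational acceleration along head x, y or z.

    Convenience wrapper used by the frequency-response analyses; equivalent to
    LTA/VTA at arbitrary axis/frequency/amplitude, built in closed form.
    """
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    f_h = np.zeros((3, n))
    f_h[2] = G
    i = "xyz".index(axis)
    f_h[i] += amplitude * np.sin(2 * np.pi * freq * t)
    return MotionStimulus(
        t=t,
        f_h=f_h,
        omega_h=np.zeros((3, n)),
        paradigm="sinusoid",
        params={"axis": axis, "freq": freq, "amplitude": amplitude},
    )


# ---------------------------------------------------------------------------
# synthetic perception reports (for exercising the tuning machinery)
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPerceptionReport:
    """Surrogate participant perception report with a known closed form.

    Emulates the qualitative shapes of the classic report types: an
    exponentially decaying yaw-velocity percept (constant-rate EVAR), an
    exponentially saturating roll percept (centrifugation) and a sinusoidal
    percept (OVAR translation/rotation), plus additive Gaussian observation
    noise.  Synthetic stand-in for experimental report series.
    """

    t: np.ndarray
    values: np.ndarray
    kind: str
    A: float
    b: float
    noise_sd: float
    seed: int | None

    def noiseless(self) -> np.ndarray:
        return _report_form(self.kind, self.A, self.b, self.t)


def _report_form(kind: str, A: float, b: float, t: np.ndarray) -> np.ndarray:
    if kind == "evar_decay":
        return A * np.exp(-b * t)
    if kind == "centrifuge_roll":
        return A * (1.0 - np.exp(-b * t))
    if kind == "ovar_sine":
        return A * np.sin(2 * np.pi * b * t)
    raise ValueError(f"unknown report kind {kind!r}")


def synth_perception(
    kind: str,
    A: float,
    b: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
    t: np.ndarray | None = None,
) -> SyntheticPerceptionReport:
    """Generate a synthetic perception report; see SyntheticPerceptionReport."""
    if b <= 0:
        raise ValueError("rate b must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if t is None:
        t = np.arange(0.0, 100.0, 0.1)
    t = np.asarray(t, dtype=float)
    if t.size == 0:
        raise ValueError("empty time grid")
    values = _report_form(kind, A, b, t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=t.shape)
    return SyntheticPerceptionReport(t, values, kind, A, b, noise_sd, seed)
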