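"""Particle Filter Model (PFM).

Stochastic estimation of head orientation, angular velocity and acceleration
from the vestibular signals, by inversion of the semicircular-canal dynamics
plus Gaussian stationarity priors.

Per time step (Euler, step ``dt``), for each particle ``i``:

1. *perturb*: a canal-state hypothesis ``C_i`` is drawn around the sensed
   canal afferent of the previous step, ``C_i = V_{t-1} + N(0, sigma_c)``;
2. *invert*: the first-order canal equation ``dC/dt = d omega/dt - C / T_c``
   is inverted for the angular velocity consistent with the hypothesis,
   ``Omega_i(t) = Omega_i(t-1) + (C_i(t) - C_i(t-1)) + dt * C_i(t-1) / T_c``;
3. *rotate*: the particle orientation quaternion is advanced by
   ``R(Omega_i dt)``;
4. *acceleration*: the earth-frame acceleration implied by the orientation is
   ``A_i = R(Theta_i) f_h + (0, 0, -G)`` -- gravity has fixed magnitude;
5. *weight*: ``w_i ~ prod_axes N(A_i; 0, sigma_a) N(Omega_i; 0, sigma_w)``
   (the brain's prior favours stationarity);
6. *resample*: systematic resampling proportional to weight (multinomial
   available behind a flag).

The posterior mean of the ensemble at each sample forms the perception trace.
No otolith conflict exists for this model; the angular-velocity conflict is
computed after the run as ``c_w = SSC(omega_h) - SSC(omega_hat)`` with SSC
the first-order canal high-pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._quat import from_rotvec, qmul, qnormalize, qrotate
from .core import G, ConflictTrace, MotionStimulus, PerceptionTrace
from .presets import preset_dict

_D2R = np.pi / 180.0


@dataclass
class PFMParams:
    """PFM parameters; noise magnitudes are quoted in deg/s (canal and
    angular-velocity prior) and m/s^2 (acceleration prior) as published."""

    tau_ssc: float = 5.7
    sigma_c: float = 10.0   # canal noise sd, deg/s
    sigma_a: float = 0.5    # acceleration prior sd, m/s^2
    sigma_w: float = 26.0   # angular-velocity prior sd, deg/s
    n_particles: int = 800
    seed: int | None = None
    resampling: str = "systematic"  # or "multinomial"

    def __post_init__(self) -> None:
        if min(self.sigma_c, self.sigma_a, self.sigma_w) <= 0:
            raise ValueError("all noise standard deviations must be positive")
        if self.n_particles < 2:
            raise ValueError("need at least two particles")
        if self.resampling not in ("systematic", "multinomial"):
            raise ValueError("resampling must be 'systematic' or 'multinomial'")

    @classmethod
    def preset(cls, name: str, **overrides) -> "PFMParams":
        kw = preset_dict("pfm", name)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class ParticleEnsemble:
    """Ensemble state at one time step (canal state and angular velocity in
    rad/s, orientation as scalar-first head-to-earth unit quaternions)."""

    C: np.ndarray        # (n, 3) canal-state hypotheses
    Omega: np.ndarray    # (n, 3) angular velocities
    Theta: np.ndarray    # (n, 4) orientation quaternions
    A: np.ndarray        # (n, 3) earth-frame accelerations
    weights: np.ndarray  # (n,) normalized
    #: posterior (pre-resampling, weighted) means of the last step
    mean_omega: np.ndarray = field(default_factory=lambda: np.zeros(3))
    mean_a: np.ndarray = field(default_factory=lambda: np.zeros(3))
    mean_g_head: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, G]))
    mean_theta: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))

    @classmethod
    def rest(cls, n: int) -> "ParticleEnsemble":
        q = np.zeros((n, 4))
        q[:, 0] = 1.0
        return cls(
            C=np.zeros((n, 3)),
            Omega=np.zeros((n, 3)),
            Theta=q,
            A=np.zeros((n, 3)),
            weights=np.full(n, 1.0 / n),
        )


def _resample_indices(weights: np.ndarray, rng: np.random.Generator, scheme: str) -> np.ndarray:
    n = weights.size
    if scheme == "systematic":
        positions = (rng.random() + np.arange(n)) / n
        return np.searchsorted(np.cumsum(weights), positions)
    return rng.choice(n, size=n, p=weights)


def pfm_step(
    ensemble: ParticleEnsemble,
    v_sensed: np.ndarray,
    f_sensed: np.ndarray,
    p: PFMParams,
    dt: float,
    rng: np.random.Generator,
) -> ParticleEnsemble:
    """Advance the ensemble by one step; see the module docstring for the
    perturb / invert / rotate / weight / resample sequence."""
    n = ensemble.C.shape[0]
    sigma_c = p.sigma_c * _D2R
    sigma_w = p.sigma_w * _D2R

    C_new = v_sensed + rng.normal(0.0, sigma_c, size=(n, 3))
    Omega = ensemble.Omega + (C_new - ensemble.C) + (dt / p.tau_ssc) * ensemble.C
    Theta = qnormalize(qmul(ensemble.Theta, from_rotvec(Omega * dt)))
    A = qrotate(Theta, f_sensed) + np.array([0.0, 0.0, -G])

    logw = -0.5 * (
        np.sum(A**2, axis=1) / p.sigma_a**2 + np.sum(Omega**2, axis=1) / sigma_w**2
    )
    logw -= logw.max()
    w = np.exp(logw)
    total = w.sum()
    if total <= 0 or not np.isfinite(total):  # total degeneracy
        w = np.full(n, 1.0 / n)
    else:
        w /= total

    # weighted posterior summaries before resampling
    mean_omega = w @ Omega
    mean_a = w @ A
    qc = Theta.copy()
    qc[:, 1:] *= -1.0
    mean_g = w @ qrotate(qc, np.array([0.0, 0.0, G]))
    qmean = w @ Theta
    qmean = qmean / np.linalg.norm(qmean)

    idx = _resample_indices(w, rng, p.resampling)
    return ParticleEnsemble(
        C=C_new[idx],
        Omega=Omega[idx],
        Theta=Theta[idx],
        A=A[idx],
        weights=np.full(n, 1.0 / n),
        mean_omega=mean_omega,
        mean_a=mean_a,
        mean_g_head=mean_g,
        mean_theta=qmean,
    )


def _canal_highpass(series: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """First-order high-pass s*tau/(1 + s*tau) along the last axis (exact
    zero-order-hold discretization of the low-pass complement)."""
    alpha = dt / (tau + dt)
    lp = np.zeros_like(series)
    for k in range(1, series.shape[-1]):
        lp[..., k] = lp[..., k - 1] + alpha * (series[..., k] - lp[..., k - 1])
    return series - lp


def pfm_simulate(
    stim: MotionStimulus, p: PFMParams, seed: int | None = None
) -> tuple[PerceptionTrace, ConflictTrace]:
    """Run the particle filter over a stimulus (Euler stepping at the
    stimulus dt).  Posterior (weighted, pre-resampling) means form the
    perception trace; the conflict trace has the single key ``c_w``.

    The run is deterministic given ``seed`` (falls back to ``p.seed``).
    """
    from ._kernels import pfm_loop

    use_seed = p.seed if seed is None else seed
    if use_seed is None:
        use_seed = 0
    t = stim.t
    dt = stim.dt
    f = np.ascontiguousarray(stim.f_h.T)
    w_true = stim.omega_h.T

    # the sensed canal afferent driving the filter
    v_sensed = np.ascontiguousarray(_canal_highpass(stim.omega_h, p.tau_ssc, dt).T)

    w_hat, a_hat_earth, g_hat, theta_hat = pfm_loop(
        f,
        v_sensed,
        dt,
        p.tau_ssc,
        p.sigma_c * _D2R,
        p.sigma_a,
        p.sigma_w * _D2R,
        p.n_particles,
        int(use_seed),
        p.resampling == "systematic",
    )

    # head-frame acceleration estimate and integrated velocity percept
    qc_all = theta_hat.copy()
    qc_all[:, 1:] *= -1.0
    a_hat = qrotate(qc_all, a_hat_earth)
    v_hat = np.cumsum(a_hat, axis=0) * dt

    ssc_true = _canal_highpass(w_true.T, p.tau_ssc, dt)
    ssc_est = _canal_highpass(w_hat.T, p.tau_ssc, dt)

    percept = PerceptionTrace(
        t=t,
        g_hat=g_hat.T,
        a_hat=a_hat.T,
        v_hat=v_hat.T,
        w_hat=w_hat.T,
        theta_hat=theta_hat.T,
    )
    conflicts = ConflictTrace(t=t, conflicts={"c_w": ssc_true - ssc_est})
    return percept, conflicts


def pfm_mean_percept(
    stim: MotionStimulus,
    p: PFMParams,
    seeds: np.ndarray | list[int],
    quantity: str = "roll",
) -> np.ndarray:
    """Average a percept over repeated filter runs with different seeds.

    ``quantity``: 'roll' (tilt of the subjective vertical about head x, rad),
    'tilt' (total tilt, rad) or 'yaw' (yaw velocity percept, rad/s).
    """
    acc = None
    for s in seeds:
        percept, _ = pfm_simulate(stim, p, seed=int(s))
        if quantity == "roll":
            y = percept.roll_percept()
        elif quantity == "tilt":
            y = percept.tilt_percept()
        elif quantity == "yaw":
            y = percept.yaw_velocity_percept()
        else:
            raise ValueError(f"unknown quantity {quantity!r}")
        acc = y if acc is None else acc + y
    return acc / len(seeds)
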