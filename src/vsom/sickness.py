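"""Mapping sensory conflict to motion-sickness metrics.

Two heads are provided:

* the primary metric, a weighted time integral of per-type conflict
  magnitudes,

      MS(t) = int_0^t W . |c(t')| dt'

  where ``|c|`` collects the per-sample Euclidean norm of each conflict type
  and ``W`` holds the fitted per-type weights (one non-zero conflict per
  model: gravity conflict for the SVM, otolith magnitude conflict for the
  MSOM, angular-velocity conflict for the PFM);

* an optional Hill + MSI head: the conflict magnitude is scaled by a Hill
  saturation ``h = (c/b)^n / (1 + (c/b)^n)`` and accumulated by a critically
  damped second-order filter ``P / (mu s + 1)^2`` whose output is the motion
  sickness incidence (percentage of a population vomiting).  Its parameters
  (b, n, P, mu) are configurable; no published values are bundled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import ConflictTrace
from .presets import sickness_weights as _preset_weights


@dataclass
class SicknessAccumulatorParams:
    """Hill scaling + MSI filter parameters."""

    b: float = 0.5   # conflict half-saturation, units of the conflict
    n: float = 2.0   # Hill exponent
    P: float = 85.0  # MSI output scale, %
    mu: float = 720.0  # MSI filter time constant, s

    def __post_init__(self) -> None:
        if self.b <= 0 or self.n <= 0 or self.mu <= 0:
            raise ValueError("b, n and mu must be positive")


@dataclass
class SicknessWeights:
    """Non-negative weight per conflict type."""

    W: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.W.values()):
            raise ValueError("weights must be non-negative")

    @classmethod
    def preset(cls, model: str) -> "SicknessWeights":
        return cls(_preset_weights(model))


@dataclass
class SicknessResult:
    t: np.ndarray
    ms_series: np.ndarray
    ms_final: float
    msi_series: np.ndarray | None = None
    normalization: str = "none"


def hill_scale(c_mag: np.ndarray, b: float, n: float) -> np.ndarray:
    """Hill saturation of a non-negative conflict magnitude into [0, 1]
    (the open bound is reached only at float overflow of ``(c/b)^n``)."""
    c_mag = np.asarray(c_mag, dtype=float)
    if (c_mag < 0).any():
        raise ValueError("conflict magnitudes must be non-negative")
    with np.errstate(over="ignore"):
        x = (c_mag / b) ** n
        return np.where(np.isinf(x), 1.0, x / (1.0 + x))


def msi_accumulate(h: np.ndarray, P: float, mu: float, dt: float) -> np.ndarray:
    """Drive the second-order MSI filter ``P / (mu s + 1)^2`` with the scaled
    conflict; zero initial conditions.  Returns the MSI time course (%)."""
    h = np.asarray(h, dtype=float)
    t = np.arange(h.size) * dt
    sys = signal.lti([P], [mu**2, 2.0 * mu, 1.0])
    _, y, _ = signal.lsim(sys, h, t)
    return np.atleast_1d(y)


def ms_integrate(
    conf: ConflictTrace,
    W: SicknessWeights,
    dt: float | None = None,
    msi_params: SicknessAccumulatorParams | None = None,
) -> SicknessResult:
    """Integrate the weighted conflict magnitudes over time (trapezoidal).

    If ``msi_params`` is given, the Hill + MSI head is also evaluated on the
    weighted conflict magnitude and returned as ``msi_series``.
    """
    missing = set(W.W) - set(conf.keys())
    if missing:
        raise KeyError(f"weights refer to conflict types absent from the trace: {missing}")
    if dt is None:
        dt = float(conf.t[1] - conf.t[0])
    norms = conf.norms()
    weighted = np.zeros_like(conf.t, dtype=float)
    for key, weight in W.W.items():
        if weight != 0.0:
            weighted = weighted + weight * norms[key]
    ms_series = np.concatenate(
        [[0.0], np.cumsum(0.5 * (weighted[1:] + weighted[:-1]) * dt)]
    )
    msi_series = None
    if msi_params is not None:
        h = hill_scale(weighted, msi_params.b, msi_params.n)
        msi_series = msi_accumulate(h, msi_params.P, msi_params.mu, dt)
    return SicknessResult(
        t=conf.t,
        ms_series=ms_series,
        ms_final=float(ms_series[-1]),
        msi_series=msi_series,
    )
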