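"""Post-processing analyses.

* exponential time-constant fits of percept traces,
* small-signal Bode magnitude responses of the perception estimates,
* sickness frequency sensitivities (time-averaged weighted conflict per
  probe frequency, self-normalized),
* the angular-velocity feedback-gain sweep of the SVM gravity conflict,
* the symmetric mean absolute error (SMAE) fit metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .core import G, ConflictTrace, MotionStimulus, PerceptionTrace
from .msom import MSOMParams, msom_simulate
from .pfm import PFMParams, pfm_simulate
from .sickness import SicknessWeights
from .stimuli import make_paradigm, translational_sinusoid
from .svm import SVMParams, svm_simulate

DEFAULT_FREQ_GRID = np.logspace(np.log10(0.01), np.log10(2.0), 30)
DEFAULT_TRANSIENT = 20.0  # s discarded before steady-state measurements


# ---------------------------------------------------------------------------
# model dispatch
# ---------------------------------------------------------------------------

def resolve_params(model: str, preset):
    """Accept a params object or a preset name for the given model."""
    model = model.lower()
    if isinstance(preset, (SVMParams, MSOMParams, PFMParams)):
        return preset
    cls = {"svm": SVMParams, "msom": MSOMParams, "pfm": PFMParams}[model]
    return cls.preset(preset)


def simulate_model(
    model: str, params, stim: MotionStimulus, seed: int | None = None
) -> tuple[PerceptionTrace, ConflictTrace]:
    model = model.lower()
    params = resolve_params(model, params)
    if model == "svm":
        return svm_simulate(stim, params)
    if model == "msom":
        return msom_simulate(stim, params)
    if model == "pfm":
        return pfm_simulate(stim, params, seed=seed)
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# exponential fits
# ---------------------------------------------------------------------------

@dataclass
class TimeConstantFit:
    A: float
    b: float  # rate, s^-1; time constant is 1/b
    residual_rms: float
    window: tuple[float, float]
    form: str
    success: bool = True

    @property
    def tau(self) -> float:
        return 1.0 / self.b


def fit_time_constant(
    t: np.ndarray,
    series: np.ndarray,
    form: str = "decay",
    window: tuple[float, float] | None = None,
) -> TimeConstantFit:
    """Nonlinear least-squares fit of ``A exp(-b t)`` (decay) or
    ``A (1 - exp(-b t))`` (saturating) on the given window.

    Time is measured from the start of the fit window.  Raises
    ``RuntimeError`` on non-convergence or a non-decaying/degenerate signal.
    """
    t = np.asarray(t, dtype=float)
    series = np.asarray(series, dtype=float)
    if window is None:
        window = (float(t[0]), float(t[-1]))
    mask = (t >= window[0]) & (t <= window[1])
    if mask.sum() < 20:
        raise ValueError("fit window must contain at least 20 samples")
    tw = t[mask] - t[mask][0]
    yw = series[mask]

    if form == "decay":
        model = lambda tt, A, b: A * np.exp(-b * tt)
        a0 = yw[0] if abs(yw[0]) > 0 else (np.max(np.abs(yw)) or 1.0)
    elif form == "saturating":
        model = lambda tt, A, b: A * (1.0 - np.exp(-b * tt))
        a0 = yw[-1] if abs(yw[-1]) > 0 else 1.0
    else:
        raise ValueError("form must be 'decay' or 'saturating'")
    span = tw[-1] - tw[0]
    try:
        popt, _ = curve_fit(
            model,
            tw,
            yw,
            p0=(a0, 3.0 / span),
            bounds=([-np.inf, 1e-6], [np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        raise RuntimeError(f"time-constant fit failed: {exc}") from exc
    resid = yw - model(tw, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    if rms > 0.5 * max(np.max(np.abs(yw)), 1e-12):
        raise RuntimeError("time-constant fit rejected: residual comparable to signal")
    return TimeConstantFit(
        A=float(popt[0]), b=float(popt[1]), residual_rms=rms, window=window, form=form
    )


# ---------------------------------------------------------------------------
# frequency responses
# ---------------------------------------------------------------------------

@dataclass
class FrequencyResponse:
    freqs: np.ndarray
    gain: np.ndarray
    probe_amplitude: float
    pair: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        order = np.argsort(self.freqs)
        self.freqs = np.asarray(self.freqs, dtype=float)[order]
        self.gain = np.asarray(self.gain, dtype=float)[order]

    def break_frequency(self) -> float:
        """-3 dB corner relative to the low-frequency plateau (linear
        interpolation in log frequency)."""
        plateau = self.gain[0]
        target = plateau / np.sqrt(2.0)
        below = np.nonzero(self.gain < target)[0]
        if below.size == 0:
            raise ValueError("gain never falls 3 dB below the plateau")
        i = below[0]
        if i == 0:
            return float(self.freqs[0])
        f0, f1 = self.freqs[i - 1], self.freqs[i]
        g0, g1 = self.gain[i - 1], self.gain[i]
        frac = (g0 - target) / (g0 - g1)
        return float(np.exp(np.log(f0) + frac * (np.log(f1) - np.log(f0))))

    def peak_frequency(self) -> float:
        return float(self.freqs[int(np.argmax(self.gain))])

    def normalized(self) -> "FrequencyResponse":
        return FrequencyResponse(
            self.freqs.copy(),
            self.gain / np.max(self.gain),
            self.probe_amplitude,
            self.pair,
            list(self.warnings),
        )


def _sinusoid_amplitude(t: np.ndarray, y: np.ndarray, freq: float) -> float:
    """Least-squares amplitude of a sinusoid at a known frequency (bias
    removed)."""
    w = 2.0 * np.pi * freq
    basis = np.column_stack([np.sin(w * t), np.cos(w * t), np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    return float(np.hypot(coef[0], coef[1]))


def _output_component(
    percept: PerceptionTrace,
    conflicts: ConflictTrace,
    quantity: str,
    axis_index: int,
) -> np.ndarray:
    """Select an output series: a percept attribute or a conflict type."""
    if quantity in conflicts.keys():
        y = conflicts[quantity][axis_index].astype(float)
    else:
        y = getattr(percept, quantity)[axis_index].astype(float)
        if quantity == "g_hat" and axis_index == 2:
            y = y - G  # deviation from the static vertical
    return y


def _probe_duration(freq: float, transient: float, min_cycles: int = 5) -> float:
    return transient + max(min_cycles / freq, 10.0)


def freq_response(
    model: str,
    preset,
    input_axis: str = "y",
    output_quantity: str = "g_hat",
    freqs: np.ndarray | None = None,
    amplitude: float = 0.1,
    dt: float = 0.01,
    transient: float = DEFAULT_TRANSIENT,
    seeds: list[int] | None = None,
) -> FrequencyResponse:
    """Small-signal Bode magnitude response of a perception estimate.

    Per frequency a sinusoidal translational-acceleration probe is simulated
    long enough for at least five steady cycles after the transient; the gain
    is the fitted steady-state output amplitude over the input amplitude.
    The output component is taken along the input axis.  For the PFM the gain
    is averaged over ``seeds``.
    """
    freqs = DEFAULT_FREQ_GRID if freqs is None else np.asarray(freqs, dtype=float)
    params = resolve_params(model, preset)
    axis_index = "xyz".index(input_axis)
    gains = np.empty_like(freqs)
    warnings: list[str] = []
    run_seeds = [None] if model.lower() != "pfm" else (seeds or [0])
    for i, f0 in enumerate(freqs):
        duration = _probe_duration(f0, transient)
        stim = translational_sinusoid(input_axis, f0, amplitude, duration, dt)
        amps = []
        for seed in run_seeds:
            percept, conflicts = simulate_model(model, params, stim, seed=seed)
            y = _output_component(percept, conflicts, output_quantity, axis_index)
            mask = stim.t >= transient
            amps.append(_sinusoid_amplitude(stim.t[mask], y[mask], f0))
            # settling check: compare the last two full cycles
            t_end = stim.t[-1]
            cyc = 1.0 / f0
            m1 = (stim.t >= t_end - 2 * cyc) & (stim.t < t_end - cyc)
            m2 = stim.t >= t_end - cyc
            a1 = _sinusoid_amplitude(stim.t[m1], y[m1], f0)
            a2 = _sinusoid_amplitude(stim.t[m2], y[m2], f0)
            if a1 > 0 and abs(a2 - a1) / max(a1, 1e-15) > 0.05:
                warnings.append(f"f={f0:.4g} Hz: amplitude drift {abs(a2-a1)/a1:.1%}")
        gains[i] = np.mean(amps) / amplitude
    return FrequencyResponse(
        freqs=freqs,
        gain=gains,
        probe_amplitude=amplitude,
        pair=f"{input_axis} acceleration -> {output_quantity}",
        warnings=warnings,
    )


def sickness_sensitivity(
    model: str,
    preset,
    axis: str = "vertical",
    freqs: np.ndarray | None = None,
    amplitude: float = 0.89,
    dt: float = 0.01,
    transient: float = DEFAULT_TRANSIENT,
    weights: SicknessWeights | None = None,
    seeds: list[int] | None = None,
    normalize: bool = True,
) -> FrequencyResponse:
    """Frequency sensitivity of the sickness proxy to sinusoidal acceleration.

    Per frequency, the post-transient time-averaged weighted conflict
    magnitude at fixed peak acceleration; by default normalized to its own
    maximum over the grid.
    """
    if axis not in ("lateral", "vertical"):
        raise ValueError("axis must be 'lateral' or 'vertical'")
    input_axis = "y" if axis == "lateral" else "z"
    freqs = DEFAULT_FREQ_GRID if freqs is None else np.asarray(freqs, dtype=float)
    params = resolve_params(model, preset)
    W = weights or SicknessWeights.preset(model.lower())
    run_seeds = [None] if model.lower() != "pfm" else (seeds or [0])
    vals = np.empty_like(freqs)
    for i, f0 in enumerate(freqs):
        duration = _probe_duration(f0, transient)
        stim = translational_sinusoid(input_axis, f0, amplitude, duration, dt)
        per_seed = []
        for seed in run_seeds:
            _, conf = simulate_model(model, params, stim, seed=seed)
            norms = conf.norms()
            mask = stim.t >= transient
            weighted = sum(wgt * norms[k][mask] for k, wgt in W.W.items() if wgt != 0.0)
            per_seed.append(np.mean(weighted))
        vals[i] = np.mean(per_seed)
    resp = FrequencyResponse(
        freqs=freqs,
        gain=vals,
        probe_amplitude=amplitude,
        pair=f"{axis} acceleration -> weighted conflict",
    )
    return resp.normalized() if normalize else resp


def komega_sweep(
    base: SVMParams,
    K_values,
    duration: float = 200.0,
    dt: float = 0.01,
    transient: float = DEFAULT_TRANSIENT,
    prp_params: dict | None = None,
    lta_params: dict | None = None,
) -> dict[str, np.ndarray]:
    """Time-averaged SVM gravity-conflict magnitude for PRP and LTA as a
    function of the angular-velocity feedback gain K_wc."""
    from dataclasses import replace

    K_values = np.asarray(list(K_values), dtype=float)
    out = {"K": K_values, "PRP": np.empty_like(K_values), "LTA": np.empty_like(K_values)}
    stims = {
        "PRP": make_paradigm("PRP", duration=duration, dt=dt, **(prp_params or {})),
        "LTA": make_paradigm("LTA", duration=duration, dt=dt, **(lta_params or {})),
    }
    for name, stim in stims.items():
        mask = stim.t >= transient
        for i, k in enumerate(K_values):
            p = replace(base, K_wc=float(k))
            _, conf = svm_simulate(stim, p)
            out[name][i] = np.mean(np.linalg.norm(conf["c_g"], axis=0)[mask])
    return out


def paradigm_ms_table(
    model: str,
    preset,
    paradigms: dict[str, dict] | None = None,
    duration: float = 200.0,
    dt: float = 0.01,
    seeds: list[int] | None = None,
    normalize_to: str | None = "CCCP",
    weights: SicknessWeights | None = None,
) -> dict[str, dict[str, float]]:
    """Cumulative sickness proxy per motion paradigm at equal session length.

    Returns ``{paradigm: {"MS": value, "MS_rel": value / MS[normalize_to]}}``.
    For the PFM the MS of each paradigm is averaged over ``seeds``.
    """
    from .sickness import ms_integrate

    if paradigms is None:
        paradigms = {"CCCP": {}, "OVAR": {}, "LTA": {}, "VTA": {}, "PRP": {}}
    params = resolve_params(model, preset)
    W = weights or SicknessWeights.preset(model.lower())
    run_seeds = [None] if model.lower() != "pfm" else (seeds or [0])
    table: dict[str, dict[str, float]] = {}
    for name, kwargs in paradigms.items():
        stim = make_paradigm(name, duration=duration, dt=dt, **kwargs)
        vals = []
        for seed in run_seeds:
            _, conf = simulate_model(model, params, stim, seed=seed)
            vals.append(ms_integrate(conf, W).ms_final)
        table[name] = {"MS": float(np.mean(vals))}
    if normalize_to is not None and normalize_to in table:
        ref = table[normalize_to]["MS"]
        for name in table:
            table[name]["MS_rel"] = table[name]["MS"] / ref if ref > 0 else np.nan
    return table


def percept_series(
    model: str,
    params,
    stim: MotionStimulus,
    quantity: str,
    seed: int | None = None,
) -> np.ndarray:
    """Convenience: simulate and extract one percept scalar series.

    ``quantity``: 'yaw' (yaw velocity, rad/s), 'roll' / 'tilt' (rad) or
    'v_lateral' (m/s).
    """
    percept, _ = simulate_model(model, params, stim, seed=seed)
    if quantity == "yaw":
        return percept.yaw_velocity_percept()
    if quantity == "roll":
        return percept.roll_percept()
    if quantity == "tilt":
        return percept.tilt_percept()
    if quantity == "v_lateral":
        return percept.v_hat[1]
    raise ValueError(f"unknown percept quantity {quantity!r}")


# ---------------------------------------------------------------------------
# SMAE
# ---------------------------------------------------------------------------

def smae(
    predicted: np.ndarray,
    reference: np.ndarray,
    t_pred: np.ndarray | None = None,
    t_ref: np.ndarray | None = None,
    eps: float = 1e-9,
) -> float:
    """Symmetric mean absolute error between two series, in [0, 2]:

        mean( 2 |p - r| / (|p| + |r| + eps) )

    If both time grids are given, the reference is linearly interpolated onto
    the overlap of the two grids.
    """
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if t_pred is not None and t_ref is not None:
        t_pred = np.asarray(t_pred, dtype=float)
        t_ref = np.asarray(t_ref, dtype=float)
        lo, hi = max(t_pred[0], t_ref[0]), min(t_pred[-1], t_ref[-1])
        mask = (t_pred >= lo) & (t_pred <= hi)
        if not mask.any():
            raise ValueError("prediction and reference grids do not overlap")
        predicted = predicted[mask]
        reference = np.interp(t_pred[mask], t_ref, reference)
    if predicted.shape != reference.shape:
        raise ValueError("series must share a common grid")
    if predicted.size == 0:
        raise ValueError("empty overlap")
    return float(np.mean(2.0 * np.abs(predicted - reference) / (np.abs(predicted) + np.abs(reference) + eps)))
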