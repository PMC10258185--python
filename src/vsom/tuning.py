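"""Two-stage parameter tuning.

The tuning procedure mirrors how the published parameter sets were obtained:

1. *anchoring* -- the angular-velocity feedback gain is solved (bisection) so
   that the model reproduces a target EVAR perception decay time constant;
   this removes one dimension from the search;
2. *global search* -- simulated annealing around the literature values
   (10 runs x 100 iterations by default); all evaluated points in the lowest
   10th percentile of the objective become candidates (capped at 30);
3. *clustering* -- k-means (on z-scored parameters) groups the candidates
   into three regions;
4. *refinement* -- bounded local optimization from each cluster centroid;
   the best refined point wins.

The objective is typically a symmetric mean absolute error (SMAE) between
model percepts and (synthetic) perception reports; any callable mapping a
parameter vector to a non-negative scalar works.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.cluster import KMeans

_PENALTY = 1e6


@dataclass
class TuningProblem:
    """A bounded minimization problem over named model parameters."""

    model: str
    names: Sequence[str]
    bounds: Sequence[tuple[float, float]]
    objective: Callable[[np.ndarray], float]
    x0: np.ndarray | None = None  # literature starting point
    anchor: float | None = None   # target EVAR time constant, s

    def __post_init__(self) -> None:
        self.bounds = [(float(lo), float(hi)) for lo, hi in self.bounds]
        for lo, hi in self.bounds:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("bounds must be finite and ordered")
        if self.anchor is not None and self.anchor <= 0:
            raise ValueError("anchor time constant must be positive")
        if self.x0 is None:
            self.x0 = np.array([(lo + hi) / 2.0 for lo, hi in self.bounds])
        self.x0 = np.asarray(self.x0, dtype=float)

    def safe_objective(self, x: np.ndarray) -> float:
        try:
            val = float(self.objective(np.asarray(x, dtype=float)))
        except Exception:
            return _PENALTY
        return val if np.isfinite(val) else _PENALTY


@dataclass
class TuningResult:
    candidates: np.ndarray          # (n_cand, dim)
    candidate_objectives: np.ndarray
    centroids: np.ndarray           # (k, dim)
    refined: np.ndarray             # (k, dim)
    refined_objectives: np.ndarray
    best: np.ndarray
    best_objective: float
    names: Sequence[str] = ()
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "names": list(self.names),
                "seed": self.seed,
                "candidates": self.candidates.tolist(),
                "candidate_objectives": self.candidate_objectives.tolist(),
                "centroids": self.centroids.tolist(),
                "refined": self.refined.tolist(),
                "refined_objectives": self.refined_objectives.tolist(),
                "best": self.best.tolist(),
                "best_objective": self.best_objective,
            },
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# stage 1: EVAR anchoring
# ---------------------------------------------------------------------------

def anchor_evar(
    predictor: Callable[[float], float],
    target: float,
    gain_bounds: tuple[float, float] = (0.0, 20.0),
    tol: float = 1e-3,
    max_iter: int = 60,
) -> float:
    """Solve for the angular-velocity feedback gain that yields the target
    EVAR decay time constant.

    ``predictor`` maps a gain to the fitted time constant (monotonically
    increasing -- velocity storage).  Bisection on the gain; raises
    ``ValueError`` when the anchor is unreachable within the bounds.
    """
    lo, hi = gain_bounds
    f_lo = predictor(lo) - target
    f_hi = predictor(hi) - target
    if abs(f_lo) <= tol * target:
        return lo
    if f_lo > 0:
        raise ValueError(
            f"anchor {target} s unreachable: even gain {lo} gives a longer time constant"
        )
    if f_hi < 0:
        raise ValueError(
            f"anchor {target} s unreachable within gain bounds {gain_bounds}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = predictor(mid) - target
        if abs(f_mid) <= tol * target:
            return mid
        if f_mid < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# stage 2: simulated annealing
# ---------------------------------------------------------------------------

def sa_search(
    problem: TuningProblem,
    n_runs: int = 10,
    n_iter: int = 100,
    seed: int | None = None,
    cooling: float = 0.95,
    proposal_frac: float = 0.10,
    percentile: float = 10.0,
    max_candidates: int = 30,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated-annealing global search.

    ``n_runs`` independent chains of ``n_iter`` iterations start at the
    literature point ``problem.x0``.  Proposals are Gaussian with sd equal to
    ``proposal_frac`` of each bound width; the temperature cools
    geometrically per iteration from the magnitude of the initial objective.
    Returns ``(candidates, objectives)``: all evaluated points in the lowest
    ``percentile`` of objective values, best first, capped at
    ``max_candidates``.
    """
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in problem.bounds])
    hi = np.array([b[1] for b in problem.bounds])
    width = hi - lo
    xs: list[np.ndarray] = []
    fs: list[float] = []

    f0 = problem.safe_objective(problem.x0)
    t0 = max(abs(f0), 1e-8)
    for _ in range(n_runs):
        x = problem.x0.copy()
        fx = f0
        xs.append(x.copy())
        fs.append(fx)
        temp = t0
        for _ in range(n_iter):
            prop = np.clip(x + rng.normal(0.0, proposal_frac * width), lo, hi)
            fp = problem.safe_objective(prop)
            if fp <= fx or rng.random() < np.exp(-(fp - fx) / temp):
                x, fx = prop, fp
            xs.append(prop.copy())
            fs.append(fp)
            temp *= cooling
    xs_arr = np.array(xs)
    fs_arr = np.array(fs)
    cut = np.percentile(fs_arr, percentile)
    keep = np.nonzero(fs_arr <= cut)[0]
    order = keep[np.argsort(fs_arr[keep])][:max_candidates]
    return xs_arr[order], fs_arr[order]


# ---------------------------------------------------------------------------
# stage 3 + 4: clustering and local refinement
# ---------------------------------------------------------------------------

def cluster_and_refine(
    problem: TuningProblem,
    candidates: np.ndarray,
    objectives: np.ndarray,
    k: int = 3,
    seed: int | None = None,
) -> TuningResult:
    """K-means the candidate parameter sets into ``k`` regions and run a
    bounded local optimization from each centroid.

    Candidates are z-scored per parameter before clustering.  If fewer than
    ``k`` distinct candidates exist, ``k`` is reduced (with a warning in the
    result, implied by fewer centroids).
    """
    candidates = np.atleast_2d(np.asarray(candidates, dtype=float))
    objectives = np.asarray(objectives, dtype=float)
    if candidates.shape[0] < 1:
        raise ValueError("need at least one candidate")
    n_unique = np.unique(candidates, axis=0).shape[0]
    k_eff = int(min(k, n_unique))

    mean = candidates.mean(axis=0)
    sd = candidates.std(axis=0)
    sd[sd == 0] = 1.0
    z = (candidates - mean) / sd
    if k_eff == 1:
        centroids = candidates.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=k_eff, n_init=10, random_state=seed)
        km.fit(z)
        centroids = km.cluster_centers_ * sd + mean

    refined = []
    refined_f = []
    for c in centroids:
        res = minimize(
            problem.safe_objective,
            np.clip(c, [b[0] for b in problem.bounds], [b[1] for b in problem.bounds]),
            method="L-BFGS-B",
            bounds=problem.bounds,
        )
        # keep whichever of centroid/refined is better (refinement never hurts)
        fc = problem.safe_objective(c)
        if res.fun <= fc:
            refined.append(res.x)
            refined_f.append(float(res.fun))
        else:
            refined.append(c)
            refined_f.append(fc)
    refined = np.array(refined)
    refined_f = np.array(refined_f)
    ibest = int(np.argmin(refined_f))
    # the best raw candidate also competes, so refinement cannot lose ground
    if objectives.min() < refined_f[ibest]:
        best = candidates[int(np.argmin(objectives))]
        best_f = float(objectives.min())
    else:
        best = refined[ibest]
        best_f = float(refined_f[ibest])
    return TuningResult(
        candidates=candidates,
        candidate_objectives=objectives,
        centroids=centroids,
        refined=refined,
        refined_objectives=refined_f,
        best=best,
        best_objective=best_f,
        names=problem.names,
        seed=seed,
    )


def make_recovery_problem(
    model: str,
    free: dict[str, tuple[float, float]],
    true_params: dict[str, float],
    paradigm: str,
    paradigm_params: dict | None = None,
    quantity: str = "yaw",
    duration: float = 60.0,
    dt: float = 0.02,
    noise_frac: float = 0.05,
    seed: int | None = None,
    base_preset: str = "perception",
) -> tuple[TuningProblem, np.ndarray]:
    """Build a synthetic parameter-recovery problem.

    A percept series is generated from the model at ``true_params`` (the
    remaining parameters come from ``base_preset``) with additive Gaussian
    observation noise of sd ``noise_frac`` times the percept amplitude.  The
    returned problem minimizes the SMAE between the model percept at a trial
    parameter vector and that noisy report.  Intended for the deterministic
    models (SVM / MSOM).

    Returns ``(problem, report_series)``.
    """
    from dataclasses import replace

    from .analysis import percept_series, resolve_params, smae
    from .stimuli import make_paradigm

    base = resolve_params(model, base_preset)
    names = list(free.keys())
    bounds = [free[n] for n in names]
    stim = make_paradigm(paradigm, duration=duration, dt=dt, **(paradigm_params or {}))

    truth = replace(base, **true_params)
    clean = percept_series(model, truth, stim, quantity)
    amp = np.max(np.abs(clean))
    rng = np.random.default_rng(seed)
    report = clean + rng.normal(0.0, noise_frac * amp, size=clean.shape)

    def objective(x: np.ndarray) -> float:
        trial = replace(base, **dict(zip(names, x)))
        pred = percept_series(model, trial, stim, quantity)
        return smae(pred, report)

    x0 = np.array([getattr(base, n) for n in names])
    problem = TuningProblem(
        model=model, names=names, bounds=bounds, objective=objective, x0=x0
    )
    return problem, report


def tune(
    problem: TuningProblem,
    n_runs: int = 10,
    n_iter: int = 100,
    k: int = 3,
    seed: int | None = None,
) -> TuningResult:
    """Full pipeline: SA search, k-means clustering, local refinement."""
    cands, objs = sa_search(problem, n_runs=n_runs, n_iter=n_iter, seed=seed)
    return cluster_and_refine(problem, cands, objs, k=k, seed=seed)
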