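from dataclasses import replace

import numpy as np
import pytest

from vsom.svm import SVMParams, svm_evar_time_constant
from vsom.tuning import (
    TuningProblem,
    anchor_evar,
    cluster_and_refine,
    make_recovery_problem,
    sa_search,
    tune,
)


def svm_tau_predictor(k_wc: float) -> float:
    if k_wc == 0.0:
        return 5.7  # raw canal decay, no velocity storage
    return svm_evar_time_constant(
        SVMParams(K_wc=k_wc), duration=160.0, dt=0.02, fit_window=(2.0, 150.0)
    )


class TestAnchoring:
    def test_published_time_constant_recovers_published_gain(self):
        gain = anchor_evar(svm_tau_predictor, 18.7, gain_bounds=(0.0, 10.0))
        assert gain == pytest.approx(2.28, rel=0.02)

    def test_anchor_at_raw_canal_needs_no_storage(self):
        gain = anchor_evar(svm_tau_predictor, 5.7, gain_bounds=(0.0, 10.0))
        assert gain == pytest.approx(0.0, abs=0.05)

    def test_long_anchor_needs_high_gain(self):
        gain = anchor_evar(svm_tau_predictor, 28.5, gain_bounds=(0.0, 10.0))
        assert gain == pytest.approx(4.0, rel=0.03)

    def test_unreachable_anchor_raises(self):
        with pytest.raises(ValueError):
            anchor_evar(svm_tau_predictor, 500.0, gain_bounds=(0.0, 10.0))


class TestSimulatedAnnealing:
    def test_convex_bowl(self):
        target = np.array([1.3, -0.4])
        problem = TuningProblem(
            model="toy",
            names=["a", "b"],
            bounds=[(-3.0, 3.0), (-3.0, 3.0)],
            objective=lambda x: float(np.sum((x - target) ** 2)),
            x0=np.zeros(2),
        )
        cands, objs = sa_search(problem, n_runs=10, n_iter=100, seed=0)
        assert len(cands) <= 30
        assert np.linalg.norm(cands[0] - target) < 0.05 * 6.0  # 5% of bound width

    def test_multimodal_beats_random_search_at_equal_budget(self):
        def rastrigin(x):
            return float(10 * 2 + np.sum(x**2 - 10 * np.cos(2 * np.pi * x)))

        problem = TuningProblem(
            model="toy",
            names=["a", "b"],
            bounds=[(-4.0, 4.0), (-4.0, 4.0)],
            objective=rastrigin,
            x0=np.array([2.5, -2.5]),
        )
        cands, objs = sa_search(problem, n_runs=10, n_iter=100, seed=3)
        rng = np.random.default_rng(3)
        random_draws = rng.uniform(-4.0, 4.0, size=(1000, 2))
        best_random = min(rastrigin(x) for x in random_draws)
        assert objs[0] < best_random

    def test_objective_failures_are_penalized_not_fatal(self):
        def flaky(x):
            if x[0] > 0.5:
                raise RuntimeError("model blew up")
            return float(x[0] ** 2)

        problem = TuningProblem(
            model="toy", names=["a"], bounds=[(-1.0, 1.0)], objective=flaky,
            x0=np.array([0.0]),
        )
        cands, objs = sa_search(problem, n_runs=3, n_iter=30, seed=1)
        assert np.isfinite(objs).all()


class TestClusterRefine:
    def test_separable_clusters_recovered(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0.0, 0.0], [5.0, 5.0], [-5.0, 4.0]])
        cands = np.vstack([c + 0.05 * rng.normal(size=(20, 2)) for c in centers])
        objs = np.array([np.min(np.sum((x - centers) ** 2, axis=1)) for x in cands])
        problem = TuningProblem(
            model="toy",
            names=["a", "b"],
            bounds=[(-8.0, 8.0), (-8.0, 8.0)],
            objective=lambda x: float(np.min(np.sum((x - centers) ** 2, axis=1))),
        )
        result = cluster_and_refine(problem, cands, objs, k=3, seed=0)
        found = sorted(result.centroids.tolist())
        expected = sorted(centers.tolist())
        for f, e in zip(found, expected):
            assert np.allclose(f, e, atol=0.1)
        assert (result.refined_objectives <= result.candidate_objectives.min() + 1e-9).any()

    def test_identical_candidates_degenerate_gracefully(self):
        cands = np.tile([1.0, 2.0], (10, 1))
        objs = np.full(10, 3.0)
        problem = TuningProblem(
            model="toy",
            names=["a", "b"],
            bounds=[(0.0, 4.0), (0.0, 4.0)],
            objective=lambda x: float(np.sum((x - [1.0, 2.0]) ** 2) + 3.0),
        )
        result = cluster_and_refine(problem, cands, objs, k=3, seed=0)
        assert result.centroids.shape[0] == 1
        assert result.best_objective <= 3.0 + 1e-9

    def test_refined_never_worse_than_raw_candidates(self):
        problem = TuningProblem(
            model="toy",
            names=["a"],
            bounds=[(-2.0, 2.0)],
            objective=lambda x: float((x[0] - 0.7) ** 4),
            x0=np.array([0.0]),
        )
        cands, objs = sa_search(problem, n_runs=4, n_iter=40, seed=2)
        result = cluster_and_refine(problem, cands, objs, k=3, seed=2)
        assert result.best_objective <= objs.min() + 1e-12


class TestEndToEndRecovery:
    def test_svm_parameter_recovery_from_noisy_reports(self):
        """Percept reports generated from known low-pass/gravity-gain values
        are recovered by anchor + SA + cluster + refine within 15%."""
        truth = {"tau_lp_xy": 1.9, "K_gc_xy": 1.2}
        problem, report = make_recovery_problem(
            model="svm",
            free={"tau_lp_xy": (0.3, 8.0), "K_gc_xy": (0.3, 8.0)},
            true_params=truth,
            paradigm="CENTRIFUGE",
            paradigm_params={"rate": 250.0, "radius": 0.54},
            quantity="roll",
            duration=60.0,
            dt=0.02,
            noise_frac=0.05,
            seed=42,
        )
        result = tune(problem, n_runs=4, n_iter=40, seed=7)
        recovered = dict(zip(result.names, result.best))
        for name, true_val in truth.items():
            assert recovered[name] == pytest.approx(true_val, rel=0.15)
        # objective comparable to the irreducible noise floor
        assert result.best_objective < 2.0 * problem.safe_objective(
            np.array([truth[n] for n in result.names])
        )

    def test_determinism_byte_for_byte(self):
        problem = TuningProblem(
            model="toy",
            names=["a", "b"],
            bounds=[(-1.0, 1.0), (-1.0, 1.0)],
            objective=lambda x: float(np.sum(x**2)),
            x0=np.array([0.5, -0.5]),
        )
        r1 = tune(problem, n_runs=3, n_iter=30, seed=9)
        r2 = tune(problem, n_runs=3, n_iter=30, seed=9)
        assert r1.to_json() == r2.to_json()
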