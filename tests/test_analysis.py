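import numpy as np
import pytest

from vsom.analysis import (
    FrequencyResponse,
    fit_time_constant,
    freq_response,
    komega_sweep,
    sickness_sensitivity,
    smae,
)
from vsom.svm import SVMParams, svm_conflict_tf, svm_evar_time_constant


class TestTimeConstantFit:
    def test_self_fit_decay(self):
        t = np.arange(0, 100, 0.05)
        y = 30.0 * np.exp(-t / 18.7)
        fit = fit_time_constant(t, y, "decay")
        assert fit.b == pytest.approx(1 / 18.7, abs=1e-6)
        assert fit.A == pytest.approx(30.0, rel=1e-6)

    def test_self_fit_saturating(self):
        t = np.arange(0, 200, 0.1)
        y = 10.0 * (1.0 - np.exp(-0.05 * t))
        fit = fit_time_constant(t, y, "saturating")
        assert fit.A == pytest.approx(10.0, rel=1e-6)
        assert fit.b == pytest.approx(0.05, rel=1e-6)

    def test_noisy_recovery_monte_carlo(self, rng):
        """Mean recovered rate over 50 noisy replicates stays within 2%."""
        t = np.arange(0, 100, 0.1)
        clean = 20.0 * np.exp(-t / 15.0)
        bs = []
        for _ in range(50):
            noisy = clean + rng.normal(0, 1.0, t.size)  # 5% of amplitude
            bs.append(fit_time_constant(t, noisy, "decay").b)
        assert np.mean(bs) == pytest.approx(1 / 15.0, rel=0.02)

    def test_window_respected_and_small_windows_rejected(self):
        t = np.arange(0, 100, 0.1)
        y = np.exp(-t / 5.0)
        with pytest.raises(ValueError):
            fit_time_constant(t, y, "decay", window=(0.0, 0.5))

    def test_non_decaying_signal_flagged(self):
        t = np.arange(0, 50, 0.1)
        with pytest.raises(RuntimeError):
            fit_time_constant(t, np.sin(t), "decay")


class TestFrequencyResponseUtilities:
    def test_break_frequency_of_known_first_order_lag(self):
        tau = 1.0 / (2 * np.pi * 0.25)  # corner at 0.25 Hz
        freqs = np.logspace(np.log10(0.01), np.log10(2.0), 30)
        gain = 1.0 / np.sqrt(1.0 + (2 * np.pi * freqs * tau) ** 2)
        resp = FrequencyResponse(freqs=freqs, gain=gain, probe_amplitude=1.0)
        fb = resp.break_frequency()
        # within one grid step of the analytic corner
        step = freqs[1] / freqs[0]
        assert 0.25 / step <= fb <= 0.25 * step

    def test_peak_and_normalization(self):
        freqs = np.logspace(-2, 0.3, 30)
        gain = freqs / (1.0 + (freqs / 0.2) ** 2)
        resp = FrequencyResponse(freqs=freqs, gain=gain, probe_amplitude=1.0)
        norm = resp.normalized()
        assert norm.gain.max() == pytest.approx(1.0)
        assert norm.peak_frequency() == resp.peak_frequency()


class TestModelFrequencyResponses:
    def test_linearized_svm_matches_conflict_tf(self, svm_perception):
        """The simulated gravity-conflict gain reproduces the closed-form
        transfer function across the band (cross-module oracle)."""
        freqs = np.array([0.02, 0.1, 0.3, 1.0])
        resp = freq_response(
            "svm", svm_perception, input_axis="y", output_quantity="c_g", freqs=freqs
        )
        num, den = svm_conflict_tf(svm_perception, "c_g", "xy")
        for f0, gain in zip(resp.freqs, resp.gain):
            s = 2j * np.pi * f0
            expected = abs(np.polyval(num, s) / np.polyval(den, s))
            assert gain == pytest.approx(expected, rel=0.02)

    def test_sensitivity_peak_invariant_to_probe_amplitude(self, svm_perception):
        freqs = np.logspace(np.log10(0.05), 0.0, 12)
        peaks = [
            sickness_sensitivity(
                "svm", svm_perception, axis="vertical", freqs=freqs, amplitude=a
            ).peak_frequency()
            for a in (0.05, 0.2)
        ]
        assert peaks[0] == peaks[1]


class TestKomegaSweep:
    def test_lta_flat_prp_decreasing_with_feedback_gain(self, svm_perception):
        sweep = komega_sweep(svm_perception, [1.0, 2.28, 4.0, 8.0], duration=60.0)
        lta = sweep["LTA"]
        assert lta.max() / lta.min() < 1.01  # unresponsive to K_wc
        prp = sweep["PRP"]
        assert prp[-1] < prp[0]  # monotone trend toward an asymptote
        assert np.all(np.diff(prp) < 0)

    def test_high_gain_side_effect_on_evar(self):
        tau = svm_evar_time_constant(SVMParams(K_wc=4.0))
        assert tau > 28.0


class TestSMAE:
    def test_closed_form_cases(self):
        r = np.linspace(1.0, 2.0, 50)
        assert smae(r, r) == pytest.approx(0.0, abs=1e-12)
        assert smae(2 * r, r) == pytest.approx(2.0 / 3.0, rel=1e-9)
        assert smae(-r, r) == pytest.approx(2.0, rel=1e-9)

    def test_reference_resampled_onto_overlap(self):
        t_ref = np.linspace(0, 10, 300)
        t_pred = np.linspace(2, 8, 100)
        ref = np.sin(t_ref)
        pred = np.sin(t_pred)
        assert smae(pred, ref, t_pred=t_pred, t_ref=t_ref) < 1e-3

    def test_disjoint_grids_error(self):
        with pytest.raises(ValueError):
            smae(np.ones(5), np.ones(5), t_pred=np.arange(5.0), t_ref=np.arange(10.0, 15.0))

    def test_range_bounded(self, rng):
        p = rng.normal(size=200)
        r = rng.normal(size=200)
        assert 0.0 <= smae(p, r) <= 2.0
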