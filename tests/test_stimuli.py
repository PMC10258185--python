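import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vsom.core import G
from vsom.stimuli import (
    ChainConfig,
    Joint,
    chain_to_stimulus,
    make_paradigm,
    static_joint,
    synth_perception,
)


class TestKinematicChain:
    def test_static_chain_senses_only_gravity(self):
        cfg = ChainConfig([static_joint(), static_joint(), static_joint()])
        stim = chain_to_stimulus(cfg, duration=5.0)
        norms = np.linalg.norm(stim.f_h, axis=0)
        assert np.allclose(norms, G, atol=1e-9)
        assert np.allclose(stim.omega_h, 0.0, atol=1e-12)

    @given(
        angle=st.floats(-np.pi, np.pi),
        axis=st.sampled_from([(1, 0, 0), (0, 1, 0), (0, 0, 1)]),
    )
    def test_static_posture_preserves_gravity_magnitude(self, angle, axis):
        joints = [
            Joint("revolute", axis, lambda t, a=angle: np.full_like(t, a)),
            static_joint(),
            static_joint(),
        ]
        stim = chain_to_stimulus(ChainConfig(joints), duration=2.0)
        assert np.allclose(np.linalg.norm(stim.f_h, axis=0), G, atol=1e-9)
        assert np.allclose(stim.omega_h, 0.0, atol=1e-12)

    @pytest.mark.parametrize(
        "rate, radius, expected",
        [(250.0, 0.54, 10.3), (200.0, 1.0, 12.2), (36.0, 6.1, 2.41)],
    )
    def test_centrifugation_centripetal_magnitude(self, rate, radius, expected):
        stim = make_paradigm("CENTRIFUGE", rate=rate, radius=radius, duration=10.0)
        centripetal = np.hypot(stim.f_h[0, -1], stim.f_h[1, -1])
        omega = np.radians(rate)
        assert centripetal == pytest.approx(omega**2 * radius, rel=1e-3)
        assert centripetal == pytest.approx(expected, rel=0.01)

    def test_chain_rejects_non_finite_trajectory(self):
        bad = Joint("revolute", (0, 0, 1), lambda t: np.where(t > 0.5, np.nan, 0.0), name="yaw")
        cfg = ChainConfig([bad, static_joint(), static_joint()])
        with pytest.raises(ValueError, match="yaw"):
            chain_to_stimulus(cfg, duration=2.0)

    def test_chain_requires_three_joints(self):
        with pytest.raises(ValueError):
            ChainConfig([static_joint()])


class TestParadigms:
    def test_lta_matches_closed_form(self):
        stim = make_paradigm("LTA", amplitude=0.89, freq=0.2, duration=30.0)
        expected = 0.89 * np.sin(2 * np.pi * 0.2 * stim.t)
        assert np.allclose(stim.f_h[1], expected, atol=2e-4)
        assert np.allclose(stim.f_h[0], 0.0, atol=1e-12)
        assert np.allclose(stim.f_h[2], G, atol=1e-9)
        assert np.all(stim.omega_h == 0.0)

    def test_vta_is_vertical(self):
        stim = make_paradigm("VTA", amplitude=0.89, freq=0.2, duration=10.0)
        assert np.allclose(stim.f_h[2] - G, 0.89 * np.sin(2 * np.pi * 0.2 * stim.t), atol=2e-4)
        assert np.allclose(stim.f_h[:2], 0.0, atol=1e-12)

    def test_ovar_geometry_and_periodicity(self):
        stim = make_paradigm("OVAR", tilt=15.0, rate=30.0, duration=40.0)
        # gravity component along the tilted long body axis is constant
        assert np.allclose(stim.f_h[2], G * np.cos(np.radians(15.0)), atol=1e-6)
        # periodic with 360/rate = 12 s after the spin-up ramp
        period_samples = int(round(12.0 / stim.dt))
        sel = (stim.t >= 5.0) & (stim.t <= 20.0)
        idx = np.nonzero(sel)[0]
        assert np.allclose(
            stim.f_h[:, idx], stim.f_h[:, idx + period_samples], atol=1e-6
        )

    def test_evar_is_pure_earth_vertical_rotation(self):
        stim = make_paradigm("EVAR", rate=90.0, duration=10.0)
        assert np.allclose(stim.f_h[:2], 0.0, atol=1e-7)
        assert np.allclose(stim.f_h[2], G, atol=1e-7)
        # rate reached after the 1 s ramp
        assert stim.omega_h[2, -1] == pytest.approx(np.radians(90.0), rel=1e-6)

    def test_cccp_roll_steps_alternate(self):
        stim = make_paradigm("CCCP", rate=138.0, duration=40.0, dwell=10.0, roll_duration=2.0)
        wx = stim.omega_h[0]
        # roll movement inside the transition windows, none during dwells
        t = stim.t
        moving = np.abs(wx) > 1e-6
        assert moving[(t > 10.2) & (t < 11.8)].all()
        assert not moving[(t > 5.0) & (t < 9.5)].any()
        # integrated roll angle toggles between 0 and 45 deg
        roll = np.cumsum(wx) * stim.dt
        assert np.degrees(roll[(t > 15) & (t < 21)]).mean() == pytest.approx(45.0, abs=0.5)
        assert np.degrees(roll[(t > 27) & (t < 33)]).mean() == pytest.approx(0.0, abs=0.5)

    def test_paradigm_errors(self):
        with pytest.raises(ValueError):
            make_paradigm("SPIN")
        with pytest.raises(ValueError):
            make_paradigm("OVAR", tilt=95.0)
        with pytest.raises(ValueError):
            make_paradigm("CENTRIFUGE", radius=-1.0)


class TestSyntheticReports:
    def test_closed_forms(self):
        r = synth_perception("evar_decay", A=30.0, b=1 / 18.7, t=np.array([0.0, 1.0]))
        assert r.values[0] == pytest.approx(30.0)
        r2 = synth_perception(
            "centrifuge_roll", A=10.0, b=0.05, t=np.array([0.0, 1000.0])
        )
        assert r2.values[-1] == pytest.approx(10.0, rel=1e-6)

    def test_noiseless_matches_stated_form_exactly(self):
        t = np.linspace(0.0, 50.0, 501)
        r = synth_perception("ovar_sine", A=2.0, b=0.1, t=t)
        assert np.array_equal(r.values, 2.0 * np.sin(2 * np.pi * 0.1 * t))

    def test_noise_is_reproducible_and_rate_recoverable(self):
        from scipy.optimize import curve_fit

        t = np.arange(0.0, 100.0, 0.1)
        r1 = synth_perception("evar_decay", A=30.0, b=1 / 18.7, noise_sd=0.5, seed=7, t=t)
        r2 = synth_perception("evar_decay", A=30.0, b=1 / 18.7, noise_sd=0.5, seed=7, t=t)
        assert np.array_equal(r1.values, r2.values)
        popt, pcov = curve_fit(
            lambda tt, A, b: A * np.exp(-b * tt), t, r1.values, p0=(25.0, 0.1)
        )
        se_b = np.sqrt(pcov[1, 1])
        assert abs(popt[1] - 1 / 18.7) < 3 * se_b

    def test_validation(self):
        with pytest.raises(ValueError):
            synth_perception("evar_decay", A=1.0, b=-0.1)
        with pytest.raises(ValueError):
            synth_perception("evar_decay", A=1.0, b=0.1, t=np.array([]))
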