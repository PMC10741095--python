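"""Hill-model factors and the Lagrangian torque oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from etorque import biomech as bm
from etorque.dataio import SubjectAnthropometry
from etorque.errors import DomainError, IntegrityError


def _unit_anthro():
    """segment mass 1 kg on a 0.3 m lever, for hand-computable torques."""
    return SubjectAnthropometry(body_mass=70.0, forearm_length=0.265,
                                elbow_radius=0.035, segment_mass=1.0)


class TestActivation:
    @pytest.mark.parametrize("u,expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_endpoints(self, u, expected):
        assert bm.activation(u, A=-2.0) == pytest.approx(expected)

    def test_worked_value(self):
        expected = (np.exp(-1.0) - 1.0) / (np.exp(-2.0) - 1.0)
        assert bm.activation(0.5, A=-2.0) == pytest.approx(expected, rel=1e-9)
        assert bm.activation(0.5, A=-2.0) == pytest.approx(0.7311, abs=1e-4)

    def test_domain_checks(self):
        with pytest.raises(DomainError):
            bm.activation(1.5, A=-2.0)
        with pytest.raises(DomainError):
            bm.activation(0.5, A=0.0)

    @given(st.floats(-5.0, -0.01))
    @settings(deadline=None, max_examples=50)
    def test_strictly_increasing_onto_unit_interval(self, A):
        u = np.linspace(0, 1, 101)
        a = bm.activation(u, A)
        assert np.all(np.diff(a) > 0)
        assert a[0] == pytest.approx(0.0, abs=1e-12)
        assert a[-1] == pytest.approx(1.0, abs=1e-12)


class TestThelenCurves:
    def test_force_length_optimum_and_worked_value(self):
        assert bm.force_length(1.0) == 1.0
        assert bm.force_length(1.5) == pytest.approx(np.exp(-0.25 / 0.45), rel=1e-9)
        assert bm.force_length(1.5) == pytest.approx(0.5738, abs=1e-4)

    @given(st.floats(0.01, 0.9))
    @settings(deadline=None, max_examples=50)
    def test_force_length_symmetric_about_optimum(self, d):
        assert bm.force_length(1 + d) == pytest.approx(bm.force_length(1 - d))

    def test_force_length_domain(self):
        with pytest.raises(DomainError):
            bm.force_length(0.0)

    def test_force_velocity_isometric_and_max_shortening(self):
        assert bm.force_velocity(0.0) == pytest.approx(1.0)
        assert bm.force_velocity(1.0) == pytest.approx(0.0, abs=1e-6)

    def test_force_velocity_monotone_and_ecc_plateau(self):
        v = np.linspace(-3.0, 1.2, 400)
        fv = bm.force_velocity(v)
        assert np.all(np.diff(fv) <= 1e-12)  # non-increasing with shortening
        assert np.all(fv <= 1.4 + 1e-12)
        assert bm.force_velocity(-50.0) == pytest.approx(1.4, abs=0.01)


class TestForces:
    def test_active_fiber_force(self):
        assert bm.active_fiber_force(0.0, 1.0, 1.0, 300.0) == 0.0
        assert bm.active_fiber_force(1.0, 1.0, 1.0, 300.0) == 300.0
        assert bm.active_fiber_force(0.5, 0.8, 1.0, 300.0) == pytest.approx(120.0)

    def test_muscle_force_pennation(self):
        assert bm.muscle_force(100.0, phi=0.0, f_pe=25.0) == pytest.approx(125.0)
        assert bm.muscle_force(100.0, phi=np.deg2rad(10.0)) == pytest.approx(98.48, abs=0.01)
        assert bm.muscle_force(0.0, phi=0.3) == 0.0

    def test_pennation_domain(self):
        with pytest.raises(DomainError):
            bm.muscle_force(10.0, phi=np.pi / 2)

    def test_hill_elbow_torque_signed_sum(self):
        assert bm.hill_elbow_torque({"biceps": 0.0, "triceps": 0.0,
                                     "brachioradialis": 0.0}) == 0.0
        assert bm.hill_elbow_torque({"biceps": 100.0}) == pytest.approx(3.0)
        # co-contraction producing equal and opposite moments cancels
        f_ext = 100.0 * 0.030 / 0.021
        assert bm.hill_elbow_torque({"biceps": 100.0, "triceps": f_ext}) == \
            pytest.approx(0.0, abs=1e-12)


class TestLagrange:
    def test_rest_configuration_zero(self):
        assert bm.lagrange_torque(0.0, 0.0, _unit_anthro()) == 0.0

    def test_gravity_term(self):
        # m=1 kg, lever 0.3 m, beta=90 deg, no acceleration
        t = bm.lagrange_torque(np.pi / 2, 0.0, _unit_anthro())
        assert t == pytest.approx(-2.94, abs=1e-9)

    def test_inertial_term(self):
        t = bm.lagrange_torque(0.0, 2.0, _unit_anthro())
        assert t == pytest.approx(0.18, abs=1e-12)

    def test_linear_in_mass_and_acceleration(self, rng):
        beta = rng.uniform(-2, 2)
        bdd = rng.uniform(-5, 5)
        a1 = _unit_anthro()
        a2 = SubjectAnthropometry(body_mass=70.0, forearm_length=0.265,
                                  elbow_radius=0.035, segment_mass=3.0)
        assert bm.lagrange_torque(beta, bdd, a2) == \
            pytest.approx(3.0 * bm.lagrange_torque(beta, bdd, a1), rel=1e-12)
        g0 = bm.lagrange_torque(beta, 0.0, a1)
        assert bm.lagrange_torque(-beta, 0.0, a1) == pytest.approx(-g0, rel=1e-12)

    def test_labels_constant_angle_is_pure_gravity(self):
        anthro = _unit_anthro()
        labels = bm.torque_labels(np.full(20, 30.0), anthro, dt=0.025)
        expected = -1.0 * 9.8 * 0.3 * np.sin(np.deg2rad(30.0))
        np.testing.assert_allclose(labels.torque, expected, rtol=1e-12)

    def test_labels_slow_ramp_tracks_gravity_term(self):
        anthro = _unit_anthro()
        beta = np.linspace(5.0, 100.0, 400)  # 10 s ramp at 40 windows/s
        labels = bm.torque_labels(beta, anthro, dt=0.025)
        gravity = bm.lagrange_torque(np.deg2rad(beta), 0.0, anthro)
        err = np.max(np.abs(labels.torque - gravity))
        assert err < 0.01 * np.max(np.abs(gravity))

    def test_labels_match_closed_form_sinusoid(self):
        anthro = _unit_anthro()
        f = 0.25  # Hz
        t = (np.arange(400) + 0.5) * 0.025  # 40 windows/s
        beta_deg = 60.0 + 50.0 * np.sin(2 * np.pi * f * t)
        labels = bm.torque_labels(beta_deg, anthro, dt=0.025)
        beta = np.deg2rad(beta_deg)
        bdd = -np.deg2rad(50.0) * (2 * np.pi * f) ** 2 * np.sin(2 * np.pi * f * t)
        exact = bm.lagrange_torque(beta, bdd, anthro)
        err = np.max(np.abs(labels.torque[2:-2] - exact[2:-2]))
        assert err < 0.01 * np.max(np.abs(exact))

    def test_labels_need_three_windows(self):
        with pytest.raises(IntegrityError):
            bm.torque_labels(np.array([10.0, 20.0]), _unit_anthro(), dt=0.025)


class TestHillVsLagrange:
    def test_same_trial_torques_positively_correlated(self, anthro):
        """Both torque models rise and fall together on one flexion cycle."""
        from etorque import synth
        cfg = synth.SynthConfig(n_cycles=1, seed=0)
        beta = synth.make_trajectory(cfg)
        env = synth.make_activation(beta, anthro)
        omega = np.gradient(beta) * cfg.fs_angle
        hill = bm.hill_torque_series(env, beta, omega)
        demand = bm.required_active_torque(beta, cfg.fs_angle, anthro)
        r = np.corrcoef(hill.torque, demand)[0, 1]
        assert r > 0.8
        # the inverse-dynamics demand may exceed the active Hill torque
        assert np.max(np.abs(hill.torque)) <= 5 * np.max(np.abs(demand))
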