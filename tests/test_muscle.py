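import numpy as np
import pytest
from hypothesis import given, settings, strategies as stst

from nmskit.model import Model
from nmskit.muscle import (EmgSettings, MuscleTendonParams,
                           activation_dynamics, activation_nonlinearity,
                           delay_and_scale, inverse_activation_dynamics,
                           muscle_joint_moments, muscle_tendon_force,
                           process_emg, rigid_tendon_state)
from nmskit.tables import TimeSeriesTable


@pytest.fixture
def params():
    return MuscleTendonParams()


class TestProcessEmg:
    def _table(self, x, fs=1000.0):
        t = np.arange(len(x)) / fs
        return TimeSeriesTable(t, {"ch": x})

    def test_dc_channel_becomes_zero(self):
        env, flagged = process_emg(self._table(np.full(2000, 0.4)), tf=1.0)
        np.testing.assert_allclose(env["ch"], 0.0, atol=1e-9)

    def test_normalization_contract_min_zero_max_one(self):
        rng = np.random.default_rng(0)
        t = np.arange(2000) / 1000
        x = np.sin(2 * np.pi * 80 * t) * (1 + 0.5 * np.sin(2 * np.pi * t))
        env, flagged = process_emg(self._table(x), tf=2.0)
        assert env["ch"].min() == pytest.approx(0.0, abs=1e-12)
        assert env["ch"].max() == pytest.approx(1.0, abs=1e-9)
        assert not flagged

    def test_highpass_keeps_80hz_removes_drift(self):
        t = np.arange(4000) / 1000
        burst = np.sin(2 * np.pi * 80 * t) * (t > 2)
        drift = 5.0 * np.sin(2 * np.pi * 0.5 * t)
        env, _ = process_emg(self._table(burst + drift), tf=4.0)
        # envelope must concentrate on the burst half despite a drift of
        # 5x the burst amplitude
        first, second = env["ch"][:2000].mean(), env["ch"][2200:3800].mean()
        assert second > 5 * max(first, 1e-6)

    def test_all_zero_channel_flagged_not_error(self):
        env, flagged = process_emg(self._table(np.zeros(1000)), tf=1.0)
        assert flagged == ["ch"]
        np.testing.assert_array_equal(env["ch"], 0.0)


class TestDelayAndScale:
    def test_identity(self):
        t = np.linspace(-0.2, 1.0, 121)
        env = np.sin(t) ** 2
        out = delay_and_scale(t, env, 0.0, 1.0)
        np.testing.assert_allclose(out, env, atol=1e-12)

    def test_pad_is_about_18_points_on_standard_grid(self):
        """A 1.111 s cycle resampled to 101 points has dt = 1.111/100;
        the 0.2 s pad then spans ~18 samples."""
        dt = 1.111 / 100
        assert round(0.2 / dt) == 18

    def test_scale_linearity(self):
        t = np.linspace(-0.2, 1.0, 121)
        env = np.abs(np.sin(5 * t))
        np.testing.assert_allclose(delay_and_scale(t, env, 0.05, 0.5),
                                   0.5 * delay_and_scale(t, env, 0.05, 1.0))

    def test_delay_beyond_pad_rejected(self):
        t = np.linspace(-0.2, 1.0, 121)
        with pytest.raises(ValueError, match="pad"):
            delay_and_scale(t, np.zeros_like(t), 0.25, 1.0)


class TestActivationDynamics:
    def test_constant_excitation_reaches_fixed_point(self, params):
        t = np.linspace(0, 1, 500)
        a = activation_dynamics(t, np.full_like(t, 0.7), params)
        assert abs(a[-1] - 0.7) < 1e-6

    def test_zero_excitation_stays_zero(self, params):
        t = np.linspace(0, 1, 100)
        a = activation_dynamics(t, np.zeros_like(t), params)
        np.testing.assert_array_equal(a, 0.0)

    def test_step_response_time_constant(self, params):
        """Time to 63.2% of a step matches tau_act within one sample."""
        dt = 0.001
        t = np.arange(0, 0.2, dt)
        e = np.where(t >= 0.05, 1.0, 0.0)
        a = activation_dynamics(t, e, params)
        i63 = np.argmax(a >= 1 - np.exp(-1))
        t63 = t[i63] - 0.05
        assert abs(t63 - params.activation_time_constant) <= dt + 1e-12

    def test_inverse_recovers_excitation(self, params):
        t = np.linspace(0, 1, 101)
        e = 0.5 + 0.4 * np.sin(2 * np.pi * t) ** 2
        a = activation_dynamics(t, e, params)
        e2 = inverse_activation_dynamics(t, a, params)
        np.testing.assert_allclose(e2[1:], e[1:], atol=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=stst.integers(0, 10 ** 6),
           tact=stst.floats(0.005, 0.05), tdeact=stst.floats(0.02, 0.12))
    def test_activation_bounded_for_bounded_excitation(self, seed, tact,
                                                       tdeact):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 1, 60)
        e = rng.random(60)
        p = MuscleTendonParams(activation_time_constant=tact,
                               deactivation_time_constant=tdeact)
        a = activation_dynamics(t, e, p)
        assert np.all(a >= -1e-12) and np.all(a <= 1 + 1e-12)


class TestActivationNonlinearity:
    def test_endpoints_fixed(self):
        for A in (-3.0, -1.0, -0.1):
            assert activation_nonlinearity(0.0, A) == pytest.approx(0.0)
            assert activation_nonlinearity(1.0, A) == pytest.approx(1.0)

    def test_small_A_limit_is_identity(self):
        a = np.linspace(0, 1, 11)
        np.testing.assert_allclose(activation_nonlinearity(a, -1e-6), a,
                                   atol=1e-6)

    def test_direct_formula_value(self):
        A, a = -2.0, 0.5
        expected = (np.exp(A * a) - 1) / (np.exp(A) - 1)
        assert activation_nonlinearity(a, A) == pytest.approx(expected)


class TestRigidTendon:
    def test_zero_pennation_fiber_length(self):
        p = MuscleTendonParams(optimal_fiber_length=0.1,
                               tendon_slack_length=0.2)
        ln, vn, cp, _ = rigid_tendon_state(0.27, 0.0, p)
        assert ln == pytest.approx(0.07 / 0.1)
        assert cp == pytest.approx(1.0)

    def test_optimal_pose(self):
        p = MuscleTendonParams(optimal_fiber_length=0.1,
                               tendon_slack_length=0.2)
        ln, vn, cp, _ = rigid_tendon_state(0.3, 0.0, p)
        assert (ln, vn, cp) == pytest.approx((1.0, 0.0, 1.0))

    def test_pennation_right_triangle(self):
        phi = np.deg2rad(20)
        p = MuscleTendonParams(optimal_fiber_length=0.1,
                               tendon_slack_length=0.2,
                               pennation_at_optimal=phi)
        ln, _, cp, _ = rigid_tendon_state(0.2 + 0.1 * np.cos(phi), 0.0, p)
        assert ln == pytest.approx(1.0)
        assert cp == pytest.approx(np.cos(phi))

    def test_guard_clamps_and_flags(self):
        p = MuscleTendonParams(optimal_fiber_length=0.1,
                               tendon_slack_length=0.2)
        *_, clamped = rigid_tendon_state(np.array([0.10, 0.30]), 0.0, p)
        assert list(clamped) == [True, False]


class TestMuscleForce:
    def test_normalization_at_optimal(self, params):
        F, Fp = muscle_tendon_force(1.0, 1.0, 0.0, 1.0, params)
        assert F == pytest.approx(params.max_isometric_force)
        assert Fp == pytest.approx(0.0)

    def test_zero_activation_zero_force_at_optimal(self, params):
        F, _ = muscle_tendon_force(0.0, 1.0, 0.0, 1.0, params)
        assert F == pytest.approx(0.0)

    def test_concentric_limit_kills_active_force(self, params):
        for a in (0.2, 1.0):
            F, Fp = muscle_tendon_force(a, 1.0, -1.0, 1.0, params)
            assert F == pytest.approx(Fp)

    def test_force_monotone_in_activation(self, params):
        a = np.linspace(0, 1, 20)
        F, _ = muscle_tendon_force(a, 0.9, -0.1, 1.0, params)
        assert np.all(np.diff(F) > 0)

    def test_passive_zero_below_optimal_and_one_at_1p6(self, params):
        _, Fp_low = muscle_tendon_force(0.0, 0.9, 0.0, 1.0, params)
        assert Fp_low == pytest.approx(0.0)
        _, Fp_ref = muscle_tendon_force(0.0, 1.6, 0.0, 1.0, params)
        assert Fp_ref == pytest.approx(params.max_isometric_force)


class TestJointMoments:
    @pytest.fixture
    def model(self):
        m = Model()
        m.add_segment("seg", com=(0, -0.5, 0))
        m.add_joint("pin", "pin", "ground", "seg",
                    coordinate_names=["q"])
        m.add_muscle("agonist", 0.3, {"q": np.array([0.05])})
        m.add_muscle("antagonist", 0.3, {"q": np.array([-0.05])})
        m.add_muscle("poly", 0.3, {"q": np.array([0.04, -0.01, 0.002])})
        m.validate()
        return m

    def test_constant_arm_moment(self, model):
        mom = muscle_joint_moments(model, np.array([[0.0]]),
                                   {"agonist": np.array([100.0])})
        assert mom["q"][0] == pytest.approx(5.0)

    def test_antagonist_pair_cancels(self, model):
        mom = muscle_joint_moments(model, np.array([[0.3]]),
                                   {"agonist": np.array([100.0]),
                                    "antagonist": np.array([100.0])})
        assert mom["q"][0] == pytest.approx(0.0)

    def test_moment_arm_is_negative_length_derivative(self, model):
        """-d l_mt / d q from finite differences equals the declared
        polynomial moment arm everywhere."""
        rng = np.random.default_rng(0)
        for name in model.muscles:
            for q in rng.uniform(-1, 1, 5):
                eps = 1e-6
                dl = (model.muscle_length(name, np.array([[q + eps]]))
                      - model.muscle_length(name,
                                            np.array([[q - eps]]))) / (2 * eps)
                r = model.muscle_moment_arm(name, "q", np.array([[q]]))
                assert -dl[0] == pytest.approx(r[0], abs=1e-6)

    def test_velocity_consistent_with_length_derivative(self, model):
        t = np.linspace(0, 1, 201)
        Q = 0.5 * np.sin(2 * np.pi * t)[None, :]
        V = 0.5 * 2 * np.pi * np.cos(2 * np.pi * t)[None, :]
        lmt = model.muscle_length("poly", Q)
        vmt = model.muscle_velocity("poly", Q, V)
        num = np.gradient(lmt, t)
        np.testing.assert_allclose(vmt[5:-5], num[5:-5], atol=2e-3)
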