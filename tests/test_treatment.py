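import numpy as np
import pytest

from nmskit.costs import continuous_term, standardized_cost
from nmskit.dynamics import inverse_dynamics_raw
from nmskit.treatment import (DesignOptimization, FormulationError,
                              OcpFormulation, SynergyController,
                              TrackingOptimization,
                              VerificationOptimization, builtin_terms,
                              kinetic_consistency_residual,
                              metabolic_power, periodicity_residuals,
                              solution_tables)


class TestStandardizedCost:
    def test_printed_amplification_value(self):
        assert standardized_cost(1.1, 0.0, 1.0) == pytest.approx(1.21)

    def test_printed_attenuation_value(self):
        assert standardized_cost(0.9, 0.0, 1.0) == pytest.approx(0.81)

    def test_zero_at_center(self):
        assert standardized_cost(3.7, 3.7, 0.5) == 0.0

    def test_nonpositive_allowable_rejected(self):
        with pytest.raises(ValueError):
            standardized_cost(1.0, 0.0, 0.0)


class TestContinuousTerm:
    def test_constant_deviation_at_allowable_is_one(self):
        for T in (0.5, 1.0, 2.0):
            t = np.linspace(0, T, 31)
            v = np.full_like(t, 2.0)
            assert continuous_term(t, v, 0.0, 2.0) == pytest.approx(1.0)

    def test_zero_deviation(self):
        t = np.linspace(0, 1, 11)
        assert continuous_term(t, np.full_like(t, 0.3), 0.3, 1.0) == 0.0

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            continuous_term(np.array([0.0]), np.array([1.0]), 0, 1.0,
                            duration=0.0)


class TestKineticConsistency:
    def test_torque_equal_to_id_gives_zero_residual(self, pendulum_form,
                                                    pendulum_ocp):
        fx = pendulum_ocp
        m = fx["model"]
        form = OcpFormulation(model=m, controllers={"theta": "torque"},
                              mesh_intervals=fx["n_intervals"],
                              final_time=fx["duration"])
        res = kinetic_consistency_residual(
            form, fx["q"][None], fx["v"][None], fx["accel"][None],
            {"theta": fx["tau"]}, {})
        assert np.abs(res["theta"]).max() < 1e-9

    def test_synergy_truth_residual_small(self, pendulum_form,
                                          pendulum_ocp):
        fx = pendulum_ocp
        acts = {m: fx["activations"][:, j]
                for j, m in enumerate(fx["muscles"])}
        res = kinetic_consistency_residual(
            pendulum_form, fx["q"][None], fx["v"][None],
            fx["accel"][None], {}, acts)
        assert np.sqrt(np.mean(res["theta"] ** 2)) < 1e-6

    def test_torque_shift_moves_residual_linearly(self, pendulum_ocp):
        fx = pendulum_ocp
        form = OcpFormulation(model=fx["model"],
                              controllers={"theta": "torque"},
                              mesh_intervals=fx["n_intervals"],
                              final_time=fx["duration"])
        r0 = kinetic_consistency_residual(
            form, fx["q"][None], fx["v"][None], fx["accel"][None],
            {"theta": fx["tau"]}, {})["theta"]
        r1 = kinetic_consistency_residual(
            form, fx["q"][None], fx["v"][None], fx["accel"][None],
            {"theta": fx["tau"] + 1.0}, {})["theta"]
        np.testing.assert_allclose(r1, r0 - 1.0, atol=1e-12)


class TestPeriodicity:
    def test_exactly_periodic_fixture(self):
        t = np.linspace(0, 1, 11)
        res = periodicity_residuals({"q": np.sin(2 * np.pi * t)})
        assert abs(res["q"]) < 1e-12

    def test_linear_ramp_residual(self):
        t = np.linspace(0, 2.0, 21)
        res = periodicity_residuals({"q": 3.0 * t})
        assert res["q"] == pytest.approx(6.0)

    def test_excluded_coordinate_absent(self):
        t = np.linspace(0, 1, 5)
        res = periodicity_residuals({"pelvis_tx": t, "hip": t ** 2},
                                    exclude=("pelvis_tx",))
        assert "pelvis_tx" not in res and "hip" in res


class TestTrackingOptimization:
    def test_noisy_grf_tracking_stays_dynamically_consistent(
            self, pendulum_form, pendulum_ocp, to_solution):
        """Tracked data perturbed by noise: the solution still satisfies
        the consistency constraints while the tracking cost is nonzero."""
        fx = pendulum_ocp
        rng = np.random.default_rng(3)
        import dataclasses
        form = dataclasses.replace(
            pendulum_form,
            tracked={**pendulum_form.tracked,
                     "loads": (fx["tau"] + rng.normal(0, 2.0,
                                                      fx["tau"].shape)
                               )[:, None],
                     "loads_names": ["theta"]})
        sol = TrackingOptimization(form, maxiter=250).solve(
            fx["states"], fx["controls"])
        assert sol.constraint_report["max_violation"] < 1e-6
        assert sol.term_values["loads"] > 0.01

    def test_nothing_to_track_is_formulation_error(self, pendulum_ocp):
        fx = pendulum_ocp
        form = OcpFormulation(model=fx["model"],
                              controllers={"theta": "torque"},
                              mesh_intervals=5, final_time=1.0)
        with pytest.raises(FormulationError):
            TrackingOptimization(form).solve(fx["states"][:6],
                                             fx["controls"][:6])

    def test_missing_controller_entry_is_error(self, pendulum_ocp):
        fx = pendulum_ocp
        form = OcpFormulation(model=fx["model"], controllers={},
                              mesh_intervals=5, final_time=1.0,
                              tracked={"coordinates": fx["q"][:6, None],
                                       "coordinates_names": ["theta"]})
        with pytest.raises(FormulationError):
            TrackingOptimization(form).solve(fx["states"][:6],
                                             fx["controls"][:6])


class TestVerification:
    def test_vo_fixed_point_reproduces_to(self, pendulum_form,
                                          to_solution, vo_solution):
        pos_rms = np.sqrt(np.mean((vo_solution.states[:, 0]
                                   - to_solution.states[:, 0]) ** 2))
        assert pos_rms < 1e-3
        lt = solution_tables(pendulum_form, to_solution)["loads"]["theta"]
        lv = solution_tables(pendulum_form, vo_solution)["loads"]["theta"]
        assert np.sqrt(np.mean((lv - lt) ** 2)) < 1e-2

    def test_vo_converges_in_fewer_iterations_than_to(self, to_solution,
                                                      vo_solution):
        assert vo_solution.n_iterations < to_solution.n_iterations

    def test_vo_constraints_satisfied(self, vo_solution):
        assert vo_solution.constraint_report["max_violation"] < 1e-6


class TestDesign:
    def test_identity_reduction_to_vo(self, pendulum_form, vo_solution):
        import dataclasses
        form = dataclasses.replace(pendulum_form,
                                   model_modification=lambda p: {})
        sol = DesignOptimization(form, maxiter=300).solve(
            vo_solution, allowables={"synergy_commands": 0.02,
                                     "coordinates": 0.05})
        assert np.abs(sol.states - vo_solution.states).max() < 1e-3

    def test_metabolic_target_reached(self, pendulum_form, pendulum_ocp,
                                      vo_solution):
        import dataclasses
        fx = pendulum_ocp
        b_form = pendulum_form
        do = DesignOptimization(b_form, maxiter=50)   # builder access only
        Q, V, _, _, acts = do.builder.trajectories(
            vo_solution.states, vo_solution.controls, None)
        P = metabolic_power(b_form, Q, V, acts)
        baseline = float(np.trapezoid(P, vo_solution.time)
                         / fx["duration"])
        target = 0.9 * baseline
        W = fx["W"]
        form = dataclasses.replace(
            b_form,
            static_parameters=[("syn_amp", 0.3, 2.0, 1.0)],
            model_modification=lambda p: {
                ("synergy_vectors", fx["group"]): p[0] * W})
        sol = DesignOptimization(form, maxiter=600).solve(
            vo_solution,
            goal_terms=[{"type": "metabolic_target", "center": target,
                         "allowable": 0.02 * baseline}],
            allowables={"synergy_commands": 0.3, "coordinates": 0.1})
        do2 = DesignOptimization(form, maxiter=1)
        Q, V, _, _, acts = do2.builder.trajectories(
            sol.states, sol.controls, sol.parameters)
        met = float(np.trapezoid(metabolic_power(form, Q, V, acts),
                                 sol.time) / sol.final_time)
        assert abs(met - target) <= 0.02 * baseline
        assert sol.constraint_report["max_violation"] < 1e-6

    def test_free_final_time_without_bounds_is_error(self, pendulum_form,
                                                     vo_solution):
        import dataclasses
        form = dataclasses.replace(pendulum_form, final_time=(1.0, 0.5))
        with pytest.raises(FormulationError):
            DesignOptimization(form).solve(vo_solution)

    def test_raising_hook_aborts_with_context(self, pendulum_form,
                                              vo_solution):
        import dataclasses

        def bad_hook(p):
            raise RuntimeError("boom")

        form = dataclasses.replace(pendulum_form,
                                   static_parameters=[("a", 0.0, 1.0,
                                                       0.5)],
                                   model_modification=bad_hook)
        with pytest.raises(RuntimeError, match="hook|boom"):
            DesignOptimization(form, maxiter=5).solve(vo_solution)


class TestBuiltinTerms:
    def test_metabolic_basal_only_at_rest(self, pendulum_form):
        n = 5
        Q = np.full((1, n), 0.3)
        V = np.zeros((1, n))
        acts = {m: np.zeros(n) for m in ("flexor", "extensor")}
        P = metabolic_power(pendulum_form, Q, V, acts)
        total_mass = sum(s.mass for s in
                         pendulum_form.model.segments.values())
        np.testing.assert_allclose(P, 1.2 * total_mass)

    def test_static_pose_zero_angular_momentum(self, pendulum_form):
        t = np.linspace(0, 1, 5)
        Q = np.full((1, 5), 0.4)
        V = np.zeros((1, 5))
        A = np.zeros((1, 5))
        out = builtin_terms(pendulum_form, t, Q, V, A, {},
                            {m: np.zeros(5) for m in
                             ("flexor", "extensor")})
        np.testing.assert_allclose(out["angular_momentum"], 0.0,
                                   atol=1e-12)

    def test_joint_energy_split(self, pendulum_form):
        t = np.linspace(0, 1, 101)
        Q = 0.3 * np.sin(2 * np.pi * t)[None]
        V = 0.3 * 2 * np.pi * np.cos(2 * np.pi * t)[None]
        tau = np.sin(2 * np.pi * t)
        out = builtin_terms(pendulum_form, t, Q, V, np.zeros_like(Q),
                            {"theta": tau},
                            {m: np.zeros(101) for m in
                             ("flexor", "extensor")})
        gen = out["joint_energy_generation"]["theta"]
        ab = out["joint_energy_absorption"]["theta"]
        # tau and omega are sin/cos: power integrates to zero with equal
        # generation and absorption
        assert gen == pytest.approx(ab, rel=1e-6)
        assert gen > 0
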