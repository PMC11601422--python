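import numpy as np
import pytest
from scipy.stats import pearsonr

from nmskit.fixtures import generate_stance_trial
from nmskit.gcp import (ContactModel, GroundContactPersonalizer,
                        bspline_node_count, contact_wrench, extract_foot,
                        shift_moment_point)
from nmskit.model import ModelError, segment_kinematics


class TestExtractFoot:
    def test_pose_consistency_over_gait_cycle(self, demo_contact):
        model, truth, trial = demo_contact
        Q = trial["coordinates"].as_matrix(model.coordinate_names).T
        foot, Qf = extract_foot(model, "hindfoot_r", "toes_r", Q)
        kin_full = segment_kinematics(model, Q)
        kin_foot = segment_kinematics(foot.model, Qf)
        for seg in ("hindfoot_r", "toes_r"):
            np.testing.assert_allclose(kin_foot[seg].phi,
                                       kin_full[seg].phi, atol=1e-9)
            np.testing.assert_allclose(kin_foot[seg].o, kin_full[seg].o,
                                       atol=1e-9)

    def test_missing_toes_is_error(self, demo_contact):
        model, _, _ = demo_contact
        with pytest.raises(ModelError):
            extract_foot(model, "hindfoot_r", "no_such_segment")


class TestContactWrench:
    def _foot(self, demo):
        model, truth, _ = demo
        foot, _ = extract_foot(model, "hindfoot_r", "toes_r")
        return foot, truth["contact"]["r"]

    def test_airborne_foot_zero_wrench(self, demo_contact):
        foot, cm = self._foot(demo_contact)
        Q = np.array([[0.0], [0.5], [0.0], [0.0]])   # high above ground
        force, mz, springs = contact_wrench(foot, cm, Q)
        assert np.abs(force).max() < 1e-9 and abs(mz[0]) < 1e-9

    def test_single_spring_static_linear_force(self):
        cm = ContactModel(rows=1, cols=1, stiffness=np.array([1e4]),
                          stations=[("hindfoot", np.array([0.0, 0.0]))],
                          damping=0.0, viscous_friction=0.0,
                          resting_length=0.0, smoothing=1e-3)
        from nmskit.model import Model
        m = Model()
        m.add_segment("hindfoot")
        m.add_joint("root", "planar_root_3dof", "ground", "hindfoot",
                    coordinate_names=["tx", "ty", "rz"])
        m.validate()
        # static penetration of 1 mm, beyond the smoothing band: force is
        # exactly linear, k * d = 10 N
        cm.smoothing = 1e-4
        Q = np.array([[0.0], [-0.001], [0.0]])
        force, _, _ = contact_wrench(m, cm, Q)
        assert force[1, 0] == pytest.approx(10.0, rel=1e-12)

    def test_no_friction_no_tangential_force(self, demo_contact):
        foot, cm = self._foot(demo_contact)
        cm = cm.copy()
        cm.viscous_friction = 0.0
        cm.dynamic_friction = 0.0
        Q = np.array([[0.0], [0.07], [0.0], [0.0]])
        V = np.array([[0.5], [0.0], [0.0], [0.0]])    # sliding fast
        force, _, _ = contact_wrench(foot, cm, Q, V)
        assert np.abs(force[0]).max() < 1e-12

    def test_moment_shift_consistency_on_random_states(self, demo_contact):
        """The wrench about any point equals the shifted wrench from any
        other point."""
        foot, cm = self._foot(demo_contact)
        rng = np.random.default_rng(0)
        Q = np.vstack([rng.normal(0, 0.01, 5),
                       0.06 + rng.normal(0, 0.005, 5),
                       rng.normal(0, 0.1, 5), rng.normal(0, 0.1, 5)])
        V = rng.normal(0, 0.2, Q.shape)
        p1 = rng.normal(0, 0.1, (2, 5))
        p2 = rng.normal(0, 0.1, (2, 5))
        f1, m1, _ = contact_wrench(foot, cm, Q, V, expression_point=p1)
        f2, m2, _ = contact_wrench(foot, cm, Q, V, expression_point=p2)
        shift = np.cross(np.column_stack([(p1 - p2).T,
                                          np.zeros(5)]),
                         np.column_stack([f1.T, np.zeros(5)]))[:, 2]
        np.testing.assert_allclose(m2, m1 + shift, atol=1e-9)


class TestShiftMomentPoint:
    def test_cross_product_arithmetic(self):
        m_new = shift_moment_point([0, 10, 0], [0, 0, 0],
                                   [-0.1, 0, 0], [0, 0, 0])
        np.testing.assert_allclose(m_new, [0, 0, -1.0])

    def test_same_point_no_change(self):
        m = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(
            shift_moment_point([1, 2, 3], m, [4, 5, 6], [4, 5, 6]), m)

    def test_involution(self):
        rng = np.random.default_rng(0)
        F, M, a, b = rng.normal(size=(4, 3))
        M2 = shift_moment_point(F, M, a, b)
        np.testing.assert_allclose(shift_moment_point(F, M2, b, a), M,
                                   atol=1e-14)


class TestBsplineNodes:
    @pytest.mark.parametrize("duration,cutoff,expected", [
        (1.0, 7.0, 11), (0.1, 7.0, 5)])
    def test_counts(self, duration, cutoff, expected):
        assert bspline_node_count(duration, cutoff) == expected

    def test_zero_cutoff_rejected(self):
        with pytest.raises(ValueError):
            bspline_node_count(1.0, 0.0)


class TestCalibration:
    @pytest.fixture(scope="class")
    def stance(self, demo_contact):
        model, truth, _ = demo_contact
        return generate_stance_trial(model, truth, "r")

    def test_cost_terms_zero_at_truth(self, stance):
        gcp = GroundContactPersonalizer(stance["foot"], stance["contact"])
        task = gcp.tasks[2]
        res = gcp._residuals(task, stance["time"], stance["coordinates"],
                             stance["force"], stance["moment"],
                             stance["point"], stance["contact"],
                             {c: np.zeros(5) for c in []})
        # tracking residuals vanish at truth; only the stiffness neighbor
        # regularizer is nonzero
        n_track = 3 * len(stance["time"])
        assert np.abs(res[:n_track]).max() < 1e-9

    def test_uniform_map_has_zero_neighbor_term(self):
        cm = ContactModel(rows=2, cols=3,
                          stiffness=np.full(6, 5e3),
                          stations=[("hindfoot", np.zeros(2))] * 6)
        k = cm.stiffness
        diffs = [k[i] - k[j] for i, j in cm.neighbor_pairs()]
        assert np.abs(diffs).max() == 0.0

    def test_stiffness_map_recovery(self, stance):
        """Staged calibration from a uniform-stiffness guess recovers the
        non-uniform truth map (r >= 0.9) with sub-newton GRF errors."""
        truth_c = stance["contact"]
        init = truth_c.copy()
        init.stiffness = np.full_like(truth_c.stiffness, 8e3)
        init.resting_length = 0.010
        init.viscous_friction = 0.3
        gcp = GroundContactPersonalizer(stance["foot"], init,
                                        allowable={"neighbor": 1e5})
        gcp.fit(stance["time"], stance["coordinates"], stance["force"],
                stance["moment"],
                np.vstack([stance["point"][0],
                           np.zeros(len(stance["time"]))]),
                midfoot_x=stance["point"][0])
        r = pearsonr(gcp.contact_.stiffness, truth_c.stiffness)[0]
        assert r >= 0.9
        final = gcp.diagnostics_[-1]
        assert final["vertical_rmse_N"] < 1.0
        assert final["horizontal_rmse_N"] < 1.0
        assert final["moment_rmse_Nm"] < 1.0

    def test_staging_contract(self, stance):
        """Stage 1 reduces the vertical-force error from the initial
        model; its cost ignores horizontal force and moments."""
        from nmskit.gcp import GcpTask
        truth_c = stance["contact"]
        init = truth_c.copy()
        init.stiffness = np.full_like(truth_c.stiffness, 9e3)
        gcp = GroundContactPersonalizer(
            stance["foot"], init, tasks=[GcpTask(track_vertical=True,
                                                 max_nfev=20)],
            allowable={"neighbor": 1e5})
        from nmskit.gcp import contact_wrench
        f0, _, _ = contact_wrench(stance["foot"], init,
                                  stance["coordinates"],
                                  stance["velocities"],
                                  expression_point=stance["point"])
        rmse0 = np.sqrt(np.mean((f0[1] - stance["force"][1]) ** 2))
        gcp.fit(stance["time"], stance["coordinates"], stance["force"],
                stance["moment"],
                np.vstack([stance["point"][0],
                           np.zeros(len(stance["time"]))]),
                midfoot_x=stance["point"][0])
        assert gcp.diagnostics_[0]["vertical_rmse_N"] < rmse0

    def test_mismatched_time_grids_rejected(self, stance):
        gcp = GroundContactPersonalizer(stance["foot"], stance["contact"])
        with pytest.raises(Exception, match="time"):
            gcp.fit(stance["time"][:-1], stance["coordinates"],
                    stance["force"], stance["moment"],
                    np.vstack([stance["point"][0],
                               np.zeros(len(stance["time"]))]))
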