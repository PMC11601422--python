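import numpy as np
import pytest

from nmskit.jmp import (JmpTask, JointModelPersonalizer, RomWarning,
                        check_rom, jmp_cost)
from nmskit.model import Model, marker_positions
from nmskit.tables import MarkerData, TimeSeriesTable


def _chain_model():
    m = Model()
    m.add_segment("thigh", com=(0, -0.2, 0))
    m.add_segment("shank", com=(0, -0.2, 0))
    m.add_joint("hip", "planar_root_3dof", "ground", "thigh",
                coordinate_names=["tx", "ty", "rz"])
    m.add_joint("knee", "pin", "thigh", "shank",
                location_in_parent=(0, -0.4, 0), coordinate_names=["knee"])
    for seg, spots in {"thigh": [(0.02, -0.1), (-0.02, -0.25),
                                 (0.03, -0.35)],
                       "shank": [(0.02, -0.08), (-0.02, -0.22),
                                 (0.02, -0.38)]}.items():
        for k, (x, y) in enumerate(spots):
            m.add_marker(f"{seg}_m{k}", seg, (x, y, 0))
    m.validate()
    return m


def _markers_for(model, Q, t):
    return MarkerData(t, marker_positions(model, Q))


@pytest.fixture
def chain_trial():
    model = _chain_model()
    t = np.linspace(0, 1, 15)
    Q = np.vstack([0.01 * np.sin(2 * np.pi * t),
                   0.9 + 0.02 * np.cos(2 * np.pi * t),
                   0.1 * np.sin(2 * np.pi * t),
                   0.6 + 0.5 * np.sin(2 * np.pi * t)])
    return model, Q, t


class TestJmpCost:
    def test_perfect_markers_give_zero_cost(self, chain_trial):
        model, Q, t = chain_trial
        md = _markers_for(model, Q, t)
        assert jmp_cost(model, md) < 1e-14

    def test_normalization_arithmetic(self):
        """A ground-fixed marker offset by 10 mm that IK cannot compensate
        contributes exactly 1e-4 m^2 regardless of duration and frame
        count."""
        for F, T in ((5, 1.0), (11, 2.5)):
            m = Model()
            m.add_segment("seg", com=(0, 0, 0))
            m.add_joint("j", "pin", "ground", "seg",
                        coordinate_names=["q"])
            m.add_marker("center", "seg", (0, 0, 0))  # at the pin: immobile
            m.validate()
            t = np.linspace(0, T, F)
            md = MarkerData(t, {"center": np.tile([0.01, 0.0, 0.0],
                                                  (F, 1))})
            assert jmp_cost(m, md) == pytest.approx(1e-4, rel=1e-6)

    def test_duplicate_markers_leave_cost_unchanged(self, chain_trial):
        model, Q, t = chain_trial
        pos = marker_positions(model, Q)
        offset = {k: v + np.array([0.005, 0, 0]) for k, v in pos.items()}
        md1 = MarkerData(t, offset)
        model2 = model.copy()
        for name in list(model.markers):
            mk = model.markers[name]
            model2.add_marker(name + "_dup", mk.segment, mk.location)
        dup = dict(offset)
        dup.update({k + "_dup": v for k, v in offset.items()})
        md2 = MarkerData(t, dup)
        assert jmp_cost(model2, md2) == pytest.approx(
            jmp_cost(model, md1), rel=1e-6)


class TestCheckRom:
    def _coords(self, sweep_deg):
        t = np.linspace(0, 1, 20)
        return TimeSeriesTable(t, {"knee": np.deg2rad(sweep_deg)
                                   * (t - 0.5)})

    def test_wide_rom_no_warning(self, recwarn):
        assert check_rom(self._coords(40), ["knee"]) == []

    def test_narrow_rom_warns_naming_coordinate(self):
        with pytest.warns(RomWarning, match="knee"):
            msgs = check_rom(self._coords(10), ["knee"])
        assert len(msgs) == 1

    def test_threshold_is_strict_less(self, recwarn):
        assert check_rom(self._coords(25.0), ["knee"]) == []


class TestPersonalization:
    def test_recovers_joint_frame_offset(self, chain_trial):
        """A 15 mm knee-frame translation is recovered within 5% from
        noise-free markers."""
        model, Q, t = chain_trial
        md = _markers_for(model, Q, t)
        perturbed = model.copy()
        true_offset = np.array([0.010, -0.011])
        for j in perturbed.joints:
            if j.name == "knee":
                j.location_in_parent = j.location_in_parent \
                    + np.array([*true_offset, 0.0])
        task = JmpTask(md, joint_parameters=[("knee", "parent",
                                              "location")])
        fit = JointModelPersonalizer([task]).fit(perturbed)
        knee = next(j for j in fit.model_.joints if j.name == "knee")
        err = np.abs(knee.location_in_parent[:2] - np.array([0, -0.4]))
        assert np.all(err <= 0.05 * np.linalg.norm(true_offset))
        assert fit.diagnostics_[0]["post_rms_m"] < 1e-6

    def test_already_optimal_model_unchanged(self, chain_trial):
        model, Q, t = chain_trial
        md = _markers_for(model, Q, t)
        task = JmpTask(md, joint_parameters=[("knee", "parent",
                                              "location")])
        fit = JointModelPersonalizer([task]).fit(model)
        knee = next(j for j in fit.model_.joints if j.name == "knee")
        np.testing.assert_allclose(knee.location_in_parent[:2], [0, -0.4],
                                   atol=1e-6)
        assert fit.diagnostics_[0]["post_cost"] <= \
            fit.diagnostics_[0]["pre_cost"] + 1e-15

    def test_task_chain_costs_monotone(self, chain_trial):
        model, Q, t = chain_trial
        md = _markers_for(model, Q, t)
        perturbed = model.copy()
        perturbed.scale_segment("shank", 1.04)
        for j in perturbed.joints:
            if j.name == "knee":
                j.location_in_parent = j.location_in_parent \
                    + np.array([0.008, 0.0, 0.0])
        tasks = [JmpTask(md, scale_segments=["shank"]),
                 JmpTask(md, joint_parameters=[("knee", "parent",
                                                "location")])]
        fit = JointModelPersonalizer(tasks).fit(perturbed)
        d0, d1 = fit.diagnostics_
        assert d0["post_cost"] <= d0["pre_cost"] + 1e-15
        assert d1["post_cost"] <= d0["post_cost"] + 1e-12

    def test_uniform_scaling_consistency(self, chain_trial):
        """FK of a uniformly scaled model with identically scaled marker
        data gives zero marker error (scale design variables act on
        geometry, markers and joint frames together)."""
        model, Q, t = chain_trial
        factor = 1.07
        scaled = model.copy()
        for seg in ("thigh", "shank"):
            scaled.scale_segment(seg, factor)
        # scaling thigh scales the knee frame; root translations live in
        # ground units, so rescale the translation trajectory accordingly
        Qs = Q.copy()
        Qs[0] *= factor
        Qs[1] *= factor
        md = MarkerData(t, marker_positions(scaled, Qs))
        assert jmp_cost(scaled, md) < 1e-14

    def test_empty_task_rejected(self, chain_trial):
        model, Q, t = chain_trial
        task = JmpTask(_markers_for(model, Q, t))
        with pytest.raises(ValueError, match="design variable"):
            JointModelPersonalizer([task]).fit(model)
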