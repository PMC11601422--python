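import numpy as np
import pytest

from nmskit.fixtures import truth_synergy_activations
from nmskit.mtp import (MtpConfigError, MtpSettings, MtpTrial,
                        MuscleTendonPersonalizer, fmax_from_regression,
                        merge_results, mtl_initialization, synx_estimate)
from nmskit.muscle import MuscleTendonParams
from nmskit.ncp import vaf
from nmskit.tables import TimeSeriesTable


def _trial_from(demo):
    model, truth, trial = demo
    return MtpTrial(coordinates=trial["coordinates"],
                    loads=trial["loads"], emg=trial["emg_all"],
                    cycle_duration=1.0)


def _recovery_settings(muscles, **kw):
    base = dict(
        muscles=muscles,
        tracked_coordinates=["hip_r", "knee_r", "ankle_r"],
        free=("lengths",),
        deviation_allowable={"delay": 0.05, "tau": 0.02,
                             "nonlinearity": 2.0, "scale": 0.5,
                             "length_fraction": 10.0},
        moment_allowable=2.0, passive_allowable=1e3,
        similarity_groups=[])
    base.update(kw)
    return MtpSettings(**base)


class TestInitialization:
    def test_fmax_formula(self):
        # sigma V / l_opt with sigma = 60 kPa, V = 3e-4 m^3, l_opt = 0.1 m
        v_frac_total = 0.0003 / ((47 * 75 * 1.75 + 1285) * 1e-6)
        f = fmax_from_regression(1.75, 75.0, v_frac_total, 0.10)
        assert f == pytest.approx(180.0, rel=1e-9)

    def test_constant_length_placed_at_region_midpoint(self):
        from nmskit.model import Model
        m = Model()
        m.add_segment("seg")
        m.add_joint("j", "pin", "ground", "seg", coordinate_names=["q"])
        m.add_muscle("mus", 0.30, {})          # no moment arms: constant
        m.validate()
        t = np.linspace(0, 1, 11)
        trial = MtpTrial(TimeSeriesTable(t, {"q": np.sin(t)}),
                         TimeSeriesTable(t, {"q": np.zeros_like(t)}),
                         TimeSeriesTable(t, {"mus": np.zeros_like(t)}),
                         1.0)
        init = mtl_initialization(m, [trial], ["mus"])
        p = init["mus"]
        lnorm = (0.30 - p.tendon_slack_length) / p.optimal_fiber_length
        assert lnorm == pytest.approx(0.75)

    def test_recovers_truth_when_range_maps_to_ascending_region(self):
        """If the truth parameters map the observed length range onto
        normalized [0.6, 0.9], initialization reproduces them."""
        from nmskit.model import Model
        l_opt, l_ts = 0.1, 0.2
        m = Model()
        m.add_segment("seg")
        m.add_joint("j", "pin", "ground", "seg", coordinate_names=["q"])
        m.add_muscle("mus", l_ts + 0.75 * l_opt, {"q": np.array([0.05])})
        m.validate()
        # q range chosen so l_mt spans [l_ts + 0.6 l_opt, l_ts + 0.9 l_opt]
        q_lo = (0.75 - 0.9) * l_opt / 0.05
        q_hi = (0.75 - 0.6) * l_opt / 0.05
        t = np.linspace(0, 1, 21)
        q = np.linspace(q_lo, q_hi, 21)
        trial = MtpTrial(TimeSeriesTable(t, {"q": q}),
                         TimeSeriesTable(t, {"q": np.zeros_like(t)}),
                         TimeSeriesTable(t, {"mus": np.zeros_like(t)}),
                         1.0)
        init = mtl_initialization(m, [trial], ["mus"])
        assert abs(init["mus"].tendon_slack_length - l_ts) < 0.002
        assert abs(init["mus"].optimal_fiber_length - l_opt) < 0.002


class TestSynX:
    def _rank3_envelopes(self, n_mus=6, F=101):
        t = np.linspace(0, 1, F)
        H = truth_synergy_activations(t, 3, 1.0)
        rng = np.random.default_rng(5)
        W = rng.uniform(0.05, 1.0, (3, n_mus))
        return H @ W, H, W

    def test_nmf_and_pca_reach_95_percent_vaf_on_rank3(self):
        E, _, _ = self._rank3_envelopes()
        for method in ("nmf", "pca"):
            out = synx_estimate(E, method=method, n_components=3)
            assert out["vaf"] >= 95.0

    def test_component_count_rule(self):
        E, _, _ = self._rank3_envelopes()
        out = synx_estimate(E, method="nmf")
        assert out["k"] <= 4 and out["vaf"] >= 95.0

    def test_too_many_components_rejected(self):
        E, _, _ = self._rank3_envelopes(n_mus=4)
        with pytest.raises(ValueError):
            synx_estimate(E, n_components=5)

    def test_hidden_channel_reconstructed_via_weight_optimization(
            self, demo_nocontact):
        """Hide one muscle's EMG; the SynX weights found by the MTP
        optimization reconstruct the hidden excitation."""
        model, truth, trial = demo_nocontact
        muscles = model.muscle_groups["leg_r"]
        hidden = "gastroc_r"
        emg = trial["emg_all"]
        shown = TimeSeriesTable(emg.time,
                                {m: emg[m] for m in muscles
                                 if m != hidden}, dict(emg.metadata))
        mt = MtpTrial(trial["coordinates"], trial["loads"], shown, 1.0)
        settings = _recovery_settings(muscles, free=(),
                                      synx_muscles=[hidden],
                                      synx_components=3)
        init = {m: truth["muscles"][m] for m in muscles}
        fit = MuscleTendonPersonalizer(settings).fit(model, [mt],
                                                     initial=init)
        n_pad = mt.pad_points
        H = fit.synx_[0]["components"][n_pad:]
        est = np.clip(H @ fit.synx_weights_[0], 0, 1)
        # truth excitation of the hidden muscle on the cycle grid
        p = truth["muscles"][hidden]
        env = emg[hidden][n_pad:]
        rmse = np.sqrt(np.mean((est / max(est.max(), 1e-9) * env.max()
                                - env) ** 2))
        assert rmse < 0.05


class TestRunMtp:
    def test_length_parameter_recovery_within_2_percent(
            self, demo_nocontact):
        model, truth, trial = demo_nocontact
        muscles = model.muscle_groups["leg_r"]
        mt = _trial_from(demo_nocontact)
        rng = np.random.default_rng(2)
        init = {}
        for m in muscles:
            p = truth["muscles"][m]
            init[m] = p.replace(
                optimal_fiber_length=p.optimal_fiber_length
                * (1 + rng.uniform(-0.1, 0.1)),
                tendon_slack_length=p.tendon_slack_length
                * (1 + rng.uniform(-0.1, 0.1)))
        fit = MuscleTendonPersonalizer(
            _recovery_settings(muscles, n_restarts=4)).fit(model, [mt],
                                                           initial=init)
        for m in muscles:
            p, q = fit.params_[m], truth["muscles"][m]
            assert abs(p.optimal_fiber_length / q.optimal_fiber_length
                       - 1) < 0.02
            assert abs(p.tendon_slack_length / q.tendon_slack_length
                       - 1) < 0.02

    def test_fmax_held_constant(self, demo_nocontact):
        model, truth, trial = demo_nocontact
        muscles = model.muscle_groups["leg_r"]
        mt = _trial_from(demo_nocontact)
        init = {m: truth["muscles"][m] for m in muscles}
        fit = MuscleTendonPersonalizer(
            _recovery_settings(muscles, max_nfev=5)).fit(model, [mt],
                                                         initial=init)
        for m in muscles:
            assert fit.params_[m].max_isometric_force == \
                init[m].max_isometric_force

    def test_start_at_truth_stays_at_truth(self, demo_nocontact):
        model, truth, trial = demo_nocontact
        muscles = model.muscle_groups["leg_r"]
        mt = _trial_from(demo_nocontact)
        init = {m: truth["muscles"][m] for m in muscles}
        fit = MuscleTendonPersonalizer(
            _recovery_settings(muscles)).fit(model, [mt], initial=init)
        for m in muscles:
            assert abs(fit.params_[m].optimal_fiber_length
                       / init[m].optimal_fiber_length - 1) < 5e-3
        assert max(max(v) for v in
                   fit.diagnostics_["moment_rmse"].values()) < 0.05

    def test_missing_moment_column_is_config_error(self, demo_nocontact):
        model, truth, trial = demo_nocontact
        muscles = model.muscle_groups["leg_r"]
        loads = trial["loads"]
        broken = TimeSeriesTable(loads.time,
                                 {k: v for k, v in loads.columns.items()
                                  if k != "knee_r"})
        mt = MtpTrial(trial["coordinates"], broken, trial["emg_all"], 1.0)
        with pytest.raises(MtpConfigError, match="knee_r"):
            MuscleTendonPersonalizer(
                _recovery_settings(muscles)).fit(model, [mt])

    def test_cost_scale_invariance_of_argmin(self, demo_nocontact):
        """Scaling every maximum allowable error by a common factor
        rescales the cost but leaves the optimum unchanged."""
        model, truth, trial = demo_nocontact
        muscles = model.muscle_groups["leg_r"]
        mt = _trial_from(demo_nocontact)
        rng = np.random.default_rng(4)
        init = {m: truth["muscles"][m].replace(
            tendon_slack_length=truth["muscles"][m].tendon_slack_length
            * (1 + rng.uniform(-0.05, 0.05))) for m in muscles}
        fits = []
        for fac in (1.0, 3.0):
            s = _recovery_settings(
                muscles, moment_allowable=2.0 * fac,
                passive_allowable=1e3 * fac,
                deviation_allowable={k: v * fac for k, v in
                                     {"delay": 0.05, "tau": 0.02,
                                      "nonlinearity": 2.0, "scale": 0.5,
                                      "length_fraction": 10.0}.items()})
            fits.append(MuscleTendonPersonalizer(s).fit(
                model, [mt], initial=init))
        for m in muscles:
            assert fits[0].params_[m].tendon_slack_length == pytest.approx(
                fits[1].params_[m].tendon_slack_length, rel=1e-4)


class TestMerge:
    def test_merge_disjoint_sets(self):
        a = {"m1": MuscleTendonParams()}
        b = {"m2": MuscleTendonParams()}
        assert set(merge_results(a, b)) == {"m1", "m2"}

    def test_merge_rejects_duplicates(self):
        a = {"m1": MuscleTendonParams()}
        with pytest.raises(ValueError, match="m1"):
            merge_results(a, a)
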