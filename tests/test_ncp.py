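import numpy as np
import pytest
from hypothesis import given, settings, strategies as stst

from nmskit.ncp import (NcpSettings, NeuralControlPersonalizer, SynergySet,
                        normalize_synergy_set, reconstruct_activations,
                        synergy_sum_residual, vaf)


class TestReconstruction:
    def test_single_allones_synergy_broadcasts_activation(self):
        H = np.linspace(0, 1, 5)[:, None]
        W = np.ones((1, 4))
        A = reconstruct_activations(H, W)
        for j in range(4):
            np.testing.assert_array_equal(A[:, j], H[:, 0])

    def test_zero_activations(self):
        assert np.all(reconstruct_activations(np.zeros((5, 2)),
                                              np.ones((2, 3))) == 0)

    def test_hand_multiplied_2x2(self):
        H = np.array([[1.0, 2.0], [3.0, 4.0]])
        W = np.array([[0.5, 1.0], [2.0, 0.0]])
        np.testing.assert_array_equal(reconstruct_activations(H, W),
                                      [[4.5, 1.0], [9.5, 3.0]])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_activations(np.zeros((5, 2)), np.zeros((3, 4)))


class TestVaf:
    def test_perfect_reconstruction_is_100(self):
        x = np.random.default_rng(0).random((7, 3))
        assert vaf(x, x) == pytest.approx(100.0)

    def test_zero_reconstruction_is_0(self):
        x = np.random.default_rng(0).random((7, 3))
        assert vaf(x, np.zeros_like(x)) == pytest.approx(0.0)

    def test_rank3_nmf_reaches_99p9(self):
        rng = np.random.default_rng(1)
        H = rng.random((50, 3))
        W = rng.random((3, 6))
        X = H @ W
        from sklearn.decomposition import NMF
        nmf = NMF(3, init="nndsvda", max_iter=5000, tol=1e-12)
        R = nmf.fit_transform(X) @ nmf.components_
        assert vaf(X, R) >= 99.9

    def test_all_zero_original_rejected(self):
        with pytest.raises(ValueError):
            vaf(np.zeros((3, 2)), np.zeros((3, 2)))


class TestSumResidual:
    @pytest.mark.parametrize("row,C,expected", [
        ([1, 1, 1, 1], 1.0, 0.0),
        ([2, 0, 1, 1], 1.0, 0.0),
        ([0, 0, 0, 0], 1.0, -4.0),
    ])
    def test_examples(self, row, C, expected):
        assert synergy_sum_residual(np.array([row]), C)[0] == \
            pytest.approx(expected)


class TestNormalization:
    def test_peak_scaling_preserves_product(self):
        H = np.array([[1.0], [2.0]])
        W = np.array([[4.0, 2.0, 1.0]])
        s = normalize_synergy_set(SynergySet("g", ["a", "b", "c"], W, H))
        assert s.W.max(axis=1) == pytest.approx(1.0)
        np.testing.assert_allclose(s.H @ s.W, H @ W, atol=1e-12)
        np.testing.assert_allclose(s.H[:, 0], [4.0, 8.0])

    def test_already_normalized_unchanged(self):
        W = np.array([[1.0, 0.5], [0.25, 1.0]])
        H = np.ones((3, 2))
        s = normalize_synergy_set(SynergySet("g", ["a", "b"], W, H))
        np.testing.assert_array_equal(s.W, W)
        np.testing.assert_array_equal(s.H, H)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=stst.integers(0, 10 ** 6))
    def test_product_invariance_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        H = rng.random((12, 3))
        W = rng.random((3, 5)) + 0.01
        s = normalize_synergy_set(SynergySet("g", list("abcde"), W, H))
        assert np.linalg.norm(s.H @ s.W - H @ W) < 1e-10

    def test_all_zero_vector_is_error_naming_synergy(self):
        W = np.array([[1.0, 0.5], [0.0, 0.0]])
        with pytest.raises(ValueError, match="synergy 1"):
            normalize_synergy_set(SynergySet("g", ["a", "b"], W,
                                             np.ones((3, 2))))


class TestRunNcp:
    def _settings(self, **kw):
        base = dict(groups={"leg_r": 3},
                    tracked_coordinates=["hip_r", "knee_r", "ankle_r"],
                    moment_allowable=2.0, activation_allowable=0.05)
        base.update(kw)
        return NcpSettings(**base)

    def test_recovery_vaf_and_moment_rmse(self, demo_nocontact):
        model, truth, trial = demo_nocontact
        fit = NeuralControlPersonalizer(self._settings()).fit(
            model, trial["time"], trial["coordinates"], trial["loads"],
            truth["muscles"], trial["activations"])
        assert fit.diagnostics_["vaf"]["leg_r"] >= 99.0
        assert max(fit.diagnostics_["moment_rmse"].values()) < 0.1
        assert fit.diagnostics_["constraint_violation"] < 1e-6

    def test_output_normalized_and_nonnegative(self, demo_nocontact):
        model, truth, trial = demo_nocontact
        fit = NeuralControlPersonalizer(self._settings()).fit(
            model, trial["time"], trial["coordinates"], trial["loads"],
            truth["muscles"], trial["activations"])
        s = fit.synergies_["leg_r"]
        np.testing.assert_allclose(s.W.max(axis=1), 1.0, atol=1e-9)
        assert np.all(s.W >= 0) and np.all(s.H >= 0)

    def test_shared_vectors_identical_across_groups(self, demo_contact):
        model, truth, trial = demo_contact
        settings = NcpSettings(
            groups={"leg_r": 2, "leg_l": 2},
            tracked_coordinates=["hip_r", "knee_r", "ankle_r",
                                 "hip_l", "knee_l", "ankle_l"],
            shared_vectors=[("leg_r", "leg_l")], max_iter=150)
        fit = NeuralControlPersonalizer(settings).fit(
            model, trial["time"], trial["coordinates"], trial["loads"],
            truth["muscles"], trial["activations"])
        np.testing.assert_array_equal(fit.raw_synergies_["leg_r"].W,
                                      fit.raw_synergies_["leg_l"].W)

    def test_no_mtp_mode_bounded_and_moments_matched(self, demo_nocontact):
        """Without MTP activations the activation-minimization term makes
        the solution unique; its allowable is set to the expected
        activation magnitude of the fixture (~0.2) so moments stay matched
        within their own allowable."""
        model, truth, trial = demo_nocontact
        settings = self._settings(activation_min_allowable=0.2,
                                  max_iter=300)
        fit = NeuralControlPersonalizer(settings).fit(
            model, trial["time"], trial["coordinates"], trial["loads"],
            truth["muscles"], None)
        A = fit.activations_.as_matrix()
        assert A.max() < 1.5
        assert max(fit.diagnostics_["moment_rmse"].values()) < 2.0

    def test_too_many_synergies_rejected(self, demo_nocontact):
        model, truth, trial = demo_nocontact
        settings = self._settings(groups={"leg_r": 7})
        with pytest.raises(ValueError, match="synergies"):
            NeuralControlPersonalizer(settings).fit(
                model, trial["time"], trial["coordinates"],
                trial["loads"], truth["muscles"], trial["activations"])

    def test_vaf_monotone_in_synergy_count(self, demo_nocontact):
        model, truth, trial = demo_nocontact
        vafs = []
        for k in (1, 2, 3):
            fit = NeuralControlPersonalizer(
                self._settings(groups={"leg_r": k}, max_iter=150)).fit(
                model, trial["time"], trial["coordinates"],
                trial["loads"], truth["muscles"], trial["activations"])
            vafs.append(fit.diagnostics_["vaf"]["leg_r"])
        assert vafs[0] <= vafs[1] + 0.1 and vafs[1] <= vafs[2] + 0.1
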