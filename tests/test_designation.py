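"""Subpeak designation: target vectors, designation rules, ratio, training."""

import numpy as np
import pytest

from icpulse.curvature import CandidateSet, candidates
from icpulse.designation import (DegenerateDesignationError, PulseLabel,
                                 SubpeakDesignator, build_designator,
                                 designate, designate_curvature_baseline,
                                 p2p1_ratio, target_vector)
from icpulse.simulate import generate_pulse_dataset


class TestTargetVector:
    def test_coincident_subpeaks_reach_one(self):
        y = target_vector(90, 90)
        assert y[90] == pytest.approx(1.0)
        assert y.max() == pytest.approx(1.0)

    def test_separated_subpeaks_half_height(self):
        y = target_vector(60, 90)
        # at p1 the own Gaussian contributes 1 and the other exp(-450)
        assert y[60] == pytest.approx(0.5 * (1 + np.exp(-450)), abs=1e-12)
        assert y[90] == pytest.approx(0.5, abs=1e-12)

    def test_negligible_between_distant_subpeaks(self):
        y = target_vector(60, 90)
        assert y[75] < 1e-40

    def test_symmetry_and_translation_covariance(self):
        a = target_vector(50, 120)
        b = target_vector(120, 50)
        assert np.allclose(a, b)
        shifted = target_vector(60, 130)
        assert np.allclose(a[40:170], shifted[50:180], atol=1e-12)

    def test_max_below_one_when_separated(self):
        assert target_vector(40, 140).max() < 1.0

    def test_wider_sigma_spreads_mass(self):
        narrow = target_vector(90, 120, sigma=1.0)
        wide = target_vector(90, 120, sigma=3.0)
        assert wide.sum() > narrow.sum()


class TestPulseLabel:
    def test_valid_and_sentinel(self):
        PulseLabel(40, 90, True)
        PulseLabel(0, 0, False)

    @pytest.mark.parametrize("p1,p2,calc", [
        (90, 40, True), (0, 90, True), (40, 40, True), (5, 9, False)])
    def test_invalid_rejected(self, p1, p2, calc):
        with pytest.raises(ValueError):
            PulseLabel(p1, p2, calc)


class TestDesignate:
    def _pulse(self):
        i = np.arange(180.0)
        return (np.exp(-((i - 40) ** 2) / 200)
                + 0.8 * np.exp(-((i - 95) ** 2) / 260))

    def test_top_two_candidates_in_temporal_order(self):
        cands = CandidateSet(indices=np.array([30, 60, 120]),
                             curvature_values=np.ones(3))
        scores = np.zeros(180)
        scores[[30, 60, 120]] = [0.1, 0.9, 0.8]
        res = designate(self._pulse(), scores, "curvature", cands)
        assert (res.i1, res.i2) == (60, 120)

    def test_nn_mode_uses_local_maxima(self):
        scores = (np.exp(-(np.arange(180.0) - 45) ** 2 / 8)
                  + 0.9 * np.exp(-(np.arange(180.0) - 95) ** 2 / 8))
        res = designate(self._pulse(), scores, "nn_output")
        assert (res.i1, res.i2) == (45, 95)

    def test_single_candidate_is_noncalculable(self):
        cands = CandidateSet(indices=np.array([40]),
                             curvature_values=np.ones(1))
        assert designate(self._pulse(), np.ones(180), "curvature", cands) is None

    def test_score_tie_keeps_earlier_index(self):
        cands = CandidateSet(indices=np.array([30, 60, 120]),
                             curvature_values=np.ones(3))
        scores = np.zeros(180)
        scores[[30, 60, 120]] = [0.8, 0.8, 0.5]
        res = designate(self._pulse(), scores, "curvature", cands)
        assert (res.i1, res.i2) == (30, 60)

    def test_curvature_mode_returns_member_candidates(self):
        pulse = self._pulse()
        cands = candidates(pulse)
        scores = np.random.default_rng(0).random(180)
        res = designate(pulse, scores, "curvature", cands)
        assert res.i1 in cands.indices and res.i2 in cands.indices

    def test_baseline_takes_two_earliest(self):
        pulse = self._pulse()
        cands = candidates(pulse)
        res = designate_curvature_baseline(pulse, cands)
        assert (res.i1, res.i2) == tuple(cands.indices[:2])


class TestP2P1Ratio:
    def test_direct_quotients(self):
        v = np.zeros(180)
        v[40], v[90] = 1.0, 0.8
        assert p2p1_ratio(v, 40, 90) == pytest.approx(0.8)
        v[40], v[90] = 0.5, 0.75
        assert p2p1_ratio(v, 40, 90) == pytest.approx(1.5)

    def test_zero_p1_amplitude_rejected(self):
        v = np.zeros(180)
        v[90] = 0.5
        with pytest.raises(DegenerateDesignationError):
            p2p1_ratio(v, 40, 90)

    def test_index_order_enforced(self):
        with pytest.raises(ValueError):
            p2p1_ratio(np.ones(180), 90, 40)

    def test_gt1_iff_later_amplitude_larger(self):
        v = np.linspace(0.01, 1.0, 180)
        assert p2p1_ratio(v, 10, 170) > 1
        assert p2p1_ratio(v[::-1], 10, 170) < 1


class TestBuildDesignator:
    @pytest.mark.parametrize("kind", ["unet", "lstm"])
    def test_output_shape(self, kind):
        net = build_designator(kind, seed=0, channels=(4, 8, 8), lstm_hidden=16)
        x = np.random.default_rng(1).random((3, 180)).astype(np.float32)
        assert net.forward(x, train=False).shape == (3, 180)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            build_designator("mlp")


class TestTrainDesignator:
    def test_noncalculable_label_rejected(self):
        X, _ = generate_pulse_dataset(10, seed=40, noncalculable_fraction=0.0)
        y = np.array([[0, 0]] * 10)
        with pytest.raises(ValueError):
            SubpeakDesignator(kind="unet", epochs=1).fit(X, y)

    def test_unet_overfits_small_noiseless_set(self):
        # 50 noiseless pulses, 100 epochs: the two best-scored samples must
        # fall within +-3 of the labels for >= 90% of training pulses
        X, lab = generate_pulse_dataset(50, seed=41, noncalculable_fraction=0.0,
                                        noise_sd=0.0)
        y = lab[["p1", "p2"]].to_numpy()
        des = SubpeakDesignator(kind="unet", mode="nn_output", target_sigma=2.0,
                                epochs=100, batch_size=16,
                                validation_fraction=0.0, random_state=2)
        des.fit(X, y)
        hits = 0
        for x, (p1, p2) in zip(X, y):
            res = des.designate(x)
            if res is not None and abs(res.i1 - p1) <= 3 and abs(res.i2 - p2) <= 3:
                hits += 1
        assert hits / len(X) >= 0.9
        # optimization sanity: loss non-increasing over any 10-epoch window
        tl = des.history_["train_loss"].to_numpy()
        assert np.all(tl[10:] <= tl[:-10] + 1e-4)

    def test_same_seed_identical_outputs(self):
        X, lab = generate_pulse_dataset(30, seed=42, noncalculable_fraction=0.0)
        y = lab[["p1", "p2"]].to_numpy()
        outs = []
        for _ in range(2):
            des = SubpeakDesignator(kind="unet", channels=(4, 8, 8), epochs=2,
                                    batch_size=16, random_state=3)
            des.fit(X, y)
            outs.append(des.predict(X))
        assert np.array_equal(outs[0], outs[1])


class TestParameterRecovery:
    def test_heldout_designation_accuracy(self, trained_designator,
                                          designator_data):
        # synthetic analogue of the published designation benchmark: mean
        # absolute appearance-time error <= 3% of pulse duration and ratio
        # MAE <= 0.08 on held-out pulses
        _, _, Xt, labt = designator_data
        yt = labt[["p1", "p2"]].to_numpy()
        scores = trained_designator.predict(Xt)
        pred, truth, rt, rp = [], [], [], []
        for x, s, (p1, p2), tr in zip(Xt, scores, yt,
                                      labt["true_ratio"].to_numpy()):
            res = designate(x, s, "curvature", candidates(x))
            if res is None:
                continue
            pred.append([res.i1, res.i2])
            truth.append([p1, p2])
            rt.append(tr)
            rp.append(res.ratio)
        assert len(pred) >= 0.95 * len(Xt)
        from icpulse.evaluate import appearance_mae, ratio_eval
        p1_mae, p2_mae = appearance_mae(np.array(truth), np.array(pred))
        ratio_mae, _ = ratio_eval(np.array(rt), np.array(rp))
        assert p1_mae <= 3.0
        assert p2_mae <= 3.0
        assert ratio_mae <= 0.08
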