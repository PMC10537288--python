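"""Synthetic record generator: morphology, ground truth, degradation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from icpulse.simulate import (PulseTemplate, RecordConfig, degrade,
                              generate_pulse_dataset, generate_record,
                              make_pulse, pulse_landmarks, read_record,
                              read_truth, write_record, write_truth)
from icpulse.simulate import _local_maxima


class TestMakePulse:
    def test_three_subpeaks_at_expected_apexes(self):
        # dense analytic evaluation of this Gaussian sum puts the local
        # maxima at samples 40, 79, 121 (overlap shifts them off 40/79/120)
        t = PulseTemplate((1.0, 0.8, 0.5), (0.22, 0.44, 0.67),
                          (0.07, 0.07, 0.07))
        w = make_pulse(t, 180)
        maxima = _local_maxima(w)
        assert len(maxima) == 3
        for apex, expect in zip(maxima, (40, 79, 121)):
            assert abs(apex - expect) <= 2
        assert w[maxima[0]] > w[maxima[1]] > w[maxima[2]]

    def test_single_gaussian_single_maximum(self):
        t = PulseTemplate((1.0, 0.0, 0.0))
        assert len(_local_maxima(make_pulse(t, 180))) == 1

    def test_narrow_width_limit_recovers_amplitude_quotient(self):
        # with well-separated narrow bumps the normalized apex quotient
        # converges to the configured amplitude ratio
        t = PulseTemplate((1.0, 0.8, 0.0), (0.2, 0.5, 0.8), (0.02, 0.02, 0.02))
        _, _, ratio, calc = pulse_landmarks(t, 180)
        assert calc
        assert ratio == pytest.approx(0.8, abs=1e-3)

    def test_invalid_template_rejected(self):
        with pytest.raises(ValueError):
            PulseTemplate(positions=(0.5, 0.4, 0.7))
        with pytest.raises(ValueError):
            PulseTemplate(amplitudes=(0.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            PulseTemplate(widths=(0.1, -0.1, 0.1))

    def test_too_short_beat_rejected(self):
        with pytest.raises(ValueError):
            make_pulse(PulseTemplate(), 10)

    def test_ground_truth_ratio_exact_at_stored_apexes(self):
        t = PulseTemplate((1.0, 0.9, 0.4), (0.2, 0.45, 0.7), (0.06, 0.08, 0.07))
        p1, p2, ratio, calc = pulse_landmarks(t, 120)
        assert calc
        w = make_pulse(t, 120)
        wn = (w - w.min()) / (w.max() - w.min())
        assert ratio == wn[p2] / wn[p1]


class TestGenerateRecord:
    def test_regular_beats_by_construction(self):
        cfg = RecordConfig(duration_s=60, heart_rate_bpm=60, hr_jitter=0, seed=0)
        signal, truth = generate_record(cfg)
        assert len(truth) == 60
        assert np.all(np.diff(truth["onset_sample"]) == 100)
        assert len(signal) == 6000

    def test_deterministic_for_fixed_seed(self):
        cfg = dict(duration_s=30, heart_rate_bpm=70, hr_jitter=0.05,
                   noise_sd=0.3, resp_amp=1.0, drift_amp=1.0,
                   missing_subpeak_rate=0.1, artifact_rate=0.05, seed=42)
        s1, t1 = generate_record(RecordConfig(**cfg))
        s2, t2 = generate_record(RecordConfig(**cfg))
        assert np.array_equal(s1, s2)
        assert t1.equals(t2)

    def test_degenerate_composition_reduces_to_template_beats(self):
        # no noise, respiration, drift, diastolic filling or amplitude
        # calibration: each beat is exactly the rendered template and all
        # beats are identical
        from icpulse.simulate import PulseTemplate as PT
        base = PT(positions=(0.22, 0.44, 0.67), widths=(0.06, 0.06, 0.06))
        cfg = RecordConfig(duration_s=10, heart_rate_bpm=60, hr_jitter=0,
                           noise_sd=0, resp_amp=0, drift_amp=0,
                           diastolic_amp=0, calibrate_ratio=False,
                           template=base, seed=0)
        signal, truth = generate_record(cfg)
        beat = signal[:100] - cfg.baseline_mmhg
        tmpl = PT(amplitudes=(4.0, 0.8 * 4.0, 0.5 * 0.8 * 4.0),
                  positions=base.positions, widths=base.widths)
        assert np.allclose(beat, make_pulse(tmpl, 100))
        for onset in truth["onset_sample"]:
            assert np.array_equal(signal[onset:onset + 100], signal[:100])

    def test_calibrated_beats_realize_ratio_trajectory(self):
        cfg = RecordConfig(duration_s=30, heart_rate_bpm=60, hr_jitter=0,
                           ratio_trajectory=lambda t: 1.2, seed=4)
        _, truth = generate_record(cfg)
        assert np.allclose(truth["true_ratio"], 1.2, atol=0.02)

    def test_onsets_strictly_increasing_and_count_matches_rate(self):
        cfg = RecordConfig(duration_s=90, heart_rate_bpm=80, hr_jitter=0.04,
                           seed=3)
        _, truth = generate_record(cfg)
        onsets = truth["onset_sample"].to_numpy()
        assert np.all(np.diff(onsets) > 0)
        expected = 90 / (60 / 80)
        assert abs(len(truth) - expected) <= 2

    def test_calculable_fraction_without_degradation_is_one(self):
        _, truth = generate_record(RecordConfig(duration_s=60, seed=5))
        assert truth["calculable"].all()

    def test_record_shorter_than_one_beat_rejected(self):
        with pytest.raises(ValueError):
            generate_record(RecordConfig(duration_s=0.5, heart_rate_bpm=40))


class TestDegrade:
    def test_zero_rates_identity(self):
        signal, truth = generate_record(RecordConfig(duration_s=20, seed=1))
        s2, t2 = degrade(signal, truth, 0.0, 0.0, seed=9)
        assert s2 is signal and t2 is truth

    def test_flagged_count_in_binomial_interval(self):
        # 1000 beats at missing rate 0.1: the flag count must fall inside
        # the central 99% binomial interval
        cfg = RecordConfig(duration_s=1000, heart_rate_bpm=60, hr_jitter=0,
                           missing_subpeak_rate=0.1, seed=17)
        _, truth = generate_record(cfg)
        n = len(truth)
        flagged = int((~truth["calculable"]).sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.1)
        assert lo <= flagged <= hi

    def test_degraded_beats_carry_sentinel_labels(self):
        cfg = RecordConfig(duration_s=120, artifact_rate=0.3, seed=8)
        _, truth = generate_record(cfg)
        bad = truth[~truth["calculable"]]
        assert len(bad) > 0
        assert (bad["p1_norm_idx"] == 0).all()
        assert (bad["p2_norm_idx"] == 0).all()
        assert bad["true_ratio"].isna().all()

    def test_invalid_rates_rejected(self):
        signal, truth = generate_record(RecordConfig(duration_s=20, seed=1))
        with pytest.raises(ValueError):
            degrade(signal, truth, 1.5, 0.0, seed=0)


class TestPulseDataset:
    def test_shapes_and_label_consistency(self):
        X, lab = generate_pulse_dataset(200, seed=0, noncalculable_fraction=0.2)
        assert X.shape == (200, 180)
        calc = lab["calculable"].to_numpy()
        # smooth calculable pulses keep their [0, 1] span through cubic
        # resampling; spiky artifact beats may lose their extrema to the grid
        assert np.all(X[calc].min(axis=1) < 0.01)
        assert np.all(X[calc].max(axis=1) > 0.99)
        assert X.min() > -0.5 and X.max() < 1.5
        assert 0.05 < (~calc).mean() < 0.45
        ok = lab[calc]
        assert (ok["p1"] < ok["p2"]).all()
        assert ((0 < ok["p1"]) & (ok["p2"] <= 179)).all()
        bad = lab[~calc]
        assert (bad[["p1", "p2"]] == 0).all().all()

    def test_deterministic(self):
        X1, l1 = generate_pulse_dataset(50, seed=3)
        X2, l2 = generate_pulse_dataset(50, seed=3)
        assert np.array_equal(X1, X2) and l1.equals(l2)


class TestIO:
    def test_record_roundtrip(self, tmp_path):
        signal, truth = generate_record(RecordConfig(duration_s=10, seed=2))
        p = tmp_path / "rec.csv"
        write_record(p, signal, 100.0)
        s2, fs = read_record(p)
        assert fs == pytest.approx(100.0)
        assert np.allclose(s2, signal, atol=1e-6)
        tp = tmp_path / "truth.csv"
        write_truth(tp, truth)
        t2 = read_truth(tp)
        pd.testing.assert_frame_equal(
            truth.reset_index(drop=True), t2, check_dtype=False)
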