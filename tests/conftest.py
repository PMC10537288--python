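"""Shared fixtures.

The trained-model fixtures are session-scoped because CPU training is the
dominant cost of the suite; every test that needs a fitted selector or
designator reuses the same one.
"""

import numpy as np
import pytest

from icpulse.designation import SubpeakDesignator
from icpulse.selection import PulseSelector
from icpulse.simulate import RecordConfig, generate_pulse_dataset, generate_record

#: problem sizes for the learned stages: large enough for the accuracy
#: targets, small enough for a CPU-only run (see docs/methods.md)
SELECTOR_TRAIN_N = 2500
SELECTOR_TEST_N = 800
DESIGNATOR_TRAIN_N = 1500
DESIGNATOR_TEST_N = 400


@pytest.fixture(scope="session")
def selector_data():
    """Labeled mixed pulses, 10% without a calculable ratio (as in real
    cohorts, where roughly 89-94% of pulses are calculable)."""
    X, lab = generate_pulse_dataset(SELECTOR_TRAIN_N, seed=101,
                                    noncalculable_fraction=0.10)
    Xt, labt = generate_pulse_dataset(SELECTOR_TEST_N, seed=102,
                                      noncalculable_fraction=0.10)
    return X, lab, Xt, labt


@pytest.fixture(scope="session")
def trained_selector(selector_data):
    X, lab, _, _ = selector_data
    sel = PulseSelector(kind="lstm", epochs=20, pos_weight="balanced",
                        random_state=7)
    sel.fit(X, lab["calculable"].to_numpy())
    return sel


@pytest.fixture(scope="session")
def designator_data():
    """Calculable-only pulses with random P2/P1 ratios in 0.6-1.4."""
    X, lab = generate_pulse_dataset(DESIGNATOR_TRAIN_N, seed=201,
                                    noncalculable_fraction=0.0, noise_sd=0.02)
    Xt, labt = generate_pulse_dataset(DESIGNATOR_TEST_N, seed=202,
                                      noncalculable_fraction=0.0, noise_sd=0.02)
    return X, lab, Xt, labt


@pytest.fixture(scope="session")
def trained_designator(designator_data):
    X, lab, _, _ = designator_data
    des = SubpeakDesignator(kind="lstm", mode="curvature", target_sigma=2.0,
                            epochs=30, random_state=0)
    des.fit(X, lab[["p1", "p2"]].to_numpy())
    return des


@pytest.fixture(scope="session")
def noiseless_record():
    cfg = RecordConfig(duration_s=60.0, heart_rate_bpm=60.0, hr_jitter=0.0,
                       seed=1)
    signal, truth = generate_record(cfg)
    return signal, truth, cfg


@pytest.fixture(scope="session")
def noisy_record():
    cfg = RecordConfig(duration_s=120.0, heart_rate_bpm=70.0, hr_jitter=0.03,
                       noise_sd=0.2, resp_amp=1.0, drift_amp=1.0,
                       missing_subpeak_rate=0.05, artifact_rate=0.03, seed=2)
    signal, truth = generate_record(cfg)
    return signal, truth, cfg
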