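"""P1/P2 designation and the P2/P1 ratio.

A network (1-D U-Net or bidirectional LSTM) regresses, for every normalized
pulse, a 180-point score vector against the sum of two Gaussians centered on
the labeled P1 and P2 positions (MSE loss).  At inference the two subpeaks
are designated either among the curvature-candidate indices ("curvature"
mode, scored by the network output at each candidate) or directly at the two
highest local maxima of the network output ("nn_output" mode); the earlier
index becomes P1.  The ratio is the quotient of the normalized pulse
amplitudes at the two designated samples (i.e. amplitudes relative to the
pulse minimum, invariant to the raw signal's scale and offset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from . import networks, nn
from .curvature import CandidateSet, candidates, local_maxima
from .networks import PULSE_LEN

DESIGNATOR_KINDS = ("unet", "lstm")
DESIGNATION_MODES = ("curvature", "nn_output")


class DegenerateDesignationError(ValueError):
    """Raised when the designated P1 sample has zero normalized amplitude."""


@dataclass
class PulseLabel:
    """Ground-truth subpeak positions in the 180-point frame.

    Non-calculable pulses carry the (0, 0) sentinel.
    """
    p1: int
    p2: int
    calculable: bool

    def __post_init__(self):
        if self.calculable:
            if not (0 < self.p1 < self.p2 <= PULSE_LEN - 1):
                raise ValueError("calculable label requires 0 < p1 < p2 <= 179")
        elif (self.p1, self.p2) != (0, 0):
            raise ValueError("non-calculable label must be the (0, 0) sentinel")


@dataclass
class DesignationResult:
    """Designated subpeak indices (temporal order) and their amplitude ratio."""
    i1: int
    i2: int
    ratio: float
    mode: str


def target_vector(p1: int, p2: int, sigma: float = 1.0) -> np.ndarray:
    """Regression target: half the sum of two Gaussians centered on p1, p2.

    y(t) = 1/2 (exp(-(t-p1)^2 / (2 sigma^2)) + exp(-(t-p2)^2 / (2 sigma^2)))
    on the sample-index axis t = 0..179.  The maximum value 1 is attained
    iff p1 == p2.  ``sigma`` defaults to one sample; training may widen it
    (unit-width targets are extremely sparse for an MSE objective).
    """
    t = np.arange(PULSE_LEN, dtype=float)
    s2 = 2.0 * sigma ** 2
    return 0.5 * (np.exp(-((t - p1) ** 2) / s2) + np.exp(-((t - p2) ** 2) / s2))


def build_designator(kind: str, seed: int = 0, *, channels=(16, 32, 64),
                     kernel: int = 7, lstm_hidden: int = 180,
                     dropout: float = 0.2) -> networks.Layer:
    """Instantiate an untrained designator network (deterministic per seed)."""
    if kind not in DESIGNATOR_KINDS:
        raise ValueError(f"unknown designator kind {kind!r}")
    rng = np.random.default_rng(seed)
    if kind == "unet":
        return networks.UNet1d(rng, channels=channels, kernel=kernel,
                               dropout=dropout)
    return networks.DesignatorLSTM(rng, hidden=lstm_hidden, dropout=dropout)


class SubpeakDesignator(BaseEstimator, RegressorMixin):
    """Sklearn-style heatmap regressor locating P1 and P2 on pulses.

    ``fit`` expects X of shape (n_pulses, 180) and y of shape (n_pulses, 2)
    holding the labeled (p1, p2) indices; every training pulse must be
    calculable.  ``predict`` returns the (n_pulses, 180) score vectors;
    ``designate`` turns scores into subpeak indices and ratios.
    """

    def __init__(self, kind: str = "lstm", mode: str = "curvature",
                 channels=(16, 32, 64), kernel: int = 7, lstm_hidden: int = 180,
                 dropout: float = 0.2, target_sigma: float = 1.0,
                 epochs: int = 150, learning_rate: float = 1e-3,
                 batch_size: int = 256, validation_fraction: float = 0.10,
                 random_state: int = 0):
        self.kind = kind
        self.mode = mode
        self.channels = channels
        self.kernel = kernel
        self.lstm_hidden = lstm_hidden
        self.dropout = dropout
        self.target_sigma = target_sigma
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def fit(self, X, y):
        if self.mode not in DESIGNATION_MODES:
            raise ValueError(f"unknown designation mode {self.mode!r}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[1] != PULSE_LEN:
            raise ValueError(f"X must be (n_pulses, {PULSE_LEN})")
        if y.shape != (len(X), 2):
            raise ValueError("y must be (n_pulses, 2) subpeak indices")
        for p1, p2 in y:
            PulseLabel(int(p1), int(p2), calculable=True)  # validates; raises
        targets = np.stack([target_vector(p1, p2, self.target_sigma)
                            for p1, p2 in y])
        self.net_ = build_designator(self.kind, seed=self.random_state,
                                     channels=tuple(self.channels),
                                     kernel=self.kernel,
                                     lstm_hidden=self.lstm_hidden,
                                     dropout=self.dropout)
        rng = np.random.default_rng(self.random_state + 1)
        hist = networks.fit(self.net_, X, targets, nn.mse_loss,
                            epochs=self.epochs, lr=self.learning_rate,
                            batch_size=self.batch_size,
                            validation_fraction=self.validation_fraction,
                            rng=rng)
        self.history_ = pd.DataFrame(hist)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise RuntimeError("designator is not fitted")
        return networks.predict(self.net_, np.asarray(X, dtype=float)).astype(float)

    def designate(self, pulse_values: np.ndarray,
                  cands: CandidateSet | None = None,
                  scores: np.ndarray | None = None) -> DesignationResult | None:
        """Designate P1 and P2 on one pulse; None if fewer than two candidates."""
        if scores is None:
            scores = self.predict(np.asarray(pulse_values, dtype=float)[None, :])[0]
        if self.mode == "curvature" and cands is None:
            cands = candidates(pulse_values)
        return designate(pulse_values, scores, self.mode, cands)


def _top_two_by_score(indices: np.ndarray, values: np.ndarray) -> tuple[int, int]:
    """Indices of the two highest values; score ties keep the earlier index."""
    order = np.lexsort((indices, -values))  # descending value, ascending index
    chosen = indices[order[:2]]
    return int(chosen.min()), int(chosen.max())


def designate(pulse_values: np.ndarray, scores: np.ndarray, mode: str,
              cands: CandidateSet | None = None) -> DesignationResult | None:
    """Core designation rule shared by both modes.

    curvature mode: score each candidate index by the network output there
    and keep the two highest; nn_output mode: keep the two highest local
    maxima of the score vector.  In both, the earlier index is P1.  Returns
    None (non-calculable) when fewer than two candidates/maxima exist.
    """
    if mode not in DESIGNATION_MODES:
        raise ValueError(f"unknown designation mode {mode!r}")
    if mode == "curvature":
        if cands is None:
            raise ValueError("curvature mode requires a CandidateSet")
        idx = np.asarray(cands.indices, dtype=int)
    else:
        idx = local_maxima(np.asarray(scores, dtype=float))
    if len(idx) < 2:
        return None
    i1, i2 = _top_two_by_score(idx, np.asarray(scores, dtype=float)[idx])
    ratio = p2p1_ratio(pulse_values, i1, i2)
    return DesignationResult(i1=i1, i2=i2, ratio=ratio, mode=mode)


def designate_curvature_baseline(pulse_values: np.ndarray,
                                 cands: CandidateSet | None = None,
                                 ) -> DesignationResult | None:
    """Reference method: the two earliest curvature candidates are P1, P2."""
    if cands is None:
        cands = candidates(pulse_values)
    if len(cands) < 2:
        return None
    i1, i2 = int(cands.indices[0]), int(cands.indices[1])
    return DesignationResult(i1=i1, i2=i2,
                             ratio=p2p1_ratio(pulse_values, i1, i2),
                             mode="curvature_baseline")


def p2p1_ratio(pulse_values: np.ndarray, i1: int, i2: int) -> float:
    """P2/P1 ratio on the [0, 1]-normalized pulse: values[i2] / values[i1].

    Amplitudes are relative to the pulse minimum, so the ratio is invariant
    to the raw signal's scale and offset.
    """
    if not 0 <= i1 < i2 <= PULSE_LEN - 1:
        raise ValueError("need 0 <= i1 < i2 <= 179")
    v = np.asarray(pulse_values, dtype=float)
    if v[i1] <= 0:
        raise DegenerateDesignationError("P1 amplitude is zero on the "
                                         "normalized pulse")
    return float(v[i2] / v[i1])
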