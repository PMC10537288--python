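"""Pulse selection: keep only pulses with a calculable P2/P1 ratio.

A binary sequence classifier scores each normalized 180-point pulse; three
architectures are available (1-D CNN, bidirectional LSTM, and their
parallel combination LSTM-FCN).  Training minimizes binary cross-entropy
with the Adam optimizer; the operating threshold is chosen on labeled data
at the Youden point of the ROC curve (maximal TPR - FPR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score

from . import networks, nn

SELECTOR_KINDS = ("cnn", "lstm", "lstm_fcn")


@dataclass
class SelectorConfig:
    """Architecture hyperparameters for the pulse-selection networks."""
    kind: str = "lstm"
    channels: tuple[int, int, int] = (32, 64, 128)
    kernel: int = 7
    pool: int = 2
    lstm_hidden: int = 64
    dense: tuple[int, int] = (128, 64)
    dropout: float = 0.2

    def __post_init__(self):
        if self.kind not in SELECTOR_KINDS:
            raise ValueError(f"unknown selector kind {self.kind!r}")
        if self.kernel % 2 == 0 or self.kernel <= 0:
            raise ValueError("kernel size must be a positive odd integer")


@dataclass
class TrainConfig:
    """Optimization settings shared by the selection and designation stages."""
    epochs: int = 150
    learning_rate: float = 1e-3
    batch_size: int = 256
    validation_fraction: float = 0.10
    seed: int = 0
    #: optional positive-class loss weight; "balanced" uses n_neg / n_pos
    pos_weight: float | str | None = None


def build_selector(cfg: SelectorConfig, seed: int = 0) -> networks.Layer:
    """Instantiate an untrained selector network (deterministic per seed)."""
    rng = np.random.default_rng(seed)
    if cfg.kind == "cnn":
        return networks.SelectorCNN(rng, channels=cfg.channels, kernel=cfg.kernel,
                                    pool=cfg.pool, dense=cfg.dense[0],
                                    dropout=cfg.dropout)
    if cfg.kind == "lstm":
        return networks.SelectorLSTM(rng, hidden=cfg.lstm_hidden,
                                     dense=cfg.dense, dropout=cfg.dropout)
    return networks.SelectorLSTMFCN(rng, channels=cfg.channels, kernel=cfg.kernel,
                                    pool=cfg.pool, hidden=cfg.lstm_hidden,
                                    dense=cfg.dense[0], dropout=cfg.dropout)


class PulseSelector(BaseEstimator, ClassifierMixin):
    """Sklearn-style binary classifier over normalized pulses.

    Parameters mirror SelectorConfig/TrainConfig; ``fit`` expects X of shape
    (n_pulses, 180) and boolean y (True = calculable P2/P1 ratio).  Fitted
    attributes: ``net_`` (the trained network), ``history_`` (per-epoch
    train/validation loss), ``classes_``.
    """

    def __init__(self, kind: str = "lstm", channels=(32, 64, 128), kernel: int = 7,
                 pool: int = 2, lstm_hidden: int = 64, dense=(128, 64),
                 dropout: float = 0.2, epochs: int = 150,
                 learning_rate: float = 1e-3, batch_size: int = 256,
                 validation_fraction: float = 0.10, pos_weight=None,
                 random_state: int = 0):
        self.kind = kind
        self.channels = channels
        self.kernel = kernel
        self.pool = pool
        self.lstm_hidden = lstm_hidden
        self.dense = dense
        self.dropout = dropout
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.pos_weight = pos_weight
        self.random_state = random_state

    def _config(self) -> SelectorConfig:
        return SelectorConfig(kind=self.kind, channels=tuple(self.channels),
                              kernel=self.kernel, pool=self.pool,
                              lstm_hidden=self.lstm_hidden,
                              dense=tuple(self.dense), dropout=self.dropout)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(bool)
        if X.ndim != 2 or X.shape[1] != networks.PULSE_LEN:
            raise ValueError(f"X must be (n_pulses, {networks.PULSE_LEN})")
        if len(y) != len(X):
            raise ValueError("X and y lengths differ")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("both classes must be present for training")
        cfg = self._config()
        self.net_ = build_selector(cfg, seed=self.random_state)
        rng = np.random.default_rng(self.random_state + 1)
        if self.pos_weight == "balanced":
            # equalize the two classes' total loss contributions; with a
            # small minority class the plain objective has a deep plateau at
            # the base rate that the recurrent nets fail to escape
            pos_weight = float((~y).sum() / y.sum())
        else:
            pos_weight = self.pos_weight

        def loss_fn(logits, targets):
            return nn.bce_with_logits(logits, targets, pos_weight=pos_weight)

        hist = networks.fit(self.net_, X, y.astype(float), loss_fn,
                            epochs=self.epochs, lr=self.learning_rate,
                            batch_size=self.batch_size,
                            validation_fraction=self.validation_fraction,
                            rng=rng)
        self.history_ = pd.DataFrame(hist)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Pre-sigmoid logit per pulse."""
        if not hasattr(self, "net_"):
            raise RuntimeError("selector is not fitted")
        return networks.predict(self.net_, np.asarray(X, dtype=float)).astype(float)

    def predict_proba(self, X) -> np.ndarray:
        p = nn.sigmoid(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return select_pulses(self, X, threshold)


def select_pulses(model: PulseSelector, X, threshold: float) -> np.ndarray:
    """Boolean keep-mask: sigmoid(logit) >= threshold."""
    return nn.sigmoid(model.decision_function(X)) >= threshold


def roc_auc(labels, scores) -> float:
    """Area under the ROC curve (trapezoidal over all score thresholds).

    Equals the probability that a random positive outscores a random
    negative, ties counting one half.
    """
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("ROC AUC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def youden_threshold(labels, scores) -> tuple[float, float, float]:
    """Operating threshold maximizing TPR - FPR (the Youden point).

    Candidate thresholds are the midpoints between consecutive distinct
    scores plus -inf and +inf; a pulse is called positive when its score is
    >= the threshold.  Ties in TPR - FPR are broken toward the higher
    threshold (fewer positives).  Returns (threshold, tpr, fpr).
    """
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("Youden threshold undefined with a single class")
    distinct = np.unique(scores)
    cands = np.concatenate([[-np.inf], (distinct[:-1] + distinct[1:]) / 2.0,
                            [np.inf]])
    best = None
    for thr in cands:  # ascending; >= keeps later (higher) thresholds on ties
        pred = scores >= thr
        tpr = float((pred & labels).sum()) / n_pos
        fpr = float((pred & ~labels).sum()) / n_neg
        j = tpr - fpr
        if best is None or j >= best[0]:
            best = (j, thr, tpr, fpr)
    return best[1], best[2], best[3]
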