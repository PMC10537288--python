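"""Network architectures for pulse selection and subpeak designation.

All networks consume a batch of normalized pulses shaped (B, 180) and
reshape internally: convolutional paths see (B, 1, 180) channel-first
tensors, recurrent paths see (B, 180, 1) step-major sequences.

Selector networks output one pre-sigmoid logit per pulse; designator
networks output a 180-point score vector per pulse.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import (Adam, BatchNorm1d, BiLSTM, Conv1d, Dense, Dropout, Flatten,
                 Layer, MaxPool1d, ReLU, Sequential, Upsample1d)

PULSE_LEN = 180


def _conv_block(cin: int, cout: int, kernel: int, rng,
                dropout: float = 0.0) -> list[Layer]:
    block: list[Layer] = [Conv1d(cin, cout, kernel, rng), BatchNorm1d(cout), ReLU()]
    if dropout > 0:
        block.append(Dropout(dropout, rng))
    return block


def _encoder(channels, kernel, pool, rng) -> tuple[Sequential, int]:
    """Three conv-BN-ReLU-pool blocks; returns (net, flattened feature dim)."""
    layers: list[Layer] = []
    cin, length = 1, PULSE_LEN
    for cout in channels:
        layers += _conv_block(cin, cout, kernel, rng)
        layers.append(MaxPool1d(pool))
        length //= pool
        cin = cout
    return Sequential(layers), cin * length


class SelectorCNN(Layer):
    """3-block convolutional encoder -> two dense layers -> 1 logit."""

    def __init__(self, rng, channels=(32, 64, 128), kernel=7, pool=2,
                 dense=128, dropout=0.2):
        enc, feat = _encoder(channels, kernel, pool, rng)
        self.net = Sequential(
            enc.layers
            + [Dropout(dropout, rng), Flatten(),
               Dense(feat, dense, rng), ReLU(), Dropout(dropout, rng),
               Dense(dense, 1, rng)])

    def parameters(self):
        return self.net.parameters()

    def forward(self, x, train):
        return self.net.forward(x[:, None, :], train)[:, 0]

    def backward(self, grad):
        return self.net.backward(grad[:, None])


class SelectorLSTM(Layer):
    """Bidirectional LSTM cell -> two dense layers -> 1 logit."""

    def __init__(self, rng, hidden=64, dense=(128, 64), dropout=0.2):
        self.net = Sequential([
            BiLSTM(1, hidden, rng), Dropout(dropout, rng),
            Dense(2 * hidden, dense[1], rng), ReLU(), Dropout(dropout, rng),
            Dense(dense[1], 1, rng)])

    def parameters(self):
        return self.net.parameters()

    def forward(self, x, train):
        return self.net.forward(x[:, :, None], train)[:, 0]

    def backward(self, grad):
        return self.net.backward(grad[:, None])


class SelectorLSTMFCN(Layer):
    """Convolutional encoder in parallel with an LSTM cell; the concatenated
    outputs feed two dense layers."""

    def __init__(self, rng, channels=(32, 64, 128), kernel=7, pool=2,
                 hidden=64, dense=128, dropout=0.2):
        self.encoder, feat = _encoder(channels, kernel, pool, rng)
        self.flat = Flatten()
        self.lstm = BiLSTM(1, hidden, rng)
        self.head = Sequential([
            Dense(feat + 2 * hidden, dense, rng), ReLU(), Dropout(dropout, rng),
            Dense(dense, 1, rng)])
        self._feat = feat

    def parameters(self):
        return (self.encoder.parameters() + self.lstm.parameters()
                + self.head.parameters())

    def forward(self, x, train):
        a = self.flat.forward(self.encoder.forward(x[:, None, :], train), train)
        b = self.lstm.forward(x[:, :, None], train)
        return self.head.forward(np.concatenate([a, b], axis=1), train)[:, 0]

    def backward(self, grad):
        g = self.head.backward(grad[:, None])
        ga, gb = g[:, :self._feat], g[:, self._feat:]
        dxa = self.encoder.backward(self.flat.backward(ga))[:, 0, :]
        dxb = self.lstm.backward(gb)[:, :, 0]
        return dxa + dxb


class DesignatorLSTM(Layer):
    """Bidirectional LSTM (hidden 180) -> dense (360,360) -> dense (360,180)."""

    def __init__(self, rng, hidden=180, dropout=0.2):
        self.net = Sequential([
            BiLSTM(1, hidden, rng),
            Dense(2 * hidden, 2 * hidden, rng), ReLU(), Dropout(dropout, rng),
            Dense(2 * hidden, PULSE_LEN, rng)])

    def parameters(self):
        return self.net.parameters()

    def forward(self, x, train):
        return self.net.forward(x[:, :, None], train)

    def backward(self, grad):
        return self.net.backward(grad)


class UNet1d(Layer):
    """Three-level 1-D U-Net with skip connections (180 -> 90 -> 45 -> 90 -> 180)."""

    def __init__(self, rng, channels=(16, 32, 64), kernel=7, dropout=0.2):
        c1, c2, c3 = channels
        self.enc1 = Sequential(_conv_block(1, c1, kernel, rng, dropout))
        self.pool1 = MaxPool1d(2)
        self.enc2 = Sequential(_conv_block(c1, c2, kernel, rng, dropout))
        self.pool2 = MaxPool1d(2)
        self.bottom = Sequential(_conv_block(c2, c3, kernel, rng, dropout))
        self.up2 = Upsample1d(2)
        self.dec2 = Sequential(_conv_block(c3 + c2, c2, kernel, rng, dropout))
        self.up1 = Upsample1d(2)
        self.dec1 = Sequential(_conv_block(c2 + c1, c1, kernel, rng, dropout))
        self.final = Conv1d(c1, 1, 1, rng)
        self._c = (c1, c2, c3)

    def parameters(self):
        return (self.enc1.parameters() + self.enc2.parameters()
                + self.bottom.parameters() + self.dec2.parameters()
                + self.dec1.parameters() + self.final.parameters())

    def forward(self, x, train):
        e1 = self.enc1.forward(x[:, None, :], train)          # (B, c1, 180)
        e2 = self.enc2.forward(self.pool1.forward(e1, train), train)  # (B, c2, 90)
        bt = self.bottom.forward(self.pool2.forward(e2, train), train)  # (B, c3, 45)
        d2 = self.dec2.forward(
            np.concatenate([self.up2.forward(bt, train), e2], axis=1), train)
        d1 = self.dec1.forward(
            np.concatenate([self.up1.forward(d2, train), e1], axis=1), train)
        return self.final.forward(d1, train)[:, 0, :]

    def backward(self, grad):
        c1, c2, c3 = self._c
        g = self.final.backward(grad[:, None, :])
        g = self.dec1.backward(g)
        g_up1, g_e1a = g[:, :c2], g[:, c2:]
        g = self.dec2.backward(self.up1.backward(g_up1))
        g_up2, g_e2a = g[:, :c3], g[:, c3:]
        g_bt = self.bottom.backward(self.up2.backward(g_up2))
        g_e2 = self.pool2.backward(g_bt) + g_e2a
        g_e1 = self.pool1.backward(self.enc2.backward(g_e2)) + g_e1a
        return self.enc1.backward(g_e1)[:, 0, :]


def fit(net: Layer, X: np.ndarray, Y: np.ndarray, loss_fn, *, epochs: int,
        lr: float, batch_size: int, validation_fraction: float,
        rng: np.random.Generator):
    """Minibatch-Adam training loop shared by selector and designator.

    The validation split is the last ``validation_fraction`` of a seeded
    shuffle; the model trains for the full epoch count (no early stopping).
    Returns a history list of dicts (epoch, train_loss, val_loss).
    """
    X = np.ascontiguousarray(X, dtype=nn.DTYPE)
    Y = np.ascontiguousarray(Y, dtype=nn.DTYPE)
    n = X.shape[0]
    perm = rng.permutation(n)
    n_val = int(round(validation_fraction * n))
    val_idx = perm[n - n_val:] if n_val > 0 else perm[:0]
    tr_idx = perm[:n - n_val]
    Xtr, Ytr = X[tr_idx], Y[tr_idx]
    Xval, Yval = X[val_idx], Y[val_idx]

    opt = Adam(net.parameters(), lr=lr)
    history = []
    for epoch in range(epochs):
        order = rng.permutation(len(Xtr))
        losses, weights = [], []
        for start in range(0, len(Xtr), batch_size):
            idx = order[start:start + batch_size]
            opt.zero_grad()
            out = net.forward(Xtr[idx], train=True)
            loss, grad = loss_fn(out, Ytr[idx])
            net.backward(grad)
            opt.step()
            losses.append(loss)
            weights.append(len(idx))
        train_loss = float(np.average(losses, weights=weights))
        if len(Xval):
            val_out = predict(net, Xval, batch_size=batch_size)
            val_loss, _ = loss_fn(val_out, Yval)
        else:
            val_loss = float("nan")
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": float(val_loss)})
    return history


def predict(net: Layer, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
    """Inference in eval mode (dropout off, batch-norm running stats)."""
    X = np.ascontiguousarray(X, dtype=nn.DTYPE)
    outs = [net.forward(X[s:s + batch_size], train=False)
            for s in range(0, len(X), batch_size)]
    return np.concatenate(outs, axis=0)
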