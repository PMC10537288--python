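"""Minimal neural-network engine used by the pulse selector and designator.

Implements exactly the layer set the pulse-analysis networks need — 1-D
convolution, batch normalisation, max pooling, dense layers, dropout and a
bidirectional LSTM cell — with hand-written backpropagation, an Adam
optimiser and the two losses (binary cross-entropy with logits, mean squared
error).  Everything runs in float32 on the CPU; all randomness (weight
initialisation, dropout masks, minibatch shuffling) flows through a single
``numpy.random.Generator``.

Gradients of every layer are validated against finite differences in the
test suite, so this module is safe to extend but should not be refactored
casually.
"""

from __future__ import annotations

import numpy as np

# Module-level dtype: float32 in production, switched to float64 by the
# gradient-check tests (finite differences are too noisy in single precision).
DTYPE = np.float32


class Parameter:
    """A trainable array with an accumulated gradient."""

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _uniform(rng: np.random.Generator, bound: float, shape) -> np.ndarray:
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Dense(Layer):
    """Affine map on (B, F) inputs."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(in_features)
        self.W = Parameter(_uniform(rng, bound, (in_features, out_features)))
        self.b = Parameter(_uniform(rng, bound, (out_features,)))

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, L) -> (B*L, C*k) columns for a same-padded width-k window."""
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (B,C,L,k)
    B, C, L, _ = win.shape
    return np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(B * L, C * k)


class Conv1d(Layer):
    """Same-padded, stride-1 1-D convolution on (B, C, L); odd kernel only."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.cin, self.cout, self.k = in_channels, out_channels, kernel
        bound = 1.0 / np.sqrt(in_channels * kernel)
        self.W = Parameter(_uniform(rng, bound, (in_channels * kernel, out_channels)))
        self.b = Parameter(_uniform(rng, bound, (out_channels,)))

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x, train):
        B, C, L = x.shape
        cols = _im2col(x, self.k)
        self._cols, self._shape = cols, (B, C, L)
        out = cols @ self.W.value + self.b.value  # (B*L, O)
        return out.reshape(B, L, self.cout).transpose(0, 2, 1)

    def backward(self, grad):
        B, C, L = self._shape
        g = np.ascontiguousarray(grad.transpose(0, 2, 1)).reshape(B * L, self.cout)
        self.W.grad += self._cols.T @ g
        self.b.grad += g.sum(axis=0)
        # dx is the same-padded correlation of grad with the kernel-flipped,
        # channel-transposed weights (valid because k is odd).
        Wr = self.W.value.reshape(self.cin, self.k, self.cout)
        V = Wr[:, ::-1, :].transpose(2, 1, 0).reshape(self.cout * self.k, self.cin)
        cols_g = _im2col(grad, self.k)
        dx = cols_g @ V
        return dx.reshape(B, L, self.cin).transpose(0, 2, 1)


class BatchNorm1d(Layer):
    """Per-channel normalisation over batch and length for (B, C, L) inputs."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(DTYPE)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None]) * invstd[:, None]
        self._xhat, self._invstd, self._train = xhat, invstd, train
        return self.gamma.value[:, None] * xhat + self.beta.value[:, None]

    def backward(self, grad):
        xhat, invstd = self._xhat, self._invstd
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        dxhat = grad * self.gamma.value[:, None]
        if not self._train:
            return dxhat * invstd[:, None]
        N = xhat.shape[0] * xhat.shape[2]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (invstd[:, None] / N) * (N * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pool; a trailing remainder of L is dropped."""

    def __init__(self, pool: int):
        self.pool = pool

    def forward(self, x, train):
        B, C, L = x.shape
        Lp = (L // self.pool) * self.pool
        self._in_len = L
        xr = x[:, :, :Lp].reshape(B, C, Lp // self.pool, self.pool)
        self._arg = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, grad):
        B, C, Lo = grad.shape
        dxr = np.zeros((B, C, Lo, self.pool), dtype=grad.dtype)
        b, c, l = np.ogrid[:B, :C, :Lo]
        dxr[b, c, l, self._arg] = grad
        dx = np.zeros((B, C, self._in_len), dtype=grad.dtype)
        dx[:, :, :Lo * self.pool] = dxr.reshape(B, C, Lo * self.pool)
        return dx


class Upsample1d(Layer):
    """Nearest-neighbour upsampling by an integer factor."""

    def __init__(self, factor: int):
        self.factor = factor

    def forward(self, x, train):
        return np.repeat(x, self.factor, axis=2)

    def backward(self, grad):
        B, C, L = grad.shape
        return grad.reshape(B, C, L // self.factor, self.factor).sum(axis=3)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p, self.rng = p, rng

    def forward(self, x, train):
        if not train or self.p == 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # overflow in exp(-z) saturates to inf and the result to exactly 0,
    # which is the correct limit, so the warning is suppressed rather than
    # avoided with a slower branch-free rewrite
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-z))


class LSTM(Layer):
    """Single unidirectional LSTM scanning (B, L, I); returns the final
    hidden state (B, H).  Gate order: input, forget, cell, output.  The
    forget-gate bias is initialised to 1 to ease gradient flow over the
    180-step pulse sequences."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        self.I, self.H = input_size, hidden_size
        bound = 1.0 / np.sqrt(hidden_size)
        self.Wx = Parameter(_uniform(rng, bound, (input_size, 4 * hidden_size)))
        self.Wh = Parameter(_uniform(rng, bound, (hidden_size, 4 * hidden_size)))
        b = _uniform(rng, bound, (4 * hidden_size,))
        b[hidden_size:2 * hidden_size] += 1.0
        self.b = Parameter(b)

    def parameters(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x, train):
        B, L, I = x.shape
        H = self.H
        # time-major internal layout keeps every per-step array contiguous,
        # which lets numpy's SIMD exp/tanh kernels run at full speed
        xt = np.ascontiguousarray(x.transpose(1, 0, 2))  # (L, B, I)
        xproj = (xt.reshape(L * B, I) @ self.Wx.value
                 + self.b.value).reshape(L, B, 4 * H)
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        gates = np.empty((L, B, 4 * H), dtype=x.dtype)
        cs = np.empty((L, B, H), dtype=x.dtype)
        tanhcs = np.empty((L, B, H), dtype=x.dtype)
        hs_prev = np.empty((L, B, H), dtype=x.dtype)
        Wh = self.Wh.value
        for t in range(L):
            hs_prev[t] = h
            z = xproj[t]
            z += h @ Wh
            g = gates[t]
            g[:, :2 * H] = _sigmoid(z[:, :2 * H])          # input, forget
            np.tanh(z[:, 2 * H:3 * H], out=g[:, 2 * H:3 * H])
            g[:, 3 * H:] = _sigmoid(z[:, 3 * H:])          # output
            c = g[:, H:2 * H] * c + g[:, :H] * g[:, 2 * H:3 * H]
            tc = np.tanh(c)
            h = g[:, 3 * H:] * tc
            cs[t] = c
            tanhcs[t] = tc
        self._cache = (xt, gates, cs, tanhcs, hs_prev)
        return h

    def backward(self, grad):
        xt, gates, cs, tanhcs, hs_prev = self._cache
        L, B, I = xt.shape
        H = self.H
        Wh = self.Wh.value
        dh = grad.astype(xt.dtype)
        dc = np.zeros((B, H), dtype=xt.dtype)
        dz_all = np.empty((L, B, 4 * H), dtype=xt.dtype)
        zeros = np.zeros((B, H), dtype=xt.dtype)
        for t in range(L - 1, -1, -1):
            gt = gates[t]
            i, f = gt[:, :H], gt[:, H:2 * H]
            g, o = gt[:, 2 * H:3 * H], gt[:, 3 * H:]
            tc = tanhcs[t]
            c_prev = cs[t - 1] if t > 0 else zeros
            dc += dh * o * (1 - tc * tc)
            dz = dz_all[t]
            dz[:, :H] = dc * g * i * (1 - i)
            dz[:, H:2 * H] = dc * c_prev * f * (1 - f)
            dz[:, 2 * H:3 * H] = dc * i * (1 - g * g)
            dz[:, 3 * H:] = dh * tc * o * (1 - o)
            self.Wh.grad += hs_prev[t].T @ dz
            dh = dz @ Wh.T
            dc *= f
        dz_flat = dz_all.reshape(L * B, 4 * H)
        self.Wx.grad += xt.reshape(L * B, I).T @ dz_flat
        self.b.grad += dz_flat.sum(axis=0)
        dx = (dz_flat @ self.Wx.value.T).reshape(L, B, I)
        return dx.transpose(1, 0, 2)


class BiLSTM(Layer):
    """Bidirectional LSTM cell; concatenates the two final hidden states."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        self.fwd = LSTM(input_size, hidden_size, rng)
        self.bwd = LSTM(input_size, hidden_size, rng)
        self.H = hidden_size

    def parameters(self):
        return self.fwd.parameters() + self.bwd.parameters()

    def forward(self, x, train):
        hf = self.fwd.forward(x, train)
        hb = self.bwd.forward(x[:, ::-1], train)
        return np.concatenate([hf, hb], axis=1)

    def backward(self, grad):
        dxf = self.fwd.backward(grad[:, :self.H])
        dxb = self.bwd.backward(grad[:, self.H:])
        return dxf + dxb[:, ::-1]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class Adam:
    """Adam with the standard bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def bce_with_logits(logits: np.ndarray, targets: np.ndarray,
                    pos_weight: float | None = None):
    """Numerically stable binary cross-entropy on raw logits.

    Returns (mean loss, gradient w.r.t. logits)."""
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    base = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    p = 1.0 / (1.0 + np.exp(-z))
    if pos_weight is None:
        loss = base.mean()
        grad = (p - y) / z.size
    else:
        w = 1.0 + (pos_weight - 1.0) * y
        loss = (w * base).mean()
        grad = w * (p - y) / z.size
    return float(loss), grad.astype(DTYPE)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    diff = pred.astype(np.float64) - target.astype(np.float64)
    loss = float(np.mean(diff ** 2))
    grad = (2.0 * diff / diff.size).astype(DTYPE)
    return loss, grad


def sigmoid(z: np.ndarray) -> np.ndarray:
    return _sigmoid(np.asarray(z, dtype=np.float64))
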