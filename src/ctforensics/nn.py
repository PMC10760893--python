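"""Minimal NumPy neural-network engine for the local patch detector.

Implements exactly the layer set the lightweight detector needs — standard
and depthwise convolutions, batch normalization, pooling, dense layers,
SELU/ReLU/sigmoid activations, spatial and channel attention gates, residual
blocks — each with an explicit hand-written backward pass, plus an Adam
optimizer with staircase learning-rate decay and L2 weight decay.

All feature maps are NCHW arrays in the module-wide ``DTYPE`` (float32 by
default).  Gradients are verified against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np

# canonical self-normalizing constants
SELU_LAMBDA = 1.0507009873554805
SELU_ALPHA = 1.6732632423543772

# dtype used for parameters and activations; float32 is the speed default,
# tests switch to float64 for finite-difference gradient checks
DTYPE = np.float32


def set_dtype(dtype) -> None:
    global DTYPE
    DTYPE = np.dtype(dtype).type


def selu(x, lam: float = SELU_LAMBDA, alpha: float = SELU_ALPHA):
    """Scaled exponential-linear activation: lam*x for x>0, lam*alpha*(e^x-1) else."""
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(float)
    return np.where(x > 0, lam * x, lam * alpha * (np.exp(np.minimum(x, 0.0)) - 1.0))


def sigmoid(x):
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Param:
    """A learnable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.decay = decay  # participates in L2 regularization


class Module:
    def params(self) -> list[Param]:
        return []

    def forward(self, x, train: bool):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Module):
    """Standard 2-D convolution (cross-correlation), SAME padding for stride 1.

    Uses an explicit im2col buffer so the heavy lifting is a single BLAS
    matmul in both directions.
    """

    def __init__(self, cin, cout, k, rng, stride=1, same=True, bias=False):
        fan_in = cin * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        self.w = Param(w)
        self.b = Param(np.zeros(cout), decay=False) if bias else None
        self.k, self.stride, self.same = k, stride, same

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train):
        k, s = self.k, self.stride
        p = (k - 1) // 2 if self.same else 0
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        n, c, hp, wp = xp.shape
        ho = (hp - k) // s + 1
        wo = (wp - k) // s + 1
        cols = np.empty((c, k, k, n, ho, wo), dtype=xp.dtype)
        for a in range(k):
            for b in range(k):
                cols[:, a, b] = xp[:, :, a : a + s * ho : s, b : b + s * wo : s].transpose(1, 0, 2, 3)
        m = cols.reshape(c * k * k, n * ho * wo)
        w2 = self.w.value.reshape(-1, c * k * k)
        y = (w2 @ m).reshape(-1, n, ho, wo).transpose(1, 0, 2, 3)
        if self.b is not None:
            y = y + self.b.value[None, :, None, None]
        self._m, self._xp_shape, self._pad, self._in_shape = m, xp.shape, p, x.shape
        return y

    def backward(self, dy):
        k, s = self.k, self.stride
        n, o, ho, wo = dy.shape
        c = self._xp_shape[1]
        dym = np.ascontiguousarray(dy.transpose(1, 0, 2, 3)).reshape(o, n * ho * wo)
        self.w.grad += (dym @ self._m.T).reshape(self.w.value.shape)
        if self.b is not None:
            self.b.grad += dym.sum(axis=1)
        dcols = (self.w.value.reshape(o, -1).T @ dym).reshape(c, k, k, n, ho, wo)
        dxp = np.zeros(self._xp_shape, dtype=dy.dtype)
        for a in range(k):
            for b in range(k):
                dxp[:, :, a : a + s * ho : s, b : b + s * wo : s] += dcols[:, a, b].transpose(1, 0, 2, 3)
        p = self._pad
        H, W = self._in_shape[2], self._in_shape[3]
        return dxp[:, :, p : p + H, p : p + W]


class DepthwiseConv2d(Module):
    """Per-channel k x k convolution, SAME padding, stride 1.

    Computed as k*k shifted fused multiply-adds; no im2col buffer.
    """

    def __init__(self, c, k, rng):
        w = rng.normal(0.0, np.sqrt(2.0 / (k * k)), size=(c, k, k))
        self.w = Param(w)
        self.k = k

    def params(self):
        return [self.w]

    def forward(self, x, train):
        k = self.k
        p = (k - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        n, c, hp, wp = xp.shape
        H, W = x.shape[2], x.shape[3]
        y = np.zeros_like(x)
        for a in range(k):
            for b in range(k):
                y += xp[:, :, a : a + H, b : b + W] * self.w.value[:, a, b][None, :, None, None]
        self._xp, self._in_shape = xp, x.shape
        return y

    def backward(self, dy):
        k = self.k
        p = (k - 1) // 2
        H, W = dy.shape[2], dy.shape[3]
        xp = self._xp
        dxp = np.zeros_like(xp)
        for a in range(k):
            for b in range(k):
                self.w.grad[:, a, b] += (dy * xp[:, :, a : a + H, b : b + W]).sum(axis=(0, 2, 3))
                dxp[:, :, a : a + H, b : b + W] += dy * self.w.value[:, a, b][None, :, None, None]
        return dxp[:, :, p : p + H, p : p + W]


class BatchNorm2d(Module):
    """Batch normalization; `keep` is the running-average keep-rate (decay)."""

    def __init__(self, c, keep=0.95, eps=1e-5):
        self.gamma = Param(np.ones(c), decay=False)
        self.beta = Param(np.zeros(c), decay=False)
        # zero-debiased exponential moving averages of the batch moments
        self.ema_mean = np.zeros(c, dtype=DTYPE)
        self.ema_var = np.zeros(c, dtype=DTYPE)
        self.ema_steps = 0
        self.keep, self.eps = keep, eps

    @property
    def running_mean(self):
        corr = 1.0 - self.keep ** self.ema_steps if self.ema_steps else 1.0
        return self.ema_mean / max(corr, 1e-12) if self.ema_steps else np.zeros_like(self.ema_mean)

    @running_mean.setter
    def running_mean(self, v):
        self.ema_mean = np.asarray(v, dtype=DTYPE).copy()
        self.ema_steps = max(self.ema_steps, 1 << 20)  # treat as converged

    @property
    def running_var(self):
        corr = 1.0 - self.keep ** self.ema_steps if self.ema_steps else 1.0
        return self.ema_var / max(corr, 1e-12) if self.ema_steps else np.ones_like(self.ema_var)

    @running_var.setter
    def running_var(self, v):
        self.ema_var = np.asarray(v, dtype=DTYPE).copy()
        self.ema_steps = max(self.ema_steps, 1 << 20)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.ema_mean = self.keep * self.ema_mean + (1 - self.keep) * mean
            self.ema_var = self.keep * self.ema_var + (1 - self.keep) * var
            self.ema_steps += 1
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._xhat, self._std, self._train = xhat, std, train
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy):
        xhat, std = self._xhat, self._std
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not self._train:
            return dy * g / std[None, :, None, None]
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) / std[None, :, None, None]
        return dx


class ReLU(Module):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class SELU(Module):
    def __init__(self, lam=SELU_LAMBDA, alpha=SELU_ALPHA):
        self.lam, self.alpha = lam, alpha

    def forward(self, x, train):
        self._x = x
        return selu(x, self.lam, self.alpha)

    def backward(self, dy):
        x = self._x
        grad = np.where(x > 0, self.lam, self.lam * self.alpha * np.exp(np.minimum(x, 0.0)))
        return dy * grad


class MaxPool2(Module):
    """2x2 max pooling, stride 2; ties split gradient evenly."""

    def forward(self, x, train):
        n, c, h, w = x.shape
        x6 = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = x6.max(axis=(3, 5))
        mask = (x6 == y[:, :, :, None, :, None]).astype(x.dtype)
        mask /= mask.sum(axis=(3, 5), keepdims=True)
        self._mask, self._shape = mask, x.shape
        return y

    def backward(self, dy):
        n, c, h, w = self._shape
        dx6 = dy[:, :, :, None, :, None] * self._mask
        return dx6.reshape(n, c, h, w)


class GlobalAvgPool(Module):
    """NCHW -> NC mean pooling."""

    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Dense(Module):
    def __init__(self, cin, cout, rng, bias=True):
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / cin), size=(cout, cin)))
        self.b = Param(np.zeros(cout), decay=False) if bias else None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train):
        self._x = x
        y = x @ self.w.value.T
        if self.b is not None:
            y += self.b.value
        return y

    def backward(self, dy):
        self.w.grad += dy.T @ self._x
        if self.b is not None:
            self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value


class SpatialAttention(Module):
    """Sigmoid gate from channel-wise max/mean maps through a k x k convolution.

    A_s(F) = sigma(Conv([max_c F ; mean_c F])); output is F * A_s.
    """

    def __init__(self, rng, k=7):
        self.conv = Conv2d(2, 1, k, rng, bias=True)

    def params(self):
        return self.conv.params()

    def attention_map(self, x, train=False):
        mx = x.max(axis=1, keepdims=True)
        mean = x.mean(axis=1, keepdims=True)
        s = np.concatenate([mx, mean], axis=1)
        a = sigmoid(self.conv.forward(s, train))
        return a, mx

    def forward(self, x, train):
        a, mx = self.attention_map(x, train)
        mask = (x == mx).astype(x.dtype)
        mask /= mask.sum(axis=1, keepdims=True)
        self._x, self._a, self._maxmask = x, a, mask
        return x * a

    def backward(self, dy):
        x, a = self._x, self._a
        dx = dy * a
        da = (dy * x).sum(axis=1, keepdims=True)
        dz = da * a * (1.0 - a)
        ds = self.conv.backward(dz)
        dx += ds[:, 0:1] * self._maxmask
        dx += ds[:, 1:2] / x.shape[1]
        return dx


class _SharedMLP:
    """The C -> C/4 -> C bottleneck shared by the two channel-attention paths."""

    def __init__(self, c, rng):
        hidden = max(1, c // 4)
        self.fc1 = Dense(c, hidden, rng)
        self.fc2 = Dense(hidden, c, rng)
        self.hidden = hidden

    def params(self):
        return self.fc1.params() + self.fc2.params()

    def forward(self, v):
        h = v @ self.fc1.w.value.T + self.fc1.b.value
        hr = np.maximum(h, 0.0)
        z = hr @ self.fc2.w.value.T + self.fc2.b.value
        return z, (v, h, hr)

    def backward(self, cache, dz):
        v, h, hr = cache
        self.fc2.w.grad += dz.T @ hr
        self.fc2.b.grad += dz.sum(axis=0)
        dhr = dz @ self.fc2.w.value
        dh = np.where(h > 0, dhr, 0.0)
        self.fc1.w.grad += dh.T @ v
        self.fc1.b.grad += dh.sum(axis=0)
        return dh @ self.fc1.w.value


class ChannelAttention(Module):
    """Sigmoid gate per channel: sigma(MLP(maxpool) + MLP(avgpool)), shared MLP."""

    def __init__(self, c, rng):
        self.mlp = _SharedMLP(c, rng)

    def params(self):
        return self.mlp.params()

    def attention_vector(self, x):
        gmax = x.max(axis=(2, 3))
        gavg = x.mean(axis=(2, 3))
        z1, c1 = self.mlp.forward(gmax)
        z2, c2 = self.mlp.forward(gavg)
        return sigmoid(z1 + z2), (gmax, c1, c2)

    def forward(self, x, train):
        a, (gmax, c1, c2) = self.attention_vector(x)
        mask = (x == gmax[:, :, None, None]).astype(x.dtype)
        mask /= mask.sum(axis=(2, 3), keepdims=True)
        self._x, self._a, self._c1, self._c2, self._maxmask = x, a, c1, c2, mask
        return x * a[:, :, None, None]

    def backward(self, dy):
        x, a = self._x, self._a
        dx = dy * a[:, :, None, None]
        da = (dy * x).sum(axis=(2, 3))
        dz = da * a * (1.0 - a)
        dgmax = self.mlp.backward(self._c1, dz)
        dgavg = self.mlp.backward(self._c2, dz)
        dx += dgmax[:, :, None, None] * self._maxmask
        dx += dgavg[:, :, None, None] / (x.shape[2] * x.shape[3])
        return dx


class Identity(Module):
    def forward(self, x, train):
        return x

    def backward(self, dy):
        return dy


class SepConv(Module):
    """Depthwise separable convolution: depthwise 3x3 then pointwise 1x1."""

    def __init__(self, cin, cout, rng):
        self.dw = DepthwiseConv2d(cin, 3, rng)
        self.pw = Conv2d(cin, cout, 1, rng)

    def params(self):
        return self.dw.params() + self.pw.params()

    def forward(self, x, train):
        return self.pw.forward(self.dw.forward(x, train), train)

    def backward(self, dy):
        return self.dw.backward(self.pw.backward(dy))


class _Seq(Module):
    def __init__(self, *mods):
        self.mods = list(mods)

    def params(self):
        return [p for m in self.mods for p in m.params()]

    def forward(self, x, train):
        for m in self.mods:
            x = m.forward(x, train)
        return x

    def backward(self, dy):
        for m in reversed(self.mods):
            dy = m.backward(dy)
        return dy


class TransitionBlock(Module):
    """Residual block that halves spatial size (max pool) and changes width.

    Main path: sepconv-BN-ReLU-sepconv-BN-pool; shortcut: 1x1 stride-2
    convolution + BN.  The sum passes through a final ReLU.
    """

    def __init__(self, cin, cout, rng, bn_keep=0.95):
        self.main = _Seq(
            MaxPool2(),
            SepConv(cin, cout, rng),
            BatchNorm2d(cout, bn_keep),
            ReLU(),
            SepConv(cout, cout, rng),
            BatchNorm2d(cout, bn_keep),
        )
        self.short = _Seq(Conv2d(cin, cout, 1, rng, stride=2, same=False), BatchNorm2d(cout, bn_keep))
        self.relu = ReLU()

    def params(self):
        return self.main.params() + self.short.params()

    def forward(self, x, train):
        y = self.main.forward(x, train) + self.short.forward(x, train)
        return self.relu.forward(y, train)

    def backward(self, dy):
        dy = self.relu.backward(dy)
        return self.main.backward(dy) + self.short.backward(dy)


class IdentityBlock(Module):
    """Residual block with identity skip (width and size preserved)."""

    def __init__(self, c, rng, bn_keep=0.95):
        self.main = _Seq(
            SepConv(c, c, rng),
            BatchNorm2d(c, bn_keep),
            ReLU(),
            SepConv(c, c, rng),
            BatchNorm2d(c, bn_keep),
        )
        self.relu = ReLU()

    def params(self):
        return self.main.params()

    def forward(self, x, train):
        y = self.main.forward(x, train) + x
        return self.relu.forward(y, train)

    def backward(self, dy):
        dy = self.relu.backward(dy)
        return self.main.backward(dy) + dy


def softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits, labels):
    """Mean cross-entropy loss and gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.maximum(p[np.arange(n), labels], 1e-300)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class Adam:
    """Adam with staircase exponential learning-rate decay and L2 weight decay."""

    def __init__(self, params, lr0=5e-4, decay_every=600, decay_rate=0.85,
                 beta1=0.9, beta2=0.999, eps=1e-8, l2=1e-4):
        self.params = list(params)
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.lr0, self.decay_every, self.decay_rate = lr0, decay_every, decay_rate
        self.beta1, self.beta2, self.eps, self.l2 = beta1, beta2, eps, l2
        self.t = 0

    @property
    def lr(self):
        return self.lr0 * self.decay_rate ** (self.t // self.decay_every)

    def step(self):
        lr = self.lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad
            if p.decay and self.l2:
                g = g + self.l2 * p.value
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
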