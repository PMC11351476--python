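"""Minimal numpy neural-network engine for the spatiotemporal CNN.

Implements exactly the layer set the classifier needs — 2-D convolutions
specialised to the (1, C, T) trial layout (temporal, depthwise-spatial,
separable), batch normalization, ELU, dropout, average pooling, dense,
sigmoid — together with reverse-mode gradients, SGD/Adam optimizers, and a
DeepLIFT (Rescale rule) multiplier pass that shares the linear-layer
transpose operations with ordinary backprop.

All parameters are float64 numpy arrays held in :class:`Param` objects; layer
`forward` caches whatever its `backward` needs.  Gradient correctness is
enforced by finite-difference tests rather than trusted by construction.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

_EPS_DELTA = 1e-7   # below this input delta, DeepLIFT falls back to the gradient


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def multipliers(self, m: np.ndarray, delta_in: np.ndarray,
                    delta_out: np.ndarray, x_in: np.ndarray) -> np.ndarray:
        """DeepLIFT multiplier propagation.  Linear layers propagate exactly
        like gradients; nonlinear layers override with the Rescale rule."""
        return self.backprop_input(m)

    def backprop_input(self, g: np.ndarray) -> np.ndarray:
        """Input gradient independent of cached activations (linear layers)."""
        raise NotImplementedError


def _corr_same(x: np.ndarray, k: int, pad: tuple[int, int]) -> np.ndarray:
    """Sliding length-k windows along the last axis after explicit
    (left, right) padding; the caller contracts them with filter weights."""
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [pad])
    return np.lib.stride_tricks.sliding_window_view(xp, k, axis=-1)


class TemporalConv(Layer):
    """F1 temporal filters of length K applied with same-padding along T.

    Input (N, 1, C, T) -> output (N, F1, C, T).  With even K the padding is
    asymmetric: K//2 - 1 on the left, K//2 on the right.
    """

    def __init__(self, f1: int, kernel: int, rng: np.random.Generator):
        self.f1, self.kernel = f1, kernel
        self.pad = (kernel // 2 - (kernel % 2 == 0), kernel // 2)
        self.w = Param(_glorot(rng, (f1, kernel), kernel, kernel * f1), "temporal_conv.w")

    def _windows(self, x: np.ndarray) -> np.ndarray:
        return _corr_same(x, self.kernel, self.pad)

    def forward(self, x, training):
        self._x = x
        win = self._windows(x)                      # (N,1,C,T,K)
        return np.einsum("nqctk,fk->nfct", win, self.w.value, optimize=True)

    def backward(self, g):
        win = self._windows(self._x)
        self.w.grad += np.einsum("nfct,nqctk->fk", g, win, optimize=True)
        return self.backprop_input(g)

    def backprop_input(self, g):
        K = self.kernel
        gp = np.pad(g, [(0, 0)] * (g.ndim - 1) + [(K - 1, K - 1)])
        wing = np.lib.stride_tricks.sliding_window_view(gp, K, axis=-1)
        dxp = np.einsum("nfcsk,fk->ncs", wing, self.w.value[:, ::-1], optimize=True)
        T = g.shape[-1]
        dx = dxp[:, :, self.pad[0]:self.pad[0] + T]
        return dx[:, None, :, :]

    def params(self):
        return [self.w]


class DepthwiseSpatialConv(Layer):
    """D spatial filters of size (C, 1) per temporal filter (no mixing across
    temporal filters).  Input (N, F1, C, T) -> output (N, D*F1, 1, T)."""

    def __init__(self, f1: int, depth: int, c: int, rng: np.random.Generator):
        self.f1, self.depth, self.c = f1, depth, c
        self.w = Param(_glorot(rng, (f1, depth, c), c, depth * c), "depthwise_conv.w")

    def forward(self, x, training):
        self._x = x
        y = np.einsum("nfct,fdc->nfdt", x, self.w.value, optimize=True)
        n, f1, d, t = y.shape
        return y.reshape(n, f1 * d, 1, t)

    def backward(self, g):
        n, fd, _, t = g.shape
        gr = g.reshape(n, self.f1, self.depth, t)
        self.w.grad += np.einsum("nfdt,nfct->fdc", gr, self._x, optimize=True)
        return self.backprop_input(g)

    def backprop_input(self, g):
        n, fd, _, t = g.shape
        gr = g.reshape(n, self.f1, self.depth, t)
        return np.einsum("nfdt,fdc->nfct", gr, self.w.value, optimize=True)

    def params(self):
        return [self.w]

    def filter_norms(self) -> np.ndarray:
        return np.linalg.norm(self.w.value, axis=2)


class SeparableConv(Layer):
    """Depthwise temporal convolution (K) followed by (1,1) pointwise mixing.

    Input (N, Ch, 1, T) -> output (N, F2, 1, T)."""

    def __init__(self, channels: int, kernel: int, f2: int, rng: np.random.Generator):
        self.channels, self.kernel, self.f2 = channels, kernel, f2
        self.pad = (kernel // 2 - (kernel % 2 == 0), kernel // 2)
        self.wd = Param(_glorot(rng, (channels, kernel), kernel, kernel), "separable_conv.depthwise")
        self.wp = Param(_glorot(rng, (f2, channels), channels, f2), "separable_conv.pointwise")

    def forward(self, x, training):
        self._x = x.squeeze(2)                       # (N,Ch,T)
        win = _corr_same(self._x, self.kernel, self.pad)   # (N,Ch,T,K)
        self._y1 = np.einsum("nctk,ck->nct", win, self.wd.value, optimize=True)
        y = np.einsum("nct,fc->nft", self._y1, self.wp.value, optimize=True)
        return y[:, :, None, :]

    def backward(self, g):
        gf = g.squeeze(2)                            # (N,F2,T)
        self.wp.grad += np.einsum("nft,nct->fc", gf, self._y1, optimize=True)
        g1 = np.einsum("nft,fc->nct", gf, self.wp.value, optimize=True)
        win = _corr_same(self._x, self.kernel, self.pad)
        self.wd.grad += np.einsum("nct,nctk->ck", g1, win, optimize=True)
        return self._dx_from_g1(g1)

    def _dx_from_g1(self, g1):
        K = self.kernel
        gp = np.pad(g1, [(0, 0), (0, 0), (K - 1, K - 1)])
        wing = np.lib.stride_tricks.sliding_window_view(gp, K, axis=-1)
        dxp = np.einsum("ncsk,ck->ncs", wing, self.wd.value[:, ::-1], optimize=True)
        T = g1.shape[-1]
        return dxp[:, :, self.pad[0]:self.pad[0] + T][:, :, None, :]

    def backprop_input(self, g):
        gf = g.squeeze(2)
        g1 = np.einsum("nft,fc->nct", gf, self.wp.value, optimize=True)
        return self._dx_from_g1(g1)

    def params(self):
        return [self.wd, self.wp]


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, *, T) for (N, Ch, A, T) input.

    Framework-default momentum 0.1 and epsilon 1e-5; batch statistics use the
    biased variance, running statistics track the same quantity.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.channels = channels
        self.momentum, self.eps = momentum, eps
        self.gamma = Param(np.ones(channels), "batchnorm.gamma")
        self.beta = Param(np.zeros(channels), "batchnorm.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def _bc(self, v):
        return v[None, :, None, None]

    def forward(self, x, training):
        if training:
            axes = (0, 2, 3)
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            self._ivar = 1.0 / np.sqrt(var + self.eps)
            self._xc = x - self._bc(mu)
            self._xhat = self._xc * self._bc(self._ivar)
            self._m = x.shape[0] * x.shape[2] * x.shape[3]
            self._training = True
            return self._bc(self.gamma.value) * self._xhat + self._bc(self.beta.value)
        self._training = False
        ivar = 1.0 / np.sqrt(self.running_var + self.eps)
        return self._bc(self.gamma.value * ivar) * (x - self._bc(self.running_mean)) \
            + self._bc(self.beta.value)

    def backward(self, g):
        axes = (0, 2, 3)
        self.gamma.grad += (g * self._xhat).sum(axis=axes)
        self.beta.grad += g.sum(axis=axes)
        dxhat = g * self._bc(self.gamma.value)
        m = self._m
        dvar = (dxhat * self._xc).sum(axis=axes) * (-0.5) * self._ivar ** 3
        dmu = (-dxhat.sum(axis=axes)) * self._ivar + dvar * (-2.0 / m) * self._xc.sum(axis=axes)
        return dxhat * self._bc(self._ivar) + self._bc(dvar) * 2.0 * self._xc / m \
            + self._bc(dmu) / m

    def backprop_input(self, g):
        # inference-mode affine transform (used by the DeepLIFT pass)
        ivar = 1.0 / np.sqrt(self.running_var + self.eps)
        return g * self._bc(self.gamma.value * ivar)

    def params(self):
        return [self.gamma, self.beta]


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, training):
        self._x = x
        self._y = np.where(x > 0, x, self.alpha * np.expm1(x))
        return self._y

    def _deriv(self, x, y):
        return np.where(x > 0, 1.0, y + self.alpha)

    def backward(self, g):
        return g * self._deriv(self._x, self._y)

    def multipliers(self, m, delta_in, delta_out, x_in):
        ratio = np.where(np.abs(delta_in) > _EPS_DELTA,
                         delta_out / np.where(np.abs(delta_in) > _EPS_DELTA, delta_in, 1.0),
                         self._deriv(x_in, np.where(x_in > 0, x_in, self.alpha * np.expm1(x_in))))
        return m * ratio


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        if not (0.0 <= p < 1.0):
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p, self.rng = p, rng

    def forward(self, x, training):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask

    def backprop_input(self, g):
        return g  # evaluation mode: identity


class AvgPool(Layer):
    """Average pooling along T with kernel = stride; trailing remainder dropped."""

    def __init__(self, kernel: int):
        self.kernel = kernel

    def forward(self, x, training):
        k = self.kernel
        n, ch, a, t = x.shape
        self._t_in = t
        t2 = t // k
        return x[..., :t2 * k].reshape(n, ch, a, t2, k).mean(axis=-1)

    def backward(self, g):
        return self.backprop_input(g)

    def backprop_input(self, g):
        k = self.kernel
        n, ch, a, t2 = g.shape
        dx = np.repeat(g / k, k, axis=-1)
        if t2 * k < self._t_in:
            dx = np.pad(dx, [(0, 0)] * 3 + [(0, self._t_in - t2 * k)])
        return dx


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return self.backprop_input(g)

    def backprop_input(self, g):
        return g.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.n_in, self.n_out = n_in, n_out
        self.w = Param(_glorot(rng, (n_out, n_in), n_in, n_out), "dense.w")
        self.b = Param(np.zeros(n_out), "dense.b")

    def forward(self, x, training):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, g):
        self.w.grad += g.T @ self._x
        self.b.grad += g.sum(axis=0)
        return self.backprop_input(g)

    def backprop_input(self, g):
        return g @ self.w.value

    def params(self):
        return [self.w, self.b]

    def row_norms(self) -> np.ndarray:
        return np.linalg.norm(self.w.value, axis=1)


class Sigmoid(Layer):
    def forward(self, x, training):
        self._x = x
        self._y = expit(x)
        return self._y

    def backward(self, g):
        return g * self._y * (1.0 - self._y)

    def multipliers(self, m, delta_in, delta_out, x_in):
        y = expit(x_in)
        ratio = np.where(np.abs(delta_in) > _EPS_DELTA,
                         delta_out / np.where(np.abs(delta_in) > _EPS_DELTA, delta_in, 1.0),
                         y * (1.0 - y))
        return m * ratio


# ---------------------------------------------------------------------------
# losses and optimizers
# ---------------------------------------------------------------------------

def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dz)."""
    z = z.ravel()
    y = np.asarray(y, dtype=float).ravel()
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    grad = (expit(z) - y) / len(z)
    return loss, grad.reshape(-1, 1)


class SGD:
    def __init__(self, lr: float, momentum: float = 0.9, weight_decay: float = 0.0):
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._vel: dict[int, np.ndarray] = {}

    def step(self, params: list[Param]) -> None:
        for p in params:
            g = p.grad + self.weight_decay * p.value
            v = self._vel.setdefault(id(p), np.zeros_like(p.value))
            v *= self.momentum
            v += g
            p.value -= self.lr * v

    def zero_grad(self, params: list[Param]) -> None:
        for p in params:
            p.grad[...] = 0.0


class Adam:
    def __init__(self, lr: float, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}
        self._t = 0

    def step(self, params: list[Param]) -> None:
        self._t += 1
        b1, b2 = self.betas
        for p in params:
            g = p.grad + self.weight_decay * p.value
            m = self._m.setdefault(id(p), np.zeros_like(p.value))
            v = self._v.setdefault(id(p), np.zeros_like(p.value))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self._t)
            vhat = v / (1 - b2 ** self._t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self, params: list[Param]) -> None:
        for p in params:
            p.grad[...] = 0.0


def make_optimizer(name: str, lr: float, weight_decay: float = 0.0):
    if name == "adam":
        return Adam(lr, weight_decay=weight_decay)
    if name in ("sgd", "sgd_momentum"):
        return SGD(lr, momentum=0.9, weight_decay=weight_decay)
    raise ValueError(f"unknown optimizer {name!r}")


# ---------------------------------------------------------------------------
# sequential container and DeepLIFT pass
# ---------------------------------------------------------------------------

class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def forward_collect(self, x: np.ndarray) -> tuple[np.ndarray, list[tuple[np.ndarray, np.ndarray]]]:
        """Evaluation-mode forward that records each layer's (input, output)."""
        acts = []
        for layer in self.layers:
            y = layer.forward(x, False)
            acts.append((x, y))
            x = y
        return x, acts

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]


def deeplift_rescale_pass(seq: Sequential, x: np.ndarray,
                          reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """DeepLIFT (Rescale rule) input multipliers for a sequential model.

    Runs evaluation-mode forward passes on the reference and the input,
    then propagates multipliers from the scalar output back to the input:
    linear layers use their exact transpose, elementwise nonlinearities use
    delta-out / delta-in with a gradient fallback for vanishing deltas.
    Returns ``(multipliers, f(x), f(reference))``; the attribution is
    ``multipliers * (x - reference)`` and sums to ``f(x) - f(reference)``.
    """
    y_ref, acts_ref = seq.forward_collect(reference)
    y_x, acts_x = seq.forward_collect(x)
    m = np.ones_like(y_x)
    for layer, (in_x, out_x), (in_ref, out_ref) in zip(
            reversed(seq.layers), reversed(acts_x), reversed(acts_ref)):
        m = layer.multipliers(m, in_x - in_ref, out_x - out_ref, in_x)
    return m, y_x, y_ref
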