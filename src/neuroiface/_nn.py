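"""Minimal NumPy neural-network engine.

Implements exactly the layer set needed for a small VGG-style classifier:
3x3 same-padding convolution, spatial batch normalization, ReLU, 2x2 max
pooling, dense layers, inverted dropout, and a softmax cross-entropy head,
each with a hand-written backward pass.  Everything is float32 and NHWC;
flattening is row-major over (h, w, c).

The engine is deliberately small: no autograd, no GPU, no graph.  A network
is an ordered list of layers; the trainer in :mod:`neuroiface.dcnn` drives
``forward``/``backward`` and a Nesterov-momentum SGD update.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Layer:
    """Base class: parameters and their gradients live in dicts keyed by name."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        # parameter names subject to l2 weight decay
        self.decayed: tuple[str, ...] = ()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 convolution, stride 1, same padding, NHWC.

    Implemented as nine shifted matrix products, which keeps memory flat
    (no im2col buffer) and is fast enough at desk scale.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        fan_in, fan_out = 9 * c_in, 9 * c_out
        sd = np.sqrt(2.0 / (fan_in + fan_out))  # Glorot normal
        self.params["W"] = rng.normal(0.0, sd, size=(3, 3, c_in, c_out)).astype(F32)
        self.params["b"] = np.zeros(c_out, dtype=F32)
        self.decayed = ("W",)
        self.c_in, self.c_out = c_in, c_out
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        y = np.zeros((n * h * w, self.c_out), dtype=F32)
        W = self.params["W"]
        for di in range(3):
            for dj in range(3):
                xs = xp[:, di : di + h, dj : dj + w, :].reshape(-1, self.c_in)
                y += xs @ W[di, dj]
        y += self.params["b"]
        # cached regardless of mode: eval-mode backward passes (gradients w.r.t.
        # injected activations) are part of the end-to-end translation fit
        self._xp = xp
        self._shape = (n, h, w)
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w = self._shape
        xp = self._xp
        dy = dout.reshape(-1, self.c_out)
        W = self.params["W"]
        dW = np.zeros_like(W)
        dxp = np.zeros_like(xp)
        for di in range(3):
            for dj in range(3):
                xs = xp[:, di : di + h, dj : dj + w, :].reshape(-1, self.c_in)
                dW[di, dj] = xs.T @ dy
                dxp[:, di : di + h, dj : dj + w, :] += (dy @ W[di, dj].T).reshape(
                    n, h, w, self.c_in
                )
        self.grads["W"] = dW
        self.grads["b"] = dy.sum(axis=0)
        self._xp = None
        return dxp[:, 1 : h + 1, 1 : w + 1, :]


class BatchNorm(Layer):
    """Spatial batch normalization (per channel over N, H, W).

    Training uses batch statistics and updates running statistics with
    momentum 0.9; evaluation uses the frozen running statistics, making the
    eval-mode forward pass a pure affine map.
    """

    eps = 1e-5
    momentum = 0.9

    def __init__(self, c: int) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(c, dtype=F32)
        self.params["beta"] = np.zeros(c, dtype=F32)
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self._training = False

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        g, b = self.params["gamma"], self.params["beta"]
        self._training = training
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            istd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu) * istd
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mu).astype(F32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(F32)
            self._xhat, self._istd, self._axes = xhat, istd.astype(F32), axes
            return (g * xhat + b).astype(F32)
        istd = 1.0 / np.sqrt(self.running_var + self.eps)
        self._eval_scale = (g * istd).astype(F32)
        return ((x - self.running_mean) * self._eval_scale + b).astype(F32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if not self._training:
            # eval mode is affine; used when only gradients w.r.t. inputs are needed
            self.grads["gamma"] = np.zeros_like(self.params["gamma"])
            self.grads["beta"] = np.zeros_like(self.params["beta"])
            return dout * self._eval_scale
        xhat, istd, axes = self._xhat, self._istd, self._axes
        nel = dout.size // dout.shape[-1]
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        dxhat = dout * self.params["gamma"]
        dx = (
            istd
            / nel
            * (
                nel * dxhat
                - dxhat.sum(axis=axes)
                - xhat * (dxhat * xhat).sum(axis=axes)
            )
        )
        self._xhat = None
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = np.maximum(x, 0.0)
        self._mask = y > 0
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2.  Requires even spatial dims."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        xw = xr.reshape(n, h // 2, w // 2, 4, c)
        self._idx = xw.argmax(axis=3)
        self._inshape = x.shape
        return np.take_along_axis(xw, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._inshape
        dxw = np.zeros((n, h // 2, w // 2, 4, c), dtype=dout.dtype)
        np.put_along_axis(dxw, self._idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dx = (
            dxw.reshape(n, h // 2, w // 2, 2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, h, w, c)
        )
        return dx


class Flatten(Layer):
    """Row-major flatten over (h, w, c) — the documented activation order."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._inshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._inshape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        sd = np.sqrt(2.0 / (n_in + n_out))
        self.params["W"] = rng.normal(0.0, sd, size=(n_in, n_out)).astype(F32)
        self.params["b"] = np.zeros(n_out, dtype=F32)
        self.decayed = ("W",)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        self._x = None
        return dout @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        self.rate = float(rate)
        self.rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z, dtype=np.float64)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    g = p.copy()
    g[np.arange(n), labels] -= 1.0
    return float(loss), (g / n).astype(F32)


class NesterovSGD:
    """SGD with Nesterov momentum and decoupled-by-gradient l2 weight decay."""

    def __init__(self, layers: list[Layer], lr: float, momentum: float, weight_decay: float):
        self.layers = layers
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self.vel: list[dict[str, np.ndarray]] = [
            {k: np.zeros_like(v) for k, v in lyr.params.items()} for lyr in layers
        ]

    def step(self) -> None:
        mu, lr, wd = self.momentum, self.lr, self.weight_decay
        for lyr, vel in zip(self.layers, self.vel):
            for k, w in lyr.params.items():
                g = lyr.grads[k]
                if wd and k in lyr.decayed:
                    g = g + wd * w
                v = vel[k]
                v *= mu
                v -= lr * g
                # Nesterov look-ahead update
                w += mu * v - lr * g


class Adadelta:
    """Adadelta with a learning-rate multiplier (the trial-level fitting mode)."""

    def __init__(self, layers: list[Layer], lr: float = 1.0, rho: float = 0.95,
                 eps: float = 1e-6, weight_decay: float = 0.0):
        self.layers = layers
        self.lr, self.rho, self.eps = float(lr), float(rho), float(eps)
        self.weight_decay = float(weight_decay)
        self.Eg = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in layers]
        self.Ed = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in layers]

    def step(self) -> None:
        rho, eps = self.rho, self.eps
        for lyr, Eg, Ed in zip(self.layers, self.Eg, self.Ed):
            for k, w in lyr.params.items():
                g = lyr.grads[k]
                if self.weight_decay and k in lyr.decayed:
                    g = g + self.weight_decay * w
                Eg[k] = rho * Eg[k] + (1 - rho) * g * g
                delta = -np.sqrt((Ed[k] + eps) / (Eg[k] + eps)) * g
                Ed[k] = rho * Ed[k] + (1 - rho) * delta * delta
                w += self.lr * delta
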