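"""A compact NumPy neural-network engine for small convolutional regressors.

Implements exactly what the fusion regression network needs — strided
convolutions (im2col), ReLU, batch normalization, global average pooling,
fully connected layers, a sequential container with activation/gradient
capture (for GradCAM), and the AdamW optimizer.  Layout is NCHW float32.

This is a deliberately small engine: single-threaded, CPU-only, no graph
autodiff — each layer implements its own forward/backward.  It is sized
for desk-scale backbones (tens of thousands of parameters on ~100 px
inputs), not for ImageNet-scale networks.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np


@dataclass
class Param:
    value: np.ndarray
    grad: np.ndarray | None = None
    decay: bool = True  # weight decay applies (off for biases / norm params)

    def zero_grad(self) -> None:
        self.grad = np.zeros_like(self.value)


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Layer):
    """k x k convolution with stride and symmetric zero padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        padding: int = 1,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.pad = kernel_size, stride, padding
        self.cin, self.cout = in_channels, out_channels
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Param(_he_init(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in))
        self.bias = Param(np.zeros(out_channels, dtype=np.float32), decay=False)
        self._xp: np.ndarray | None = None

    def _out_hw(self, h: int, w: int) -> tuple[int, int]:
        return (
            (h + 2 * self.pad - self.k) // self.stride + 1,
            (w + 2 * self.pad - self.k) // self.stride + 1,
        )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = self._out_hw(h, w)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        self._xp = xp  # cached for backward (GradCAM backprops through eval passes too)
        self._in_hw = (h, w)
        # windows: (n, c, ho, wo, k, k)
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        win = win[:, :, :: self.stride, :: self.stride]
        out = np.tensordot(win, self.weight.value, axes=([1, 4, 5], [1, 2, 3]))
        out = out.transpose(0, 3, 1, 2)  # (n, cout, ho, wo)
        out += self.bias.value[None, :, None, None]
        return np.ascontiguousarray(out, dtype=np.float32)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        assert self._xp is not None, "forward must run before backward"
        xp = self._xp
        n = xp.shape[0]
        ho, wo = grad_out.shape[2:]
        s, k = self.stride, self.k
        if self.bias.grad is None:
            self.bias.zero_grad()
        if self.weight.grad is None:
            self.weight.zero_grad()
        self.bias.grad += grad_out.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        W = self.weight.value
        for i in range(k):
            for j in range(k):
                patch = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
                # dW[o,c,i,j] = sum_nhw grad[n,o,h,w] * patch[n,c,h,w]
                self.weight.grad[:, :, i, j] += np.tensordot(
                    grad_out, patch, axes=([0, 2, 3], [0, 2, 3])
                )
                # dx contribution
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += np.einsum(
                    "nohw,oc->nchw", grad_out, W[:, :, i, j], optimize=True
                )
        if self.pad:
            h, w = self._in_hw
            return dxp[:, :, self.pad : self.pad + h, self.pad : self.pad + w]
        return dxp

    def params(self) -> list[Param]:
        return [self.weight, self.bias]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._mask


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels, dtype=np.float32), decay=False)
        self.beta = Param(np.zeros(channels, dtype=np.float32), decay=False)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            self._xhat = (x - mean[None, :, None, None]) / np.sqrt(
                var[None, :, None, None] + self.eps
            )
            self._var = var
            self._train_mode = True
            out = self.gamma.value[None, :, None, None] * self._xhat + self.beta.value[None, :, None, None]
        else:
            inv_std = 1.0 / np.sqrt(self.running_var[None, :, None, None] + self.eps)
            self._xhat = (x - self.running_mean[None, :, None, None]) * inv_std
            self._inv_std_eval = inv_std
            self._train_mode = False
            out = self.gamma.value[None, :, None, None] * self._xhat + self.beta.value[None, :, None, None]
        return out.astype(np.float32)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self.gamma.grad is None:
            self.gamma.zero_grad()
        if self.beta.grad is None:
            self.beta.zero_grad()
        xhat = self._xhat
        self.gamma.grad += (grad_out * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad_out.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        dxhat = grad_out * g
        if not self._train_mode:
            # eval: running stats are constants
            return (dxhat * self._inv_std_eval).astype(np.float32)
        inv_std = 1.0 / np.sqrt(self._var[None, :, None, None] + self.eps)
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv_std
        return dx.astype(np.float32)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class GlobalAvgPool(Layer):
    """NCHW -> NC spatial mean."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        h, w = self._hw
        return np.broadcast_to(
            grad_out[:, :, None, None] / (h * w), grad_out.shape + (h, w)
        ).astype(np.float32)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = Param(_he_init(rng, (d_in, d_out), d_in))
        self.bias = Param(np.zeros(d_out, dtype=np.float32), decay=False)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self.weight.grad is None:
            self.weight.zero_grad()
        if self.bias.grad is None:
            self.bias.zero_grad()
        self.weight.grad += self._x.T @ grad_out
        self.bias.grad += grad_out.sum(axis=0)
        return grad_out @ self.weight.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self.capture_index: int | None = None  # capture output of this layer index
        self.captured_activation: np.ndarray | None = None
        self.captured_gradient: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, train=train)
            if self.capture_index is not None and i == self.capture_index:
                self.captured_activation = x
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for i in range(len(self.layers) - 1, -1, -1):
            if self.capture_index is not None and i == self.capture_index:
                self.captured_gradient = grad_out
            grad_out = self.layers[i].backward(grad_out)
        return grad_out

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def last_conv_index(self) -> int:
        idx = [i for i, l in enumerate(self.layers) if isinstance(l, Conv2d)]
        if not idx:
            raise ValueError("no convolutional layer in this branch")
        return idx[-1]


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-3,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            if p.decay and self.weight_decay:
                p.value -= self.lr * self.weight_decay * p.value
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def clone_params(layer: Layer) -> list[np.ndarray]:
    return [p.value.copy() for p in layer.params()]


def load_params(layer: Layer, values: list[np.ndarray]) -> None:
    params = layer.params()
    if len(params) != len(values):
        raise ValueError("parameter count mismatch")
    for p, v in zip(params, values):
        if p.value.shape != v.shape:
            raise ValueError("parameter shape mismatch")
        p.value = v.copy()


def deep_copy_layer(layer: Layer) -> Layer:
    return copy.deepcopy(layer)
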