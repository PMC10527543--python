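"""Compact CPU neural-network engine on numpy (NCHW, float32).

Provides the handful of layers the Modified U-Net and the classifier need --
3x3/1x1 convolution (im2col + BLAS matmul), batch normalization, ReLU,
2x2 max pooling, 2x2-stride-2 transposed convolution, dropout, global
average pooling and a dense layer -- each with an explicit backward pass,
plus an Adam optimizer.  Scoped to the small networks and image sizes this
package trains; no GPU, no autograd graph.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "ConvTranspose2d",
    "Dropout",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "Adam",
    "softmax",
    "collect_params",
    "get_state",
    "set_state",
]


class Layer:
    """Base layer: holds parameters and their gradients by name."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(xp: np.ndarray, k: int) -> np.ndarray:
    # xp: (N, C, Hp, Wp) padded input -> (N*H*W, C*k*k) view-based columns
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
    N, C, H, W = win.shape[:4]
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(N * H * W, C * k * k), (N, H, W)


class Conv2d(Layer):
    """k x k convolution, stride 1, 'same' padding (k odd), He init."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.pad = k // 2
        fan_in = in_ch * k * k
        w = rng.standard_normal((out_ch, in_ch, k, k)) * np.sqrt(2.0 / fan_in)
        self.params = {"W": w.astype(np.float32), "b": np.zeros(out_ch, np.float32)}

    def forward(self, x, train=True):
        self._in_shape = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        cols, (N, H, W) = _im2col(xp, self.k)
        self._cols = np.ascontiguousarray(cols, dtype=np.float32)
        W_mat = self.params["W"].reshape(self.out_ch, -1)
        out = self._cols @ W_mat.T + self.params["b"]
        return out.reshape(N, H, W, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout):
        N, _, H, W = dout.shape
        d_mat = dout.transpose(0, 2, 3, 1).reshape(-1, self.out_ch)
        self.grads["W"] = (d_mat.T @ self._cols).reshape(self.params["W"].shape)
        self.grads["b"] = d_mat.sum(axis=0)
        # dx = 'same' correlation of dout with the flipped, channel-swapped kernel
        w_flip = self.params["W"][:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        dp = np.pad(dout, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        cols, _ = _im2col(dp, self.k)
        dx = cols @ w_flip.reshape(self.in_ch, -1).T
        del self._cols
        return dx.reshape(N, H, W, self.in_ch).transpose(0, 3, 1, 2).astype(np.float32)


class BatchNorm2d(Layer):
    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {"gamma": np.ones(ch, np.float32), "beta": np.zeros(ch, np.float32)}
        self.running_mean = np.zeros(ch, np.float32)
        self.running_var = np.ones(ch, np.float32)

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps).astype(np.float32)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        return (
            self.params["gamma"][None, :, None, None] * self._xhat
            + self.params["beta"][None, :, None, None]
        )

    def backward(self, dout):
        N, C, H, W = dout.shape
        m = N * H * W
        self.grads["gamma"] = (dout * self._xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = dout * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) / self._std[None, :, None, None]
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2."""

    def forward(self, x, train=True):
        N, C, H, W = x.shape
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        return out

    def backward(self, dout):
        d = dout[:, :, :, None, :, None] * self._mask
        N, C, Ho, _, Wo, _ = d.shape
        return d.reshape(N, C, Ho * 2, Wo * 2).astype(np.float32)


class ConvTranspose2d(Layer):
    """2x2 transposed convolution with stride 2 (exact 2x upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        w = rng.standard_normal((in_ch, out_ch, 2, 2)) * np.sqrt(2.0 / in_ch)
        self.params = {"W": w.astype(np.float32), "b": np.zeros(out_ch, np.float32)}

    def forward(self, x, train=True):
        self._x = x
        N, C, H, W = x.shape
        out = np.einsum("nchw,coab->nohawb", x, self.params["W"], optimize=True)
        out = out.reshape(N, self.out_ch, H * 2, W * 2)
        return out + self.params["b"][None, :, None, None]

    def backward(self, dout):
        N, O, H2, W2 = dout.shape
        d = dout.reshape(N, O, H2 // 2, 2, W2 // 2, 2)  # (n,o,h,a,w,b)
        self.grads["W"] = np.einsum("nohawb,nchw->coab", d, self._x, optimize=True)
        self.grads["b"] = dout.sum(axis=(0, 2, 3))
        dx = np.einsum("nohawb,coab->nchw", d, self.params["W"], optimize=True)
        return dx.astype(np.float32)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p, self.rng = float(p), rng

    def forward(self, x, train=True):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.uniform(size=x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask.astype(np.float32)

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class GlobalAvgPool(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        N, C, H, W = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (H * W), self._shape).astype(np.float32)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        w = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.params = {"W": w.astype(np.float32), "b": np.zeros(n_out, np.float32)}

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return (dout @ self.params["W"].T).astype(np.float32)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, train=True):
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def backward(self, dout):
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return dout


def collect_params(root) -> list[Layer]:
    """All parameterized layers under a model, in definition order."""
    found: list[Layer] = []

    def visit(obj):
        if isinstance(obj, Sequential):
            for lay in obj.layers:
                visit(lay)
        elif isinstance(obj, Layer):
            if obj.params:
                found.append(obj)
        elif isinstance(obj, (list, tuple)):
            for o in obj:
                visit(o)

    visit(root)
    return found


class Adam:
    """Adam over a list of parameterized layers."""

    def __init__(self, layers: list[Layer], lr: float = 2e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.layers = layers
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in layers]
        self.v = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in layers]

    def step(self):
        self.t += 1
        for i, lay in enumerate(self.layers):
            for k, p in lay.params.items():
                g = lay.grads[k].astype(np.float32)
                if self.weight_decay and k == "W":
                    g = g + self.weight_decay * p
                self.m[i][k] = self.b1 * self.m[i][k] + (1 - self.b1) * g
                self.v[i][k] = self.b2 * self.v[i][k] + (1 - self.b2) * g * g
                mh = self.m[i][k] / (1 - self.b1**self.t)
                vh = self.v[i][k] / (1 - self.b2**self.t)
                p -= self.lr * mh / (np.sqrt(vh) + self.eps)


def softmax(x: np.ndarray, axis: int = 1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def get_state(root) -> list[dict[str, np.ndarray]]:
    """Deep-copied parameter snapshot, including batch-norm running stats."""
    state = []
    for lay in collect_params(root):
        st = {k: v.copy() for k, v in lay.params.items()}
        if isinstance(lay, BatchNorm2d):
            st["_running_mean"] = lay.running_mean.copy()
            st["_running_var"] = lay.running_var.copy()
        state.append(st)
    return state


def set_state(root, state: list[dict[str, np.ndarray]]) -> None:
    for lay, st in zip(collect_params(root), state, strict=True):
        for k in lay.params:
            lay.params[k][...] = st[k]
        if isinstance(lay, BatchNorm2d):
            lay.running_mean[...] = st["_running_mean"]
            lay.running_var[...] = st["_running_var"]
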