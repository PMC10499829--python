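"""A compact reverse-mode automatic-differentiation engine for small CNNs.

This is a deliberately minimal, numpy-backed training engine sized for
networks that train comfortably on a CPU: dynamic computation graph over
:class:`Tensor`, the handful of operations a UNet needs (3x3/1x1
convolutions via im2col + matmul, batch normalization, ReLU/sigmoid, 2x2 max
pooling, bilinear 2x upsampling, channel concatenation, global average
pooling, dense layers, channel/spatial gating, elementwise max) and an Adam
optimizer.  Every operation's gradient is validated against central finite
differences in the test suite.

Arrays are float32 throughout, NCHW layout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "conv2d",
    "linear",
    "relu",
    "sigmoid",
    "maxpool2",
    "upsample_bilinear2",
    "concat_channels",
    "global_avg_pool",
    "scale_channels",
    "scale_spatial",
    "elementwise_max",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "Adam",
]


class Tensor:
    """A node in the computation graph: value, gradient, and backward rule."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def backward(self, grad: np.ndarray) -> None:
        """Backpropagate an upstream gradient (same shape as ``data``)."""
        grad = np.asarray(grad, dtype=np.float32)
        if grad.shape != self.data.shape:
            raise ValueError("seed gradient shape must match tensor shape")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = grad if self.grad is None else self.grad + grad
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None:
                    continue
                parent.grad = g if parent.grad is None else parent.grad + g
            if not node.requires_grad and node is not self:
                node.grad = None  # free intermediate gradients early


def Parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


# ---------------------------------------------------------------------------
# ops
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """'same' convolution, stride 1, odd kernel, via im2col."""
    N, C, H, W = x.data.shape
    Co, Ci, kh, kw = w.data.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Ci}")
    ph, pw = kh // 2, kw // 2
    if ph or pw:
        xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    else:
        xp = x.data
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N * H * W, C * kh * kw
    )
    wmat = w.data.reshape(Co, -1)
    out = cols @ wmat.T
    if b is not None:
        out += b.data
    out_nchw = out.reshape(N, H, W, Co).transpose(0, 3, 1, 2)

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * H * W, Co)
        dw = (gmat.T @ cols).reshape(w.data.shape)
        db = None if b is None else gmat.sum(axis=0)
        dcols = (gmat @ wmat).reshape(N, H, W, C, kh, kw)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + H, j:j + W] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        dx = dxp[:, :, ph:ph + H, pw:pw + W] if (ph or pw) else dxp
        return (dx, dw) if b is None else (dx, dw, db)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_nchw, parents, backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    out = x.data @ w.data
    if b is not None:
        out = out + b.data

    def backward(g):
        dx = g @ w.data.T
        dw = x.data.T @ g
        if b is None:
            return dx, dw
        return dx, dw, g.sum(axis=0)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, parents, backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, (x,), lambda g: (g * mask,))


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor(s, (x,), lambda g: (g * s * (1.0 - s),))


def maxpool2(x: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2 needs even spatial dimensions")
    H2, W2 = H // 2, W // 2
    xr = np.ascontiguousarray(
        x.data.reshape(N, C, H2, 2, W2, 2).transpose(0, 1, 2, 4, 3, 5)
    ).reshape(N, C, H2, W2, 4)
    arg = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        dxr = np.zeros((N, C, H2, W2, 4), dtype=np.float32)
        np.put_along_axis(dxr, arg[..., None], g[..., None], axis=-1)
        dx = dxr.reshape(N, C, H2, W2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W)
        return (dx,)

    return Tensor(out, (x,), backward)


_BILINEAR_CACHE: dict[int, np.ndarray] = {}


def _bilinear_matrix(h: int) -> np.ndarray:
    """(2h, h) interpolation matrix for 2x upsampling, align_corners=False."""
    mat = _BILINEAR_CACHE.get(h)
    if mat is None:
        src = (np.arange(2 * h) + 0.5) / 2.0 - 0.5
        i0 = np.floor(src).astype(int)
        f = (src - i0).astype(np.float32)
        lo = np.clip(i0, 0, h - 1)
        hi = np.clip(i0 + 1, 0, h - 1)
        mat = np.zeros((2 * h, h), dtype=np.float32)
        np.add.at(mat, (np.arange(2 * h), lo), 1.0 - f)
        np.add.at(mat, (np.arange(2 * h), hi), f)
        _BILINEAR_CACHE[h] = mat
    return mat


def upsample_bilinear2(x: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    Ah, Aw = _bilinear_matrix(H), _bilinear_matrix(W)
    t = np.tensordot(x.data, Aw, axes=([3], [1]))          # N,C,H,2W
    out = np.tensordot(t, Ah, axes=([2], [1]))             # N,C,2W,2H
    out = np.ascontiguousarray(out.transpose(0, 1, 3, 2))  # N,C,2H,2W

    def backward(g):
        gt = np.tensordot(g, Ah, axes=([2], [0]))          # N,C,2W? -> N,C,2W,H
        gt = gt.transpose(0, 1, 3, 2)                      # N,C,H,2W
        dx = np.tensordot(gt, Aw, axes=([3], [0]))         # N,C,H,W
        return (np.ascontiguousarray(dx),)

    return Tensor(out, (x,), backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[1]
    out = np.concatenate([a.data, b.data], axis=1)
    return Tensor(out, (a, b), lambda g: (g[:, :ca], g[:, ca:]))


def global_avg_pool(x: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    out = x.data.mean(axis=(2, 3))

    def backward(g):
        return (np.broadcast_to(g[:, :, None, None] / (H * W), x.data.shape).astype(np.float32),)

    return Tensor(out, (x,), backward)


def scale_channels(x: Tensor, s: Tensor) -> Tensor:
    """Multiply feature maps by per-(sample, channel) gains s of shape (N, C)."""
    sb = s.data[:, :, None, None]
    out = x.data * sb

    def backward(g):
        dx = g * sb
        ds = (g * x.data).sum(axis=(2, 3))
        return dx, ds

    return Tensor(out, (x, s), backward)


def scale_spatial(x: Tensor, s: Tensor) -> Tensor:
    """Multiply feature maps by a per-pixel gate s of shape (N, 1, H, W)."""
    out = x.data * s.data

    def backward(g):
        dx = g * s.data
        ds = (g * x.data).sum(axis=1, keepdims=True)
        return dx, ds

    return Tensor(out, (x, s), backward)


def elementwise_max(a: Tensor, b: Tensor) -> Tensor:
    mask = a.data >= b.data
    out = np.where(mask, a.data, b.data)
    return Tensor(out, (a, b), lambda g: (g * mask, g * (~mask)))


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    """Base class: parameter collection and train/eval mode propagation."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def set_training(self, training: bool) -> None:
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.set_training(training)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.set_training(training)
        if hasattr(self, "training"):
            self.training = training


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 bias: bool = True):
        fan_in = c_in * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, (c_out, c_in, kernel, kernel)))
        # convolutions feeding a batch norm omit the bias: the normalization
        # subtracts any constant channel offset, leaving a dead parameter
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / c_in)
        self.weight = Parameter(rng.normal(0.0, std, (c_in, c_out)))
        self.bias = Parameter(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        return linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
        out = self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]
        gamma, training = self.gamma, self.training

        def backward(g):
            dgamma = (g * xhat).sum(axis=(0, 2, 3))
            dbeta = g.sum(axis=(0, 2, 3))
            gs = gamma.data[None, :, None, None] * inv_std[None, :, None, None]
            if training:
                m = g.shape[0] * g.shape[2] * g.shape[3]
                sum_g = g.sum(axis=(0, 2, 3), keepdims=True)
                sum_gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = gs * (g - sum_g / m - xhat * sum_gx / m)
            else:
                dx = gs * g
            return dx.astype(np.float32), dgamma, dbeta

        return Tensor(out, (x, self.gamma, self.beta), backward)


class Adam:
    """Adam optimizer with the standard bias-corrected moments."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * (g * g)
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
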