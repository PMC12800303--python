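"""Minimal CPU tensor engine for the segmentation and regression networks.

A small reverse-mode autodiff over numpy ``float32`` arrays, providing just
the operations the residual U-Net family needs: same-padded convolution,
batch normalization, ReLU, 2x2 max pooling, nearest-neighbour upsampling,
channel concatenation, linear layers, and the segmentation losses (binary
cross-entropy, softmax cross-entropy, soft Dice, and their compounds).

Everything is deterministic given the seeds used for initialization and
shuffling: no threading, no fused kernels, plain numpy arithmetic. This is
deliberately sized for desk-scale experiments (small images, narrow
networks), which is all the package's tests and pipelines require.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "Adam",
    "relu",
    "maxpool2",
    "upsample2",
    "concat",
    "global_avg_pool",
    "softplus",
    "sigmoid_np",
    "softmax_np",
    "bce_loss",
    "softmax_ce_loss",
    "dice_loss_binary",
    "dice_loss_softmax",
    "add_losses",
]


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False,
                 _prev: tuple = (), _backward: Callable[[], None] | None = None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = _backward
        self._prev = _prev

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Reverse-mode sweep from this (scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    def __add__(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _backward():
            self._accum(out.grad)
            other._accum(out.grad)

        out._backward = _backward
        return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, _prev=(x,))

    def _backward():
        x._accum(out.grad * mask)

    out._backward = _backward
    return out


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along the channel axis of (N, C, H, W) tensors."""
    ca = a.data.shape[1]
    out = Tensor(np.concatenate([a.data, b.data], axis=1), _prev=(a, b))

    def _backward():
        a._accum(out.grad[:, :ca])
        b._accum(out.grad[:, ca:])

    out._backward = _backward
    return out


def maxpool2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    flat = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, _prev=(x,))

    def _backward():
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], out.grad[..., None], axis=-1)
        g = gflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accum(g.reshape(n, c, h, w))

    out._backward = _backward
    return out


def upsample2(x: Tensor) -> Tensor:
    out = Tensor(x.data.repeat(2, axis=2).repeat(2, axis=3), _prev=(x,))

    def _backward():
        n, c, h, w = out.grad.shape
        g = out.grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
        x._accum(g)

    out._backward = _backward
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) mean over the spatial axes."""
    n, c, h, w = x.data.shape
    out = Tensor(x.data.mean(axis=(2, 3)), _prev=(x,))

    def _backward():
        x._accum(np.broadcast_to(out.grad[:, :, None, None] / (h * w), x.data.shape))

    out._backward = _backward
    return out


def softplus(x: Tensor) -> Tensor:
    z = x.data
    out_data = np.where(z > 20, z, np.log1p(np.exp(np.minimum(z, 20))))
    out = Tensor(out_data, _prev=(x,))

    def _backward():
        x._accum(out.grad / (1.0 + np.exp(-z)))

    out._backward = _backward
    return out


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Module:
    def _children(self):
        """Yield (name, value) over tensors, buffers and submodules,
        recursing through arbitrarily nested lists/tuples."""

        def expand(name, v):
            if isinstance(v, (Tensor, np.ndarray, Module)):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    yield from expand(f"{name}.{i}", item)

        for name, v in self.__dict__.items():
            yield from expand(name, v)

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for _, v in self._children():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
        return params

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and buffers (for I/O)."""
        out: dict[str, np.ndarray] = {}

        def walk(mod: "Module", prefix: str) -> None:
            for name, v in mod._children():
                key = f"{prefix}{name}"
                if isinstance(v, Tensor) and v.requires_grad:
                    out[key] = v.data
                elif isinstance(v, np.ndarray):
                    out[key] = v
                elif isinstance(v, Module):
                    walk(v, key + ".")

        walk(self, "")
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        target = self.state_arrays()
        for key, arr in state.items():
            if key not in target:
                raise KeyError(f"unknown parameter {key!r}")
            np.copyto(target[key], np.asarray(arr, dtype=target[key].dtype))


class Conv2d(Module):
    """Same-padded odd-kernel convolution, stride 1."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.k = k
        scale = np.sqrt(2.0 / (cin * k * k))
        self.weight = Tensor(rng.normal(0.0, scale, (cout, cin, k, k)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return _conv2d(x, self.weight, self.bias, self.k)


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray | None, k: int) -> np.ndarray:
    n, c, h, wd = x.shape
    cout = w.shape[0]
    if k == 1:
        out = np.tensordot(x, w[:, :, 0, 0], axes=([1], [1])).transpose(0, 3, 1, 2)
    else:
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (n, c, h, wd, k, k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h, wd, c * k * k)
        wm = w.reshape(cout, c * k * k).T
        out = (cols @ wm).transpose(0, 3, 1, 2)
    if b is not None:
        out = out + b[None, :, None, None]
    return np.ascontiguousarray(out, dtype=np.float32)


def _conv2d(x: Tensor, weight: Tensor, bias: Tensor, k: int) -> Tensor:
    out = Tensor(_conv_forward(x.data, weight.data, bias.data, k),
                 _prev=(x, weight, bias))

    def _backward():
        g = out.grad
        bias._accum(g.sum(axis=(0, 2, 3)))
        n, c, h, wd = x.data.shape
        cout = weight.data.shape[0]
        if k == 1:
            dw = np.tensordot(g, x.data, axes=([0, 2, 3], [0, 2, 3]))
            weight._accum(dw[:, :, None, None])
        else:
            pad = k // 2
            xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
            win = sliding_window_view(xp, (k, k), axis=(2, 3))
            cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(-1, c * k * k)
            gm = g.transpose(0, 2, 3, 1).reshape(-1, cout)
            weight._accum((gm.T @ cols).reshape(cout, c, k, k))
        # dx: same-pad convolution of the gradient with the flipped kernel
        wflip = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        x._accum(_conv_forward(g, np.ascontiguousarray(wflip), None, k))

    out._backward = _backward
    return out


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
        out = Tensor(self.gamma.data[None, :, None, None] * xhat
                     + self.beta.data[None, :, None, None],
                     _prev=(x, self.gamma, self.beta))

        def _backward():
            g = out.grad
            self.beta._accum(g.sum(axis=(0, 2, 3)))
            self.gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            gs = self.gamma.data[None, :, None, None] * inv[None, :, None, None]
            if training:
                m = g.shape[0] * g.shape[2] * g.shape[3]
                gmean = g.mean(axis=(0, 2, 3))[None, :, None, None]
                gxmean = (g * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
                x._accum(gs * (g - gmean - xhat * gxmean))
            else:
                x._accum(gs * g)

        out._backward = _backward
        return out


class Linear(Module):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / nin)
        self.weight = Tensor(rng.normal(0.0, scale, (nin, nout)), requires_grad=True)
        self.bias = Tensor(np.zeros(nout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        out = Tensor(x.data @ self.weight.data + self.bias.data,
                     _prev=(x, self.weight, self.bias))

        def _backward():
            g = out.grad
            self.bias._accum(g.sum(axis=0))
            self.weight._accum(x.data.T @ g)
            x._accum(g @ self.weight.data.T)

        out._backward = _backward
        return out


class Adam:
    """Adam optimizer with bias correction."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Activations on raw arrays and losses on logits
# ---------------------------------------------------------------------------

def sigmoid_np(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax_np(z: np.ndarray, axis: int = 1) -> np.ndarray:
    zmax = z.max(axis=axis, keepdims=True)
    e = np.exp(z - zmax)
    return e / e.sum(axis=axis, keepdims=True)


def bce_loss(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on logits (numerically stable)."""
    z = logits.data
    t = np.asarray(targets, dtype=np.float32)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(loss.mean(), _prev=(logits,))

    def _backward():
        logits._accum(out.grad * (sigmoid_np(z) - t) / z.size)

    out._backward = _backward
    return out


def softmax_ce_loss(logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Mean per-pixel cross-entropy for (N, C, H, W) logits vs one-hot."""
    p = softmax_np(logits.data, axis=1)
    t = np.asarray(onehot, dtype=np.float32)
    npix = logits.data.shape[0] * logits.data.shape[2] * logits.data.shape[3]
    loss = -(t * np.log(np.maximum(p, 1e-12))).sum() / npix
    out = Tensor(loss, _prev=(logits,))

    def _backward():
        logits._accum(out.grad * (p - t) / npix)

    out._backward = _backward
    return out


def dice_loss_binary(logits: Tensor, targets: np.ndarray, eps: float = 1.0) -> Tensor:
    """1 - soft Dice on sigmoid probabilities."""
    z = logits.data
    t = np.asarray(targets, dtype=np.float32)
    p = sigmoid_np(z)
    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum() + eps)
    out = Tensor(1.0 - 2.0 * inter / denom, _prev=(logits,))

    def _backward():
        dldp = -(2.0 * t * denom - 2.0 * inter) / denom**2
        logits._accum(out.grad * dldp * p * (1.0 - p))

    out._backward = _backward
    return out


def dice_loss_softmax(logits: Tensor, onehot: np.ndarray, eps: float = 1.0,
                      fg_channels: Sequence[int] = (1, 2)) -> Tensor:
    """1 - mean soft Dice over foreground channels of a softmax head."""
    t = np.asarray(onehot, dtype=np.float32)
    p = softmax_np(logits.data, axis=1)
    dldp = np.zeros_like(p)
    dice_sum = 0.0
    for c in fg_channels:
        inter = float((p[:, c] * t[:, c]).sum())
        denom = float(p[:, c].sum() + t[:, c].sum() + eps)
        dice_sum += 2.0 * inter / denom
        dldp[:, c] = -(2.0 * t[:, c] * denom - 2.0 * inter) / denom**2
    k = len(fg_channels)
    out = Tensor(1.0 - dice_sum / k, _prev=(logits,))
    dldp /= k

    def _backward():
        inner = (dldp * p).sum(axis=1, keepdims=True)
        logits._accum(out.grad * p * (dldp - inner))

    out._backward = _backward
    return out


def add_losses(*losses: Tensor) -> Tensor:
    total = losses[0]
    for loss in losses[1:]:
        total = total + loss
    return total
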