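"""Neural-network layers, containers and optimizers on top of the autograd core.

The module system mirrors the conventions of mainstream deep-learning
frameworks at a small scale: a :class:`Module` owns named :class:`Parameter`
tensors and sub-modules, exposes ``parameters()`` / ``state_dict()`` and a
``zero_grad()``.  Frozen state (e.g. fixed wavelet analysis filters) is held
in *buffers*: plain tensors that never receive gradients and are excluded
from optimizer updates.
"""

from __future__ import annotations

import math
from collections import OrderedDict

import numpy as np

from .autograd import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "LayerNorm",
    "MLP",
    "Sequential",
    "conv2d",
    "depthwise_conv2d",
    "SGD",
    "AdamW",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self._parameters: OrderedDict[str, Parameter] = OrderedDict()
        self._buffers: OrderedDict[str, Tensor] = OrderedDict()
        self._modules: OrderedDict[str, Module] = OrderedDict()

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_parameters", OrderedDict())[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", OrderedDict())[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: Tensor):
        value.requires_grad = False
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._parameters.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for mname, m in self._modules.items():
            yield from m.named_buffers(prefix + mname + ".")

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        out = {}
        for name, p in self.named_parameters():
            out[name] = p.data.copy()
        for name, b in self.named_buffers():
            out[name] = b.data.copy()
        return out

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        own.update(dict(self.named_buffers()))
        for name, arr in state.items():
            if name not in own:
                raise KeyError(f"unexpected key in state dict: {name}")
            if own[name].data.shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}")
            own[name].data = np.asarray(arr, dtype=np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.weight + self.bias


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class MLP(Module):
    """Multi-layer perceptron with ReLU between hidden layers."""

    def __init__(self, in_dim: int, hidden_dim: int, out_dim: int, n_layers: int,
                 rng: np.random.Generator):
        super().__init__()
        dims = [in_dim] + [hidden_dim] * (n_layers - 1) + [out_dim]
        self.n_layers = n_layers
        for i in range(n_layers):
            self._modules[f"lin{i}"] = Linear(dims[i], dims[i + 1], rng)

    def forward(self, x: Tensor) -> Tensor:
        for i in range(self.n_layers):
            x = self._modules[f"lin{i}"](x)
            if i < self.n_layers - 1:
                x = x.relu()
        return x


# ---------------------------------------------------------------------------
# Convolution (im2col gather composite; adjoint handled by the autograd core)
# ---------------------------------------------------------------------------

def _window_view(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """Zero-copy sliding-window view (N, C, OH, OW, KH, KW) of padded input."""
    view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(-2, -1))
    if stride > 1:
        view = view[:, :, ::stride, ::stride]
    return view


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """Dense 2-D cross-correlation as a single autograd primitive.

    x: (N, C, H, W); weight: (Cout, C, KH, KW) -> (N, Cout, OH, OW).
    """
    n, cin, h, w = x.shape
    cout, cin_w, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError("channel mismatch in conv2d")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding),
                         (padding, padding))) if padding else x.data
    view = _window_view(xp, kh, kw, stride)
    out_data = np.einsum("nchwij,ocij->nohw", view, weight.data,
                         optimize=True)
    oh, ow = out_data.shape[-2:]

    def backward(g):
        if weight.requires_grad:
            weight._accum(np.einsum("nchwij,nohw->ocij", view, g,
                                    optimize=True))
        if x.requires_grad:
            gx = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    contrib = np.einsum("nohw,oc->nchw", g,
                                        weight.data[:, :, i, j], optimize=True)
                    gx[:, :, i:i + oh * stride:stride,
                       j:j + ow * stride:stride] += contrib
            if padding:
                gx = gx[:, :, padding:padding + h, padding:padding + w]
            x._accum(gx)

    out = Tensor._make(out_data, (x, weight), backward)
    if bias is not None:
        out = out + bias.reshape(1, cout, 1, 1)
    return out


def depthwise_conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
                     stride: int = 1, padding: int = 0) -> Tensor:
    """Per-channel 2-D cross-correlation (no cross-channel mixing).

    x: (N, C, H, W); weight: (C, KH, KW) -> (N, C, OH, OW).
    """
    n, c, h, w = x.shape
    cw, kh, kw = weight.shape
    if c != cw:
        raise ValueError("channel mismatch in depthwise_conv2d")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding),
                         (padding, padding))) if padding else x.data
    view = _window_view(xp, kh, kw, stride)
    out_data = np.einsum("nchwij,cij->nchw", view, weight.data, optimize=True)
    oh, ow = out_data.shape[-2:]

    def backward(g):
        if weight.requires_grad:
            weight._accum(np.einsum("nchwij,nchw->cij", view, g,
                                    optimize=True))
        if x.requires_grad:
            gx = np.zeros_like(xp)
            wd = weight.data
            for i in range(kh):
                for j in range(kw):
                    gx[:, :, i:i + oh * stride:stride,
                       j:j + ow * stride:stride] += g * wd[:, i, j][:, None, None]
            if padding:
                gx = gx[:, :, padding:padding + h, padding:padding + w]
            x._accum(gx)

    out = Tensor._make(out_data, (x, weight), backward)
    if bias is not None:
        out = out + bias.reshape(1, c, 1, 1)
    return out


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

class SGD:
    def __init__(self, params: list, lr: float = 1e-2):
        self.params = list(params)
        self.lr = lr

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad


class AdamW:
    def __init__(self, params: list, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)
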